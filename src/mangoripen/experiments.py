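"""Seeded parameter-recovery and model-selection studies.

These are the end-to-end checks the pipeline is validated by: simulate
data whose generating parameters are known (published fixture values),
run the estimation stage, and compare the recovered quantity with the
generating one.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .characterize import transpiration_coefficient
from .model import ModelSpec, StorageTimeResults, candidate_specs, compare_models, fit_mlr
from .profiles import LOCAL_VARIETIES, default_profiles
from .published import LinearModel, load_published_models
from .simulate import CampaignDesign, simulate_campaign, simulate_harvest_lot, simulate_weight_series

_COLUMN_OF = {"Hue": "hue_deg"}


def evaluate_on_frame(linear: LinearModel, df: pd.DataFrame) -> np.ndarray:
    """Vectorized evaluation of a linear model on observation rows."""
    y = np.full(len(df), linear.intercept, dtype=float)
    for p, beta in linear.coefficients.items():
        col = p if p in df.columns else _COLUMN_OF.get(p, p)
        y += beta * df[col].to_numpy(dtype=float)
    return y


def diourou_xform_recovery(n_fruit: int = 20) -> StorageTimeResults:
    """Refit the published Diourou X-form equation on noiseless data.

    Generates ``n_fruit`` fruits' pulp trajectories along the Diourou
    anchors with zero noise at days 0/4/8/12, computes the response
    exactly from the published equation, and refits OLS with intercept.
    The recovered coefficients equal the generating ones up to float
    round-off.
    """
    profile = default_profiles()["Diourou"].noiseless()
    design = CampaignDesign(
        varieties=(profile,), n_per_variety=n_fruit, seed=0, replicates=1
    )
    obs = simulate_campaign(design)
    bank = load_published_models()
    obs["R_ST_true"] = evaluate_on_frame(bank.intra["Diourou"]["X"], obs)
    spec = ModelSpec(("pH", "Hue", "SSC"), "X", scope="single-variety",
                     label="Diourou refit")
    return fit_mlr(obs, spec, response="R_ST_true")


def model3_recovery(n_fruit: int = 20) -> StorageTimeResults:
    """Refit the published multi-varietal model 3 on noiseless data.

    Five local varieties x ``n_fruit`` fruit x days 0/4/8/12, noiseless
    trajectories; C_f from the published per-variety values and C_c from
    the weight/volume-derived fixtures; response computed exactly from
    the model-3 equation; OLS refit on (pH, Hue, SSC, C_f, C_c).
    """
    profiles = default_profiles()
    design = CampaignDesign(
        varieties=tuple(profiles[v].noiseless() for v in LOCAL_VARIETIES),
        n_per_variety=n_fruit, seed=0, replicates=1,
    )
    obs = simulate_campaign(design)
    bank = load_published_models()
    obs["C_f"] = obs["variety"].map(bank.c_f)
    obs["C_c"] = obs["variety"].map(bank.c_c)
    obs["R_ST_true"] = evaluate_on_frame(bank.multivarietal[3], obs)
    spec = ModelSpec(("pH", "Hue", "SSC", "C_f", "C_c"), "X", label="model 3 refit")
    return fit_mlr(obs, spec, response="R_ST_true")


def ctr_recovery(
    seed: int,
    n_replicates: int = 100,
    n_fruit: int = 5,
    noise_sd: float = 0.3,
    variety: str = "Boukodiekhal",
    condition: str = "CC",
) -> tuple[float, np.ndarray]:
    """Recover the transpiration rate from noisy weight series.

    Per replicate: simulate ``n_fruit`` fruits' weight series at days
    0/4/8/12 with additive loss noise of ``noise_sd`` percentage points,
    pool the fruits and estimate the through-origin slope.  Returns the
    mean estimate over replicates and the per-replicate estimates.
    """
    from dataclasses import replace

    profile = replace(default_profiles()[variety], loss_noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_replicates)
    for r in range(n_replicates):
        lot = simulate_harvest_lot(profile, n_fruit, rng)
        series = [
            simulate_weight_series(profile, fruit, (0, 4, 8, 12), condition, rng)
            for fruit in lot
        ]
        slopes[r], _ = transpiration_coefficient(series)
    return float(slopes.mean()), slopes


def model_selection_study(
    seed: int,
    n_replicates: int = 50,
    noise_sd: float = 0.73,
    n_fruit: int = 20,
) -> tuple[float, list[str]]:
    """How often AIC selects the generating model (or a superset of it).

    Per replicate: simulate a noisy five-variety campaign, attach the
    published varietal fixtures, generate the response from the
    multi-varietal model-3 equation plus Gaussian noise (SD in days),
    fit all six candidates and rank by AIC.  Success means the winner is
    model 3 or its superset model 2.  Returns the success fraction and
    the winner labels.
    """
    bank = load_published_models()
    profiles = default_profiles()
    rng = np.random.default_rng(seed)
    winners = []
    specs = candidate_specs("X")
    for _ in range(n_replicates):
        design = CampaignDesign(
            varieties=tuple(profiles[v] for v in LOCAL_VARIETIES),
            n_per_variety=n_fruit,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        obs = simulate_campaign(design)
        obs["C_f"] = obs["variety"].map(bank.c_f)
        obs["C_c"] = obs["variety"].map(bank.c_c)
        obs["C_tr"] = obs["variety"].map(bank.c_tr_cc)
        obs["R_ST_sim"] = evaluate_on_frame(
            bank.multivarietal[3], obs
        ) + rng.normal(0.0, noise_sd, size=len(obs))
        comparison = compare_models(obs, specs, response="R_ST_sim")
        winners.append(comparison.best_label)
    rate = sum(w in ("3", "2") for w in winners) / len(winners)
    return rate, winners
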