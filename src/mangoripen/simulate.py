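"""Synthetic harvest lots, weight-loss series and ripening campaigns.

The generator emulates the study design the models were developed on:
per-variety harvest lots whose weight follows ``cc_true * L*l*e`` with
multiplicative noise, linear percentage weight loss at the variety's
transpiration rate, and pulp physicochemistry following monotone
piecewise-linear trajectories between anchor values at storage days
0/4/8/12, with two pseudo-replicate measurements per fruit and day.
Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characterize import FruitCaliber, PulpMeasurement, WeightSeries
from .errors import ValidationError
from .profiles import ANCHOR_DAYS, PULP_PARAMS, VarietyProfile, default_profiles

#: Column order of the tidy observation table (the io schema).
OBSERVATION_COLUMNS = [
    "fruit_id", "variety", "campaign", "day", "replicate",
    "weight_g", "L_cm", "l_cm", "e_cm", "condition",
    "pH", "TA", "SSC", "DM", "Lstar", "astar", "bstar", "hue_deg",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _positive_normal(rng, means, sds, n):
    """Draw n x len(means) truncated-positive normals (resample <= 0)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    out = rng.normal(means, sds, size=(n, means.size))
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(
            np.broadcast_to(means, out.shape)[bad],
            np.broadcast_to(sds, out.shape)[bad],
        )
        bad = out <= 0
    return out


def simulate_harvest_lot(
    profile: VarietyProfile, n: int, seed
) -> list[FruitCaliber]:
    """Draw ``n`` fruits of one variety at the green-mature stage.

    Dimensions are truncated-positive normal with the profile's means
    and SDs; weight is ``cc_true * L*l*e * (1 + eps)`` with relative
    Gaussian noise ``eps``.
    """
    if n < 1:
        raise ValidationError("lot size must be >= 1")
    rng = _rng(seed)
    dims = _positive_normal(rng, profile.dim_means, profile.dim_sds, n)
    eps = rng.normal(0.0, profile.weight_rel_noise, size=n)
    tag = profile.name.replace(" ", "")
    lot = []
    for i in range(n):
        L, l, e = dims[i]
        weight = profile.cc_true * L * l * e * (1.0 + eps[i])
        lot.append(
            FruitCaliber(
                fruit_id=f"{tag}-{i + 1:03d}",
                variety=profile.name,
                weight_g=weight,
                L_cm=L, l_cm=l, e_cm=e,
            )
        )
    return lot


def simulate_weight_series(
    profile: VarietyProfile,
    fruit: FruitCaliber,
    days,
    condition: str,
    seed,
) -> WeightSeries:
    """Simulate one fruit's storage weight trajectory.

    Percentage loss follows ``ctr_true * t`` plus additive Gaussian
    noise at each post-harvest weighing (none at day 0); the noisy loss
    is clipped to be non-decreasing so weights never increase.
    """
    days = tuple(float(d) for d in days)
    if not days or days[0] != 0 or any(b < a for a, b in zip(days, days[1:])):
        raise ValidationError("days must be sorted and start at 0")
    rate = profile.transpiration_rate(condition)
    rng = _rng(seed)
    loss = rate * np.asarray(days)
    noise = rng.normal(0.0, profile.loss_noise_sd, size=len(days))
    noise[0] = 0.0
    loss = np.maximum.accumulate(np.clip(loss + noise, 0.0, 100.0))
    weights = fruit.weight_g * (1.0 - loss / 100.0)
    return WeightSeries(
        fruit_id=fruit.fruit_id,
        condition=condition,
        days=days,
        weights_g=tuple(float(w) for w in weights),
    )


def _interp_anchor(profile: VarietyProfile, param: str, day: float) -> float:
    return float(np.interp(day, ANCHOR_DAYS, profile.anchors[param]))


def simulate_ripening_trajectory(
    profile: VarietyProfile,
    fruit: FruitCaliber,
    days,
    seed,
    replicates: int = 2,
) -> list[PulpMeasurement]:
    """Simulate destructive pulp assays for one fruit.

    Each parameter follows monotone piecewise-linear interpolation of
    the day-{0,4,8,12} anchors plus Gaussian measurement noise, drawn
    independently for each of the pseudo-replicates.  Colour channels
    (a*, b*) are back-computed from the generated hue at the profile's
    reference chroma so the hue round-trips exactly.
    """
    if profile.anchors is None:
        raise ValidationError(f"{profile.name}: no trajectory anchors")
    lo, hi = ANCHOR_DAYS[0], ANCHOR_DAYS[-1]
    days = [float(d) for d in days]
    if any(d < lo or d > hi for d in days):
        raise ValidationError(f"days must lie within [{lo}, {hi}]")
    rng = _rng(seed)
    chroma = profile.chroma_ref
    out = []
    for day in days:
        for rep in range(1, replicates + 1):
            values = {}
            for param in PULP_PARAMS:
                sd = profile.meas_noise_sd.get(param, 0.0)
                v = _interp_anchor(profile, param, day) + rng.normal(0.0, sd)
                if param in ("TA", "SSC"):
                    v = max(v, 0.0)
                values[param] = v
            hue_rad = math.radians(values["Hue"])
            out.append(
                PulpMeasurement(
                    fruit_id=fruit.fruit_id,
                    day=day,
                    replicate=rep,
                    pH=values["pH"],
                    TA=values["TA"],
                    SSC=values["SSC"],
                    DM=values["DM"],
                    Lstar=values["Lstar"],
                    astar=chroma * math.cos(hue_rad),
                    bstar=chroma * math.sin(hue_rad),
                    hue_deg=values["Hue"],
                )
            )
    return out


@dataclass(frozen=True)
class CampaignDesign:
    """Design of one simulated measurement campaign."""

    varieties: tuple[VarietyProfile, ...]
    n_per_variety: int
    seed: int
    sampling_days: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    condition: str = "CC"
    campaign: str = "C1"
    replicates: int = 2

    def __post_init__(self):
        if self.n_per_variety < 1:
            raise ValidationError("n_per_variety must be >= 1")
        days = self.sampling_days
        if not days or days[0] != 0 or any(b < a for a, b in zip(days, days[1:])):
            raise ValidationError("sampling_days must be sorted and start at 0")
        if self.condition not in ("CC", "CA"):
            raise ValidationError("condition must be CC or CA")
        names = [p.name for p in self.varieties]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate variety names in design: {names}")


def simulate_campaign(design: CampaignDesign) -> pd.DataFrame:
    """Run a full campaign: one tidy row per fruit x day x replicate.

    The ``day`` column is the ripening storage time R_ST (the response
    variable); ``weight_g`` is the fruit's weight at that day from its
    simulated weight series.  Varieties without trajectory anchors (the
    Kent reference) contribute caliber and weight rows with empty pulp
    columns.
    """
    rng = _rng(design.seed)
    rows = []
    for profile in design.varieties:
        lot = simulate_harvest_lot(profile, design.n_per_variety, rng)
        for fruit in lot:
            series = simulate_weight_series(
                profile, fruit, design.sampling_days, design.condition, rng
            )
            weight_at = dict(zip(series.days, series.weights_g))
            if profile.anchors is not None:
                pulp = simulate_ripening_trajectory(
                    profile, fruit, design.sampling_days, rng,
                    replicates=design.replicates,
                )
            else:
                pulp = [
                    PulpMeasurement(fruit.fruit_id, d, r, 4.0, 0.0, 10.0, 15.0,
                                    75.0, 0.0, 40.0, 90.0)
                    for d in design.sampling_days
                    for r in range(1, design.replicates + 1)
                ]
            blank = profile.anchors is None
            for m in pulp:
                rows.append({
                    # campaign prefix keeps fruit ids disjoint across campaigns
                    "fruit_id": f"{design.campaign}-{fruit.fruit_id}",
                    "variety": profile.name,
                    "campaign": design.campaign,
                    "day": m.day,
                    "replicate": m.replicate,
                    "weight_g": weight_at[m.day],
                    "L_cm": fruit.L_cm,
                    "l_cm": fruit.l_cm,
                    "e_cm": fruit.e_cm,
                    "condition": design.condition,
                    "pH": np.nan if blank else m.pH,
                    "TA": np.nan if blank else m.TA,
                    "SSC": np.nan if blank else m.SSC,
                    "DM": np.nan if blank else m.DM,
                    "Lstar": np.nan if blank else m.Lstar,
                    "astar": np.nan if blank else m.astar,
                    "bstar": np.nan if blank else m.bstar,
                    "hue_deg": np.nan if blank else m.hue_deg,
                })
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def calibration_design(seed: int, **overrides) -> CampaignDesign:
    """Default calibration campaign: 5 local varieties x 20 fruit."""
    profiles = default_profiles()
    kwargs = dict(
        varieties=tuple(profiles[v] for v in _local_names()),
        n_per_variety=20,
        seed=seed,
        campaign="C1",
    )
    kwargs.update(overrides)
    return CampaignDesign(**kwargs)


def validation_design(seed: int, **overrides) -> CampaignDesign:
    """Default validation campaign: 5 local varieties x 15 fruit."""
    profiles = default_profiles()
    kwargs = dict(
        varieties=tuple(profiles[v] for v in _local_names()),
        n_per_variety=15,
        seed=seed,
        campaign="C2",
    )
    kwargs.update(overrides)
    return CampaignDesign(**kwargs)


def _local_names():
    from .profiles import LOCAL_VARIETIES

    return LOCAL_VARIETIES
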