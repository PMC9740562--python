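"""Published model and parameter fixtures.

The study that developed this pipeline reported, for five Senegalese
mango varieties ripened at 25 °C/86 % RH:

* per-variety intra-varietal models of storage time on (pH, Hue, SSC),
  each in absolute (X) and relative (alpha) variable form;
* six multi-varietal candidate models adding the varietal variables
  C_tr, C_f and C_c in different combinations (model 1 is the
  physicochemical control, model 3 the AIC-selected one);
* an alpha-form multi-varietal model (the "days-to-quality" model)
  with predictors alpha_pH, alpha_Hue, alpha_SSC, C_f and C_c;
* the variety-level fixtures: shape coefficients C_f, transpiration
  rates C_tr under both storage conditions, and caliber coefficients
  C_c (derived here as mean fruit weight divided by the product of the
  mean dimensions, since only the per-variety regression lines were
  published graphically).

These coefficients are fixtures, kept verbatim; they are what the
prediction module evaluates when no freshly fitted model is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import IntegrityError, ValidationError
from .profiles import LOCAL_VARIETIES, default_profiles

_ALLOWED_COEFFICIENTS = {"pH", "Hue", "SSC", "C_tr", "C_f", "C_c"}


@dataclass(frozen=True)
class LinearModel:
    """A linear storage-time model: intercept plus named coefficients."""

    label: str
    form: str  # "X" or "alpha"
    intercept: float
    coefficients: Mapping[str, float]
    scope: str = "multi-variety"
    baselines: Mapping[str, Mapping[str, float]] | None = None
    metrics: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.form not in ("X", "alpha"):
            raise IntegrityError(f"{self.label}: unknown variable form {self.form!r}")
        unknown = set(self.coefficients) - _ALLOWED_COEFFICIENTS
        if unknown:
            raise IntegrityError(f"{self.label}: unknown coefficient(s) {unknown}")
        if not self.coefficients:
            raise IntegrityError(f"{self.label}: empty coefficient set")

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def evaluate(self, features: Mapping[str, float]) -> float:
        """Intercept + sum of coefficient * feature; features must be on
        the model's own scale (alpha values for alpha-form models)."""
        missing = [p for p in self.coefficients if p not in features]
        if missing:
            raise ValidationError(f"{self.label}: missing predictor(s) {missing}")
        return self.intercept + sum(
            beta * float(features[p]) for p, beta in self.coefficients.items()
        )


@dataclass(frozen=True)
class PublishedModelBank:
    """All published models and varietal parameter fixtures."""

    intra: Mapping[str, Mapping[str, LinearModel]]
    multivarietal: Mapping[int, LinearModel]
    eq_alpha: LinearModel
    c_f: Mapping[str, float]
    c_tr_cc: Mapping[str, float]
    c_tr_ca: Mapping[str, float]
    c_c: Mapping[str, float]

    def __getitem__(self, variety: str) -> Mapping[str, LinearModel]:
        return self.intra[variety]


def _intra(variety, form, intercept, b_ph, b_hue, b_ssc):
    return LinearModel(
        label=f"{variety} [{form}]",
        form=form,
        intercept=intercept,
        coefficients={"pH": b_ph, "Hue": b_hue, "SSC": b_ssc},
        scope="single-variety",
    )


def load_published_models() -> PublishedModelBank:
    """Build the versioned fixture bank of published models."""
    intra = {
        "Boukodiekhal": {
            "X": _intra("Boukodiekhal", "X", 5.148, 1.346, -0.133, 0.554),
            "alpha": _intra("Boukodiekhal", "alpha", 5.148, 4.393, -13.377, 3.916),
        },
        "Diourou": {
            "X": _intra("Diourou", "X", 9.729, 0.79, -0.168, 0.548),
            "alpha": _intra("Diourou", "alpha", 9.729, 2.221, -16.810, 4.890),
        },
        "Papaye": {
            "X": _intra("Papaye", "X", 1.277, 1.75, -0.109, 0.523),
            "alpha": _intra("Papaye", "alpha", 1.277, 5.031, -10.273, 4.108),
        },
        "Sierra Léone": {
            "X": _intra("Sierra Léone", "X", 1.442, 0.998, -0.13, 0.821),
            "alpha": _intra("Sierra Léone", "alpha", 1.442, 3.368, -12.375, 7.673),
        },
        "Sewe": {
            "X": _intra("Sewe", "X", 4.285, 1.367, -0.14, 0.679),
            "alpha": _intra("Sewe", "alpha", 4.285, 4.665, -13.857, 5.166),
        },
    }

    multi = {
        1: LinearModel("multivarietal 1 (control)", "X", 4.440,
                       {"pH": 0.996, "Hue": -0.132, "SSC": 0.665}),
        2: LinearModel("multivarietal 2", "X", 17.817,
                       {"pH": 1.060, "Hue": -0.134, "SSC": 0.662,
                        "C_tr": -0.731, "C_f": -0.100, "C_c": -21.614}),
        3: LinearModel("multivarietal 3", "X", 16.335,
                       {"pH": 0.989, "Hue": -0.139, "SSC": 0.660,
                        "C_f": -0.090, "C_c": -18.698}),
        4: LinearModel("multivarietal 4", "X", 12.038,
                       {"pH": 1.090, "Hue": -0.131, "SSC": 0.657,
                        "C_c": -14.836}),
        5: LinearModel("multivarietal 5", "X", 5.000,
                       {"pH": 0.966, "Hue": -0.134, "SSC": 0.666,
                        "C_f": -0.022}),
        6: LinearModel("multivarietal 6", "X", 5.302,
                       {"pH": 0.781, "Hue": -0.152, "SSC": 0.655,
                        "C_tr": 2.386}),
    }

    eq_alpha = LinearModel(
        "multivarietal alpha (days-to-quality)",
        "alpha",
        8.44,
        {"pH": 2.49, "Hue": -16.28, "SSC": 4.70, "C_f": -0.11, "C_c": 4.06},
    )

    c_f = {"Boukodiekhal": 16.8, "Diourou": 12.9, "Papaye": 15.9,
           "Sierra Léone": 11.1, "Sewe": 6.7, "Kent": 13.8}
    c_tr_cc = {"Boukodiekhal": 1.05, "Diourou": 0.76, "Papaye": 0.52,
               "Sierra Léone": 0.75, "Sewe": 0.85, "Kent": 0.41}
    c_tr_ca = {"Boukodiekhal": 2.35, "Diourou": 1.35, "Papaye": 1.07,
               "Sierra Léone": 2.22, "Sewe": 1.93, "Kent": 0.93}

    # C_c fixture: mean weight / volume of mean dimensions per variety.
    profiles = default_profiles()
    c_c = {name: p.weight_mean_g / math.prod(p.dim_means)
           for name, p in profiles.items()}

    bank = PublishedModelBank(
        intra=intra, multivarietal=multi, eq_alpha=eq_alpha,
        c_f=c_f, c_tr_cc=c_tr_cc, c_tr_ca=c_tr_ca, c_c=c_c,
    )
    _verify(bank)
    return bank


def _verify(bank: PublishedModelBank) -> None:
    """Internal consistency of the fixture bank."""
    for variety in LOCAL_VARIETIES:
        if variety not in bank.intra:
            raise IntegrityError(f"missing intra-varietal models for {variety}")
        forms = bank.intra[variety]
        if forms["X"].intercept != forms["alpha"].intercept:
            raise IntegrityError(f"{variety}: X/alpha intercepts must match")
        for fixture in (bank.c_f, bank.c_tr_cc, bank.c_tr_ca, bank.c_c):
            if variety not in fixture:
                raise IntegrityError(f"missing varietal fixture for {variety}")
    if set(bank.multivarietal) != {1, 2, 3, 4, 5, 6}:
        raise IntegrityError("multi-varietal bank must hold models 1-6")
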