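"""Applying storage-time models: point prediction and days-to-quality.

``predict_storage_time`` evaluates a linear model (published fixture or
freshly fitted results) on a feature mapping and returns the continuous
prediction alongside a whole-day answer (nearest integer, clamped at
zero — storage times are reported in whole days).

``days_to_quality`` answers the operational question the alpha-form
multi-varietal model was built for: starting from a measured initial
pulp range (pH, SSC, Hue), how many storage days at 25 °C/86 % RH until
a target range is reached, for a variety described by its shape (C_f)
and caliber (C_c) parameters.  Only the ratios target/initial enter the
model, so the answer is invariant to the absolute scale of the ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from .errors import BaselineError, ValidationError
from .model import ALPHA_TRANSFORMED, StorageTimeResults
from .published import LinearModel


@dataclass(frozen=True)
class QualityRange:
    """A pulp quality state: pH, SSC (°Brix) and hue angle (degrees)."""

    pH: float
    SSC: float
    Hue: float

    def __post_init__(self):
        if min(self.pH, self.SSC, self.Hue) <= 0:
            raise ValidationError("quality range components must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {"pH": self.pH, "SSC": self.SSC, "Hue": self.Hue}


@dataclass(frozen=True)
class Prediction:
    """Continuous and whole-day storage-time prediction."""

    days: float
    rounded: int


def _as_linear(model) -> LinearModel:
    if isinstance(model, LinearModel):
        return model
    if isinstance(model, StorageTimeResults):
        return LinearModel(
            label=model.spec.label,
            form=model.spec.variable_form,
            intercept=model.intercept,
            coefficients={k: float(v) for k, v in model.coefficients.items()},
            scope=model.spec.scope,
        )
    raise ValidationError(f"cannot predict from {type(model).__name__}")


def predict_storage_time(
    model,
    features: Mapping[str, float],
    baselines: Mapping[str, float] | None = None,
) -> Prediction:
    """Evaluate a storage-time model on one feature mapping.

    ``features`` must cover the model's predictors.  For alpha-form
    models the physicochemical features are divided by ``baselines``
    (harvest values X_p(0)) when provided; otherwise they are assumed to
    be alpha values already.  Negative continuous predictions are
    clamped to 0 with a warning.
    """
    linear = _as_linear(model)
    feats = dict(features)
    if linear.form == "alpha" and baselines is not None:
        for p in ALPHA_TRANSFORMED:
            if p in feats:
                x0 = baselines.get(p)
                if x0 is None or x0 <= 0:
                    raise BaselineError(f"baseline for {p} must be > 0")
                feats[p] = feats[p] / x0
    days = linear.evaluate(feats)
    if days < 0:
        warnings.warn(
            f"negative storage-time prediction ({days:.2f} d) clamped to 0",
            stacklevel=2,
        )
    rounded = max(0, round(days))
    return Prediction(days=days, rounded=int(rounded))


def days_to_quality(
    alpha_model,
    initial: QualityRange,
    target: QualityRange,
    c_f: float,
    c_c: float,
) -> Prediction:
    """Storage days from an initial to a target pulp quality range.

    Computes the alpha ratios target/initial for pH, SSC and Hue and
    evaluates the alpha-form multi-varietal model with the variety's
    shape and caliber coefficients.
    """
    linear = _as_linear(alpha_model)
    if linear.form != "alpha":
        raise ValidationError("days_to_quality requires an alpha-form model")
    ini, tgt = initial.as_dict(), target.as_dict()
    features = {p: tgt[p] / ini[p] for p in ("pH", "SSC", "Hue")}
    features["C_f"] = c_f
    features["C_c"] = c_c
    return predict_storage_time(linear, features)
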