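"""Variety-level simulation profiles.

A :class:`VarietyProfile` bundles everything the synthetic-campaign
generator needs to emulate one mango variety: the harvest caliber
distribution (mean and SD of the three dimensions L, l, e and of fruit
weight), the caliber coefficient ``cc_true`` relating weight to the
dimension product, the transpiration rates under controlled (CC,
25 °C/86 % RH) and ambient (CA, 29 °C/57 % RH) storage, and the pulp
ripening trajectory expressed as anchor values of pH, TA, SSC, DM, Hue
(and L*) at storage days 0, 4, 8 and 12.

:func:`default_profiles` returns the fixture set for the five Senegalese
varieties studied (Boukodiekhal, Diourou, Papaye, Sierra Léone, Sewe)
plus the export reference Kent.  Caliber and weight-loss numbers are the
published variety means; trajectory anchors reproduce the published
harvest and ripe-stage values and interpolate plausibly in between.  The
Kent profile carries caliber and weight-loss fixtures only (its pulp was
not followed), so its ``anchors`` is ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ValidationError

#: Storage days at which trajectory anchors are defined.
ANCHOR_DAYS = (0.0, 4.0, 8.0, 12.0)

#: Pulp parameters carried by the trajectory anchors.
PULP_PARAMS = ("pH", "TA", "SSC", "DM", "Hue", "Lstar")

_INCREASING = ("pH", "SSC")
_DECREASING = ("TA", "Hue", "Lstar")

#: Relative tolerance for the "dry matter stays approximately constant"
#: invariant (DM is a harvest-maturity indicator, not a ripening one).
_DM_REL_DRIFT = 0.10


@dataclass(frozen=True)
class VarietyProfile:
    """True parameters and trajectory anchors driving simulation.

    Parameters
    ----------
    name : str
        Variety label.
    dim_means, dim_sds : tuple of float
        Means and SDs of (L_max, l_max, e_max) in cm.
    weight_mean_g, weight_sd_g : float
        Harvest fruit weight mean and SD in g (reference values; the
        generator derives weight from the dimensions via ``cc_true``).
    ctr_true_cc, ctr_true_ca : float
        True transpiration rates (% of initial weight lost per day)
        under controlled and ambient storage.
    cc_true : float, optional
        True caliber coefficient in g/cm^3 (slope of weight on L*l*e).
        Defaults to ``weight_mean_g`` divided by the volume of the
        dimension means.
    weight_rel_noise : float
        Relative SD of the multiplicative weight noise around
        ``cc_true * L * l * e``.
    loss_noise_sd : float
        SD, in percentage points, of the additive noise on the
        weight-loss percentage at each post-harvest weighing.
    anchors : mapping or None
        ``{parameter: (value at day 0, 4, 8, 12)}`` for the pulp
        parameters; ``None`` when the variety's pulp was not followed.
    meas_noise_sd : mapping
        Per-parameter SD of the pulp measurement noise.
    chroma_ref : float
        CIELAB chroma used to back-compute (a*, b*) from the generated
        hue angle.
    """

    name: str
    dim_means: tuple[float, float, float]
    dim_sds: tuple[float, float, float]
    weight_mean_g: float
    weight_sd_g: float
    ctr_true_cc: float
    ctr_true_ca: float
    cc_true: float | None = None
    weight_rel_noise: float = 0.03
    loss_noise_sd: float = 0.3
    anchors: Mapping[str, tuple[float, ...]] | None = None
    meas_noise_sd: Mapping[str, float] = field(default_factory=dict)
    chroma_ref: float = 40.0

    def __post_init__(self):
        if self.cc_true is None:
            volume = math.prod(self.dim_means)
            object.__setattr__(self, "cc_true", self.weight_mean_g / volume)
        if any(s < 0 for s in self.dim_sds) or self.weight_sd_g < 0:
            raise ValidationError(f"{self.name}: standard deviations must be >= 0")
        if self.weight_rel_noise < 0 or self.loss_noise_sd < 0:
            raise ValidationError(f"{self.name}: noise SDs must be >= 0")
        if any(s < 0 for s in self.meas_noise_sd.values()):
            raise ValidationError(f"{self.name}: measurement noise SDs must be >= 0")
        if self.cc_true <= 0:
            raise ValidationError(f"{self.name}: cc_true must be > 0")
        if self.ctr_true_cc < 0 or self.ctr_true_ca < 0:
            raise ValidationError(f"{self.name}: transpiration rates must be >= 0")
        if self.anchors is not None:
            self._check_anchors()

    def _check_anchors(self):
        for param, values in self.anchors.items():
            if len(values) != len(ANCHOR_DAYS):
                raise ValidationError(
                    f"{self.name}: {param} needs {len(ANCHOR_DAYS)} anchor values"
                )
            diffs = [b - a for a, b in zip(values, values[1:])]
            if param in _INCREASING and any(d < 0 for d in diffs):
                raise ValidationError(
                    f"{self.name}: {param} anchors must be non-decreasing"
                )
            if param in _DECREASING and any(d > 0 for d in diffs):
                raise ValidationError(
                    f"{self.name}: {param} anchors must be non-increasing"
                )
            if param == "DM" and abs(values[-1] - values[0]) > _DM_REL_DRIFT * values[0]:
                raise ValidationError(
                    f"{self.name}: DM anchors must be approximately constant"
                )

    # -- convenience -------------------------------------------------

    @property
    def mean_volume_cm3(self) -> float:
        return math.prod(self.dim_means)

    def transpiration_rate(self, condition: str) -> float:
        if condition == "CC":
            return self.ctr_true_cc
        if condition == "CA":
            return self.ctr_true_ca
        raise ValidationError(f"unknown storage condition {condition!r} (use CC or CA)")

    def noiseless(self, keep_dim_sds: bool = False) -> "VarietyProfile":
        """Copy of the profile with every noise source set to zero.

        Dimension SDs are also zeroed unless ``keep_dim_sds`` is true
        (harvest lots then still show between-fruit size variation).
        """
        kwargs = dict(
            weight_rel_noise=0.0,
            loss_noise_sd=0.0,
            meas_noise_sd={p: 0.0 for p in self.meas_noise_sd} or {},
        )
        if not keep_dim_sds:
            kwargs["dim_sds"] = (0.0, 0.0, 0.0)
        return replace(self, **kwargs)

    def scaled_anchors(self, factors: Mapping[str, float]) -> "VarietyProfile":
        """Copy with whole-trajectory anchors multiplied per parameter.

        Used to emulate a harvest-period (season) shift: the entire
        trajectory of a parameter moves by a common factor, so its
        relative (alpha) trajectory is unchanged.
        """
        if self.anchors is None:
            raise ValidationError(f"{self.name}: profile has no trajectory anchors")
        new = {
            p: tuple(v * factors.get(p, 1.0) for v in vals)
            for p, vals in self.anchors.items()
        }
        return replace(self, anchors=new)


def _noise_defaults(anchors, printed):
    """Printed between-fruit SDs where available, else 5 % of day-0 anchor."""
    out = {}
    for param in PULP_PARAMS:
        if param in printed:
            out[param] = printed[param]
        else:
            out[param] = 0.05 * anchors[param][0]
    return out


# L* declines mildly as the pulp turns from milky-green to yellow-orange;
# one shared trajectory is used for all varieties (not a model input).
_LSTAR = (78.0, 75.0, 72.0, 68.0)


def default_profiles() -> dict[str, VarietyProfile]:
    """Fixture profiles for the five local varieties plus Kent.

    Caliber means/SDs, weight means/SDs and transpiration rates are the
    published per-variety values (n = 40 fruit for caliber, n = 5 for
    weight loss); ``cc_true`` defaults to mean weight divided by the
    volume of the dimension means.
    """
    specs = []

    anchors = {
        "pH": (3.20, 3.60, 4.40, 4.75),
        "TA": (2.00, 0.80, 0.13, 0.13),
        "SSC": (7.50, 10.50, 13.50, 16.30),
        "DM": (16.45, 16.60, 16.75, 16.90),
        "Hue": (99.8, 98.0, 84.0, 71.0),
        "Lstar": _LSTAR,
    }
    specs.append(
        VarietyProfile(
            name="Boukodiekhal",
            dim_means=(12.6, 10.2, 7.6),
            dim_sds=(0.9, 0.3, 0.5),
            weight_mean_g=469.7,
            weight_sd_g=44.5,
            ctr_true_cc=1.05,
            ctr_true_ca=2.35,
            anchors=anchors,
            meas_noise_sd=_noise_defaults(anchors, {"TA": 0.10, "Hue": 2.6}),
        )
    )

    anchors = {
        "pH": (2.81, 3.09, 4.80, 6.01),
        "TA": (3.24, 1.20, 0.10, 0.06),
        "SSC": (8.93, 14.50, 15.55, 15.55),
        "DM": (15.80, 15.93, 16.06, 16.20),
        "Hue": (100.3, 92.0, 83.0, 75.0),
        "Lstar": _LSTAR,
    }
    specs.append(
        VarietyProfile(
            name="Diourou",
            dim_means=(11.2, 10.8, 8.2),
            dim_sds=(0.6, 0.7, 0.7),
            weight_mean_g=442.2,
            weight_sd_g=51.2,
            ctr_true_cc=0.76,
            ctr_true_ca=1.35,
            anchors=anchors,
            meas_noise_sd=_noise_defaults(
                anchors, {"TA": 0.30, "SSC": 0.55, "Hue": 2.6}
            ),
        )
    )

    anchors = {
        "pH": (3.00, 3.40, 4.34, 4.80),
        "TA": (4.09, 1.50, 0.12, 0.11),
        "SSC": (7.50, 13.50, 14.51, 14.51),
        "DM": (15.90, 16.03, 16.16, 16.30),
        "Hue": (95.5, 89.0, 80.0, 79.0),
        "Lstar": _LSTAR,
    }
    specs.append(
        VarietyProfile(
            name="Papaye",
            dim_means=(12.5, 8.4, 7.2),
            dim_sds=(0.9, 0.4, 0.3),
            weight_mean_g=423.3,
            weight_sd_g=50.7,
            ctr_true_cc=0.52,
            ctr_true_ca=1.07,
            anchors=anchors,
            meas_noise_sd=_noise_defaults(anchors, {"TA": 0.31, "Hue": 2.6}),
        )
    )

    anchors = {
        "pH": (3.50, 4.13, 5.43, 5.60),
        "TA": (1.19, 0.50, 0.11, 0.10),
        "SSC": (9.35, 12.50, 12.50, 14.90),
        "DM": (15.27, 15.40, 15.55, 15.70),
        "Hue": (96.0, 90.0, 81.0, 78.0),
        "Lstar": _LSTAR,
    }
    specs.append(
        VarietyProfile(
            name="Sierra Léone",
            dim_means=(8.3, 8.4, 6.2),
            dim_sds=(0.6, 0.5, 1.0),
            weight_mean_g=214.4,
            weight_sd_g=31.5,
            ctr_true_cc=0.75,
            ctr_true_ca=2.22,
            anchors=anchors,
            meas_noise_sd=_noise_defaults(
                anchors, {"TA": 0.12, "SSC": 0.85, "Hue": 2.6}
            ),
        )
    )

    anchors = {
        "pH": (3.76, 3.90, 4.50, 4.90),
        "TA": (1.19, 0.60, 0.13, 0.08),
        "SSC": (7.50, 12.00, 12.00, 17.10),
        "DM": (15.30, 15.50, 15.75, 16.00),
        "Hue": (97.0, 91.0, 80.0, 70.0),
        "Lstar": _LSTAR,
    }
    specs.append(
        VarietyProfile(
            name="Sewe",
            dim_means=(5.1, 6.7, 5.2),
            dim_sds=(0.5, 0.5, 0.4),
            weight_mean_g=102.5,
            weight_sd_g=23.4,
            ctr_true_cc=0.85,
            ctr_true_ca=1.93,
            anchors=anchors,
            meas_noise_sd=_noise_defaults(anchors, {"TA": 0.12, "Hue": 2.6}),
        )
    )

    # Reference export variety: caliber and weight-loss fixtures only.
    specs.append(
        VarietyProfile(
            name="Kent",
            dim_means=(12.0, 10.0, 8.5),
            dim_sds=(0.9, 0.7, 0.6),
            weight_mean_g=600.6,
            weight_sd_g=69.2,
            ctr_true_cc=0.41,
            ctr_true_ca=0.93,
            anchors=None,
        )
    )

    return {p.name: p for p in specs}


#: The five varieties whose pulp ripening was followed.
LOCAL_VARIETIES = ("Boukodiekhal", "Diourou", "Papaye", "Sierra Léone", "Sewe")
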