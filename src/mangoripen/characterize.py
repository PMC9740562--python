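"""Per-fruit and per-variety derived quantities.

Implements the quantities the ripening analysis is built on:

* hue angle of pulp colour, ``Hue = atan2(b*, a*)`` in degrees;
* relative (alpha) values ``X_p(t) / X_p(0)`` of a pulp parameter;
* percentage weight loss ``100 * (M(0) - M(t)) / M(0)``;
* the three varietal parameters: shape coefficient ``C_f = L*l/e``,
  caliber coefficient ``C_c`` (through-origin slope of weight on the
  dimension product) and transpiration coefficient ``C_tr``
  (through-origin slope of weight-loss % on storage days);
* descriptive statistics (mean, SD, CV%) and Tukey-HSD compact letter
  displays for between-variety comparisons;
* the Codex size-code classification of fruit weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BaselineError,
    DegenerateVarianceError,
    UndefinedHueError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FruitCaliber:
    """One fruit's harvest dimensions and weight M(0)."""

    fruit_id: str
    variety: str
    weight_g: float
    L_cm: float
    l_cm: float
    e_cm: float

    def __post_init__(self):
        if min(self.L_cm, self.l_cm, self.e_cm) <= 0:
            raise ValidationError(f"{self.fruit_id}: dimensions must be > 0")
        if self.weight_g <= 0:
            raise ValidationError(f"{self.fruit_id}: weight must be > 0")

    @property
    def volume_cm3(self) -> float:
        """Equivalent polyhedral volume L * l * e."""
        return self.L_cm * self.l_cm * self.e_cm

    @property
    def c_f(self) -> float:
        return shape_coefficient(self.L_cm, self.l_cm, self.e_cm)


@dataclass(frozen=True)
class WeightSeries:
    """One fruit's storage weight trajectory M(t)."""

    fruit_id: str
    condition: str
    days: tuple[float, ...]
    weights_g: tuple[float, ...]

    def __post_init__(self):
        if len(self.days) != len(self.weights_g):
            raise ValidationError(f"{self.fruit_id}: days/weights length mismatch")
        if not self.days or self.days[0] != 0:
            raise ValidationError(f"{self.fruit_id}: series must start at day 0")
        if any(b < a for a, b in zip(self.days, self.days[1:])):
            raise ValidationError(f"{self.fruit_id}: days must be sorted")
        m0 = self.weights_g[0]
        if any(w > m0 for w in self.weights_g):
            raise ValidationError(f"{self.fruit_id}: weights exceed initial weight")

    @property
    def loss_percent(self) -> np.ndarray:
        m0 = self.weights_g[0]
        return np.array([weight_loss_percent(m0, w) for w in self.weights_g])


@dataclass(frozen=True)
class PulpMeasurement:
    """One destructive pulp assay at a storage day."""

    fruit_id: str
    day: float
    replicate: int
    pH: float
    TA: float
    SSC: float
    DM: float
    Lstar: float
    astar: float
    bstar: float
    hue_deg: float

    def __post_init__(self):
        if self.TA < 0 or self.SSC < 0:
            raise ValidationError(f"{self.fruit_id}: TA and SSC must be >= 0")
        if not 0 < self.DM < 100:
            raise ValidationError(f"{self.fruit_id}: DM must be in (0, 100)")


@dataclass(frozen=True)
class BaselineSet:
    """Per-variety harvest means X_p(0) used for the alpha transform."""

    variety: str
    x0: Mapping[str, float]
    n_fruit: int

    def __post_init__(self):
        for p, v in self.x0.items():
            if v <= 0:
                raise BaselineError(f"{self.variety}: baseline {p} must be > 0")


@dataclass(frozen=True)
class VarietalParameters:
    """The three engineered varietal variables with fit quality."""

    variety: str
    c_f: float
    c_f_sd: float
    c_c: float
    c_c_r2: float
    c_tr: float
    c_tr_r2: float


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------


def hue_angle(astar, bstar):
    """Quadrant-correct CIELAB hue angle in degrees, in (-180, 180].

    The naive one-argument arctan of b*/a* cannot produce the 97-100
    degree hue of green-mature pulp (a* < 0, b* > 0); the two-argument
    arctangent is the convention consistent with such colours.
    """
    a = np.asarray(astar, dtype=float)
    b = np.asarray(bstar, dtype=float)
    if np.any((a == 0) & (b == 0)):
        raise UndefinedHueError("hue undefined at a* = b* = 0")
    out = np.degrees(np.arctan2(b, a))
    return float(out) if out.ndim == 0 else out


def relative_value(x_t, x_0):
    """Alpha value of a pulp parameter: X_p(t) / X_p(0)."""
    x0 = np.asarray(x_0, dtype=float)
    if np.any(x0 <= 0):
        raise BaselineError("baseline X_p(0) must be > 0")
    out = np.asarray(x_t, dtype=float) / x0
    return float(out) if out.ndim == 0 else out


def weight_loss_percent(m0, mt):
    """Percent weight loss 100 * (M(0) - M(t)) / M(0), in [0, 100]."""
    if m0 <= 0:
        raise ValidationError("initial weight must be > 0")
    m0a = np.asarray(m0, dtype=float)
    mta = np.asarray(mt, dtype=float)
    if np.any(mta > m0a):
        raise ValidationError("weight gain during storage: M(t) > M(0)")
    out = (m0a - mta) / m0a * 100.0
    return float(out) if out.ndim == 0 else out


def shape_coefficient(L, l, e):
    """Shape coefficient C_f = L_max * l_max / e_max (lateral surface / thickness)."""
    if min(L, l, e) <= 0:
        raise ValidationError("dimensions must be > 0")
    return L * l / e


def size_code(weight_g: float) -> str:
    """Codex size category from fruit weight.

    A: 200-350 g, B: 351-550 g, C: 551-800 g; weights are rounded to
    whole grams first so the printed integer boundaries leave no gap.
    """
    if weight_g <= 0:
        raise ValidationError("weight must be > 0")
    w = round(weight_g)
    if 200 <= w <= 350:
        return "A"
    if 351 <= w <= 550:
        return "B"
    if 551 <= w <= 800:
        return "C"
    return "unclassified"


# ---------------------------------------------------------------------------
# Through-origin regression kernel (shared by C_c and C_tr)
# ---------------------------------------------------------------------------


def through_origin_slope(x, y) -> tuple[float, float]:
    """Least-squares slope of ``y = s * x`` and the about-zero R^2.

    ``s = sum(x*y) / sum(x^2)``; ``R^2 = 1 - RSS / sum(y^2)`` (total sum
    of squares taken about zero, matching the no-intercept model form).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValidationError("need at least two (x, y) pairs")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValidationError("all x values are zero; slope undefined")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    rss = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 if syy == 0 else 1.0 - rss / syy
    return slope, r2


def caliber_coefficient(lot: Sequence[FruitCaliber]) -> tuple[float, float]:
    """Caliber coefficient C_c: through-origin slope of weight on L*l*e."""
    if len(lot) < 2:
        raise ValidationError("need at least two fruits")
    v = [f.volume_cm3 for f in lot]
    w = [f.weight_g for f in lot]
    return through_origin_slope(v, w)


def transpiration_coefficient(series: WeightSeries | Iterable[WeightSeries]):
    """Transpiration coefficient C_tr: through-origin slope of loss % on days.

    Accepts a single fruit's series or an iterable of series (points are
    then pooled across fruits before the fit, as when a variety rate is
    estimated from n = 5 fruits).
    """
    if isinstance(series, WeightSeries):
        series = [series]
    t, loss = [], []
    for s in series:
        t.extend(s.days)
        loss.extend(s.loss_percent)
    if len(t) < 2:
        raise ValidationError("need at least two time points")
    return through_origin_slope(t, loss)


def variety_shape_coefficient(lot: Sequence[FruitCaliber]) -> tuple[float, float]:
    """Mean and SD of per-fruit C_f over a single-variety lot.

    The variety-level C_f is the mean of per-fruit ratios (not the ratio
    of mean dimensions); SD is 0 by convention for a single fruit.
    """
    if not lot:
        raise ValidationError("empty lot")
    varieties = {f.variety for f in lot}
    if len(varieties) > 1:
        raise ValidationError(f"mixed varieties in lot: {sorted(varieties)}")
    values = np.array([f.c_f for f in lot])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def varietal_parameters(
    calibers: Sequence[FruitCaliber],
    series: Sequence[WeightSeries],
) -> pd.DataFrame:
    """Estimate C_f, C_c and C_tr per variety from observed records.

    ``series`` fruit ids must appear among ``calibers`` so each weight
    series can be attributed to a variety.
    """
    variety_of = {f.fruit_id: f.variety for f in calibers}
    rows = []
    by_variety: dict[str, list[FruitCaliber]] = {}
    for f in calibers:
        by_variety.setdefault(f.variety, []).append(f)
    series_by_variety: dict[str, list[WeightSeries]] = {}
    for s in series:
        if s.fruit_id not in variety_of:
            raise ValidationError(f"weight series {s.fruit_id} has no caliber record")
        series_by_variety.setdefault(variety_of[s.fruit_id], []).append(s)
    for variety, lot in sorted(by_variety.items()):
        c_f, c_f_sd = variety_shape_coefficient(lot)
        c_c, c_c_r2 = caliber_coefficient(lot)
        if variety in series_by_variety:
            c_tr, c_tr_r2 = transpiration_coefficient(series_by_variety[variety])
        else:
            c_tr, c_tr_r2 = math.nan, math.nan
        rows.append(
            VarietalParameters(variety, c_f, c_f_sd, c_c, c_c_r2, c_tr, c_tr_r2)
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("variety")


# ---------------------------------------------------------------------------
# Descriptive statistics and group letters
# ---------------------------------------------------------------------------


def descriptive_table(
    data: pd.DataFrame, by: str, cols: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-group mean, SD and CV% of the requested columns.

    CV = 100 * SD / mean; flagged undefined (NaN) when the group mean is
    zero.  Returns a tidy frame with one row per (group, variable).
    """
    if cols is None:
        cols = [c for c in data.columns if c != by and pd.api.types.is_numeric_dtype(data[c])]
    rows = []
    for group, sub in data.groupby(by, sort=True):
        for col in cols:
            values = sub[col].dropna().to_numpy(dtype=float)
            if values.size == 0:
                raise ValidationError(f"group {group!r} has no values for {col!r}")
            mean = float(values.mean())
            sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
            cv = math.nan if mean == 0 else 100.0 * sd / abs(mean)
            rows.append(
                {by: group, "variable": col, "n": values.size,
                 "mean": mean, "sd": sd, "cv_percent": cv}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TukeyLetters:
    """Compact letter display with the underlying ANOVA and pairwise tests."""

    letters: Mapping[str, str]
    anova_f: float
    anova_p: float
    pairwise_p: pd.DataFrame = field(repr=False)


def tukey_letters(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyLetters:
    """One-way ANOVA plus Tukey-HSD compact letter display.

    Groups sharing no letter differ significantly at ``alpha``.  Letters
    are assigned in descending order of group mean by a sweep over
    maximal windows of pairwise non-significant groups; displays for
    non-interval non-significance patterns can be conservative (two
    non-significant groups separated by a significant one may not share
    a letter).
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    samples = []
    for name in names:
        arr = np.asarray(values_by_group[name], dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {name!r} needs n >= 2")
        samples.append(arr)
    if all(np.ptp(s) == 0 for s in samples):
        raise DegenerateVarianceError("zero within-group variance in every group")

    anova = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    pmat = pd.DataFrame(hsd.pvalue, index=names, columns=names)

    order = sorted(range(len(names)), key=lambda i: -float(np.mean(samples[i])))

    def nonsig(i, j):
        return pmat.iloc[order[i], order[j]] > alpha

    k = len(names)
    cliques: list[set[int]] = []
    for start in range(k):
        end = start
        while end + 1 < k and all(nonsig(i, end + 1) for i in range(start, end + 1)):
            end += 1
        window = set(range(start, end + 1))
        if not any(window <= c for c in cliques):
            cliques.append(window)

    letters = {name: "" for name in names}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx)
        for pos in sorted(clique):
            letters[names[order[pos]]] += letter

    return TukeyLetters(letters, float(anova.statistic), float(anova.pvalue), pmat)


# ---------------------------------------------------------------------------
# Harvest baselines
# ---------------------------------------------------------------------------

#: Pulp parameters with a meaningful harvest baseline for the alpha form.
BASELINE_PARAMS = ("pH", "TA", "SSC", "Hue")


def harvest_baselines(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-variety harvest means X_p(0) of pH, TA, SSC and Hue.

    Computed over all day-0 rows (fruits x replicates) of a tidy
    observation table; the hue column of the table is ``hue_deg``.
    """
    day0 = observations[observations["day"] == 0]
    if day0.empty:
        raise BaselineError("no day-0 observations to compute baselines from")
    colmap = {"pH": "pH", "TA": "TA", "SSC": "SSC", "Hue": "hue_deg"}
    rows = {}
    for variety, sub in day0.groupby("variety"):
        x0 = {}
        for param, col in colmap.items():
            values = sub[col].dropna()
            if values.empty:
                raise BaselineError(f"{variety}: no day-0 {param} values")
            x0[param] = float(values.mean())
            if x0[param] <= 0:
                raise BaselineError(f"{variety}: baseline {param} <= 0")
        rows[variety] = x0
    return pd.DataFrame.from_dict(rows, orient="index")[list(colmap)]
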