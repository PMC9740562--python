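"""Multi-linear prediction of ripening storage time (R_ST).

The central object is :class:`StorageTimeModel`, an OLS model of the
storage-time response on pulp physicochemistry (pH, Hue, SSC) and,
for multi-varietal scope, the engineered varietal variables C_f, C_c
and C_tr.  ``fit()`` returns a :class:`StorageTimeResults` carrying the
coefficients, their standard errors and significance stars, and the
evaluation metrics the pipeline selects models by:

* RMSE and MRD with a degrees-of-freedom correction ``n - f`` where
  ``f`` counts coefficients including the intercept (MRD, the mean
  relative deviation, excludes day-0 observations whose relative error
  is undefined);
* a Gaussian-OLS AIC ``n ln(RSS/n) + 2 (f + 1)`` comparable only within
  one dataset.

Predictors may enter in absolute form (``X``) or relative form
(``alpha``), i.e. divided by the per-variety harvest baseline X_p(0).
The two forms fit identically well: the alpha fit equals the X fit with
rescaled columns, so intercept and R^2 coincide and coefficients map as
``beta_alpha = beta_X * X_p(0)`` within a variety.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .characterize import (
    FruitCaliber,
    WeightSeries,
    harvest_baselines,
    varietal_parameters,
)
from .errors import CollinearityError, LeakageError, ValidationError

#: Physicochemical predictors eligible for the alpha transform.
ALPHA_TRANSFORMED = ("pH", "Hue", "SSC")

#: Variety-level predictors (never alpha-transformed).
VARIETAL_PREDICTORS = ("C_f", "C_c", "C_tr")

_KNOWN_PREDICTORS = ALPHA_TRANSFORMED + VARIETAL_PREDICTORS

#: Observation-table column holding each predictor.
_SOURCE_COLUMN = {"Hue": "hue_deg"}


# ---------------------------------------------------------------------------
# Specifications and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: which predictors, in which variable form."""

    predictors: tuple[str, ...]
    variable_form: str = "X"
    scope: str = "multi-variety"
    label: str = ""

    def __post_init__(self):
        if not self.predictors:
            raise ValidationError("spec needs at least one predictor")
        unknown = [p for p in self.predictors if p not in _KNOWN_PREDICTORS]
        if unknown:
            raise ValidationError(f"unknown predictor(s): {unknown}")
        if self.variable_form not in ("X", "alpha"):
            raise ValidationError("variable_form must be 'X' or 'alpha'")
        if not self.label:
            object.__setattr__(
                self, "label", "+".join(self.predictors) + f" [{self.variable_form}]"
            )

    @property
    def f(self) -> int:
        """Coefficient count including the intercept."""
        return len(self.predictors) + 1


def candidate_specs(form: str = "X") -> list[ModelSpec]:
    """The six multi-varietal candidate models (1 = physicochemical control)."""
    base = ("pH", "Hue", "SSC")
    sets = {
        "1 (control)": base,
        "2": base + ("C_tr", "C_f", "C_c"),
        "3": base + ("C_f", "C_c"),
        "4": base + ("C_c",),
        "5": base + ("C_f",),
        "6": base + ("C_tr",),
    }
    return [
        ModelSpec(predictors=p, variable_form=form, label=label)
        for label, p in sets.items()
    ]


def rmse(observed, estimated, f: int) -> float:
    """Root mean square error with n - f degrees of freedom, in days."""
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.size != est.size:
        raise ValidationError("observed/estimated length mismatch")
    n = obs.size
    if n <= f:
        raise ValidationError(f"RMSE undefined for n={n} <= f={f}")
    return float(np.sqrt(np.sum((obs - est) ** 2) / (n - f)))


def mrd(observed, estimated, f: int) -> float:
    """Mean relative deviation with n - f degrees of freedom.

    Observations at R_ST = 0 have no defined relative error and are
    excluded, reducing n accordingly.
    """
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.size != est.size:
        raise ValidationError("observed/estimated length mismatch")
    mask = obs != 0
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("MRD undefined: all observations at R_ST = 0")
    if n <= f:
        raise ValidationError(f"MRD undefined for n={n} nonzero obs <= f={f}")
    rel = (obs[mask] - est[mask]) / obs[mask]
    return float(np.sqrt(np.sum(rel**2) / (n - f)))


def aic_from_rss(rss: float, n: int, f: int) -> float:
    """Gaussian-OLS AIC up to a dataset-wide constant; -inf when RSS = 0."""
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (f + 1)


@dataclass(frozen=True)
class FitMetrics:
    """Evaluation of one model on one dataset (calibration or validation)."""

    phase: str
    n: int
    f: int
    r2: float
    rmse: float
    mrd: float
    aic: float


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def _dedupe_fruit_days(obs: pd.DataFrame) -> pd.DataFrame:
    return obs.drop_duplicates(subset=["fruit_id", "day"])


def extract_calibers(obs: pd.DataFrame) -> list[FruitCaliber]:
    """Harvest caliber records (day-0 weight and dimensions) per fruit."""
    day0 = _dedupe_fruit_days(obs[obs["day"] == 0])
    return [
        FruitCaliber(
            fruit_id=r.fruit_id, variety=r.variety, weight_g=r.weight_g,
            L_cm=r.L_cm, l_cm=r.l_cm, e_cm=r.e_cm,
        )
        for r in day0.itertuples()
    ]


def extract_weight_series(obs: pd.DataFrame) -> list[WeightSeries]:
    """Per-fruit weight trajectories from the tidy observation table."""
    out = []
    for (fruit_id, condition), sub in _dedupe_fruit_days(obs).groupby(
        ["fruit_id", "condition"], sort=True
    ):
        sub = sub.sort_values("day")
        out.append(
            WeightSeries(
                fruit_id=fruit_id,
                condition=condition,
                days=tuple(sub["day"].astype(float)),
                weights_g=tuple(sub["weight_g"].astype(float)),
            )
        )
    return out


def prepare_model_frame(obs: pd.DataFrame) -> pd.DataFrame:
    """Attach estimated varietal variables C_f, C_c, C_tr to each row.

    The three coefficients are estimated from the table itself: C_f and
    C_c from the day-0 caliber records, C_tr from the weight series.
    """
    params = varietal_parameters(extract_calibers(obs), extract_weight_series(obs))
    out = obs.copy()
    out["C_f"] = out["variety"].map(params["c_f"])
    out["C_c"] = out["variety"].map(params["c_c"])
    out["C_tr"] = out["variety"].map(params["c_tr"])
    return out


# ---------------------------------------------------------------------------
# Model and results
# ---------------------------------------------------------------------------


class StorageTimeModel:
    """OLS model of ripening storage time on pulp and varietal predictors.

    Parameters
    ----------
    data : DataFrame
        Tidy observations; must contain the response column and every
        predictor (``Hue`` is read from the ``hue_deg`` column of the
        observation schema when no ``Hue`` column is present).
    spec : ModelSpec
        Predictors and variable form.
    response : str
        Response column; the storage day (R_ST) by default.
    baselines : DataFrame, optional
        Per-variety harvest means X_p(0) (index = variety) for the
        alpha form; computed from the data's day-0 rows when omitted.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: ModelSpec,
        response: str = "day",
        baselines: pd.DataFrame | None = None,
    ):
        if response not in data.columns:
            raise ValidationError(f"response column {response!r} missing")
        self.spec = spec
        self.response = response
        self.data = data
        if spec.variable_form == "alpha" and baselines is None:
            baselines = harvest_baselines(data)
        self.baselines = baselines
        self._X, self._y = self._design(data)
        n, ncol = self._X.shape
        if n <= spec.f:
            raise ValidationError(f"need n > f: n={n}, f={spec.f}")
        rank = np.linalg.matrix_rank(self._X)
        if rank < ncol:
            raise CollinearityError(self._offending_columns())

    @classmethod
    def from_dataframe(cls, data, spec, **kwargs) -> "StorageTimeModel":
        return cls(data, spec, **kwargs)

    # -- design matrix ----------------------------------------------

    def _predictor_columns(self, data: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for p in self.spec.predictors:
            source = p if p in data.columns else _SOURCE_COLUMN.get(p, p)
            if source not in data.columns:
                raise ValidationError(f"predictor column {p!r} missing from data")
            values = data[source].astype(float)
            if self.spec.variable_form == "alpha" and p in ALPHA_TRANSFORMED:
                values = self._alpha(data, p, values)
            cols[p] = values
        return pd.DataFrame(cols, index=data.index)

    def _alpha(self, data, param, values):
        if self.baselines is None:
            raise ValidationError("alpha form requires harvest baselines")
        if len(self.baselines) == 1:
            x0 = float(self.baselines[param].iloc[0])
            return values / x0
        if "variety" not in data.columns:
            raise ValidationError("multi-variety alpha form needs a variety column")
        x0 = data["variety"].map(self.baselines[param]).astype(float)
        if x0.isna().any():
            missing = sorted(set(data.loc[x0.isna(), "variety"]))
            raise ValidationError(f"no baseline for variety {missing}")
        return values / x0

    def _design(self, data):
        frame = self._predictor_columns(data).dropna()
        y = data.loc[frame.index, self.response].astype(float)
        keep = y.notna()
        frame, y = frame[keep], y[keep]
        X = np.column_stack([np.ones(len(frame)), frame.to_numpy(dtype=float)])
        return X, y.to_numpy(dtype=float)

    def _offending_columns(self):
        names = ("Intercept",) + self.spec.predictors
        full_rank = np.linalg.matrix_rank(self._X)
        offending = []
        for j in range(1, self._X.shape[1]):
            reduced = np.delete(self._X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == full_rank:
                offending.append(names[j])
        return offending or list(names[1:])

    # -- fitting -----------------------------------------------------

    def fit(self) -> "StorageTimeResults":
        """Exact least-squares solution via orthogonal decomposition."""
        X, y = self._X, self._y
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        n, ncol = X.shape
        df_resid = n - ncol
        sigma2 = rss / df_resid if df_resid > 0 else math.nan
        xtx_inv = np.linalg.pinv(X.T @ X)
        bse = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, beta / bse, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
        names = ["Intercept", *self.spec.predictors]
        return StorageTimeResults(
            model=self,
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            nobs=n,
            f=ncol,
            rss=rss,
            tss=tss,
            fittedvalues=fitted,
            resid=resid,
            observed=y,
        )


def _stars(p: float) -> str:
    if p < 1e-4:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class StorageTimeResults:
    """Fitted coefficients, uncertainties and diagnostics."""

    model: StorageTimeModel
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    nobs: int
    f: int
    rss: float
    tss: float
    fittedvalues: np.ndarray = field(repr=False)
    resid: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def intercept(self) -> float:
        return float(self.params["Intercept"])

    @property
    def coefficients(self) -> pd.Series:
        return self.params.drop("Intercept")

    @property
    def rsquared(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else math.nan

    def stars(self) -> pd.Series:
        return self.pvalues.map(_stars)

    def rmse(self) -> float:
        return rmse(self.observed, self.fittedvalues, self.f)

    def mrd(self) -> float:
        return mrd(self.observed, self.fittedvalues, self.f)

    def aic(self) -> float:
        return aic_from_rss(self.rss, self.nobs, self.f)

    # -- prediction --------------------------------------------------

    def predict(
        self, data: pd.DataFrame, baselines: pd.DataFrame | None = None
    ) -> np.ndarray:
        """Linear prediction on new data.

        For alpha-form models the transform uses ``baselines`` when
        given (e.g. the validation campaign's own harvest means), else
        the baselines stored at fit time.
        """
        model = self.model
        if baselines is not None:
            model = StorageTimeModel.__new__(StorageTimeModel)
            model.__dict__.update(self.model.__dict__)
            model.baselines = baselines
        frame = model._predictor_columns(data)
        X = np.column_stack([np.ones(len(frame)), frame.to_numpy(dtype=float)])
        return X @ self.params.to_numpy()

    def metrics(
        self,
        phase: str = "calibration",
        data: pd.DataFrame | None = None,
        baselines: pd.DataFrame | None = None,
        response: str | None = None,
    ) -> FitMetrics:
        """Metrics on the training data or on a held-out dataset.

        Held-out R^2 is computed about the held-out response mean and
        may be negative.
        """
        if data is None:
            obs, est = self.observed, self.fittedvalues
        else:
            response = response or self.model.response
            est = self.predict(data, baselines=baselines)
            obs = data[response].astype(float).to_numpy()
        rss = float(np.sum((obs - est) ** 2))
        tss = float(np.sum((obs - np.mean(obs)) ** 2))
        return FitMetrics(
            phase=phase,
            n=len(obs),
            f=self.f,
            r2=1.0 - rss / tss if tss > 0 else math.nan,
            rmse=rmse(obs, est, self.f),
            mrd=mrd(obs, est, self.f),
            aic=aic_from_rss(rss, len(obs), self.f),
        )

    # -- presentation ------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Storage-time prediction model [{self.spec.label}]",
            f"form: {self.spec.variable_form}   n = {self.nobs}   "
            f"f = {self.f}   R2 = {self.rsquared:.4f}",
            f"RMSE = {self.rmse():.3f} d   MRD = {self.mrd():.3f}   "
            f"AIC = {self.aic():.1f}",
            "",
            f"{'term':<12}{'coef':>12}{'se':>10}{'t':>9}{'p':>11}  sig",
        ]
        stars = self.stars()
        for name in self.params.index:
            lines.append(
                f"{name:<12}{self.params[name]:>12.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>9.2f}{self.pvalues[name]:>11.2e}  "
                f"{stars[name]}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        baselines = self.model.baselines
        return {
            "label": self.spec.label,
            "form": self.spec.variable_form,
            "scope": self.spec.scope,
            "response": self.model.response,
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "baselines": None
            if baselines is None
            else {v: {p: float(baselines.loc[v, p]) for p in baselines.columns}
                  for v in baselines.index},
            "n": int(self.nobs),
            "f": int(self.f),
            "metrics": {
                "r2": self.rsquared,
                "rmse": self.rmse(),
                "mrd": self.mrd(),
                "aic": self.aic(),
            },
        }


# ---------------------------------------------------------------------------
# Protocol operations
# ---------------------------------------------------------------------------


def fit_mlr(
    data: pd.DataFrame, spec: ModelSpec, response: str = "day", **kwargs
) -> StorageTimeResults:
    """Fit one candidate model (thin functional wrapper over the class)."""
    return StorageTimeModel(data, spec, response=response, **kwargs).fit()


def residual_normality(results: StorageTimeResults) -> tuple[float, float]:
    """Shapiro-Wilk test of the residuals.

    Logs a warning (does not abort) when p <= 0.05, since the modelling
    protocol only gates on residual normality informally.
    """
    resid = np.asarray(results.resid)
    if resid.size < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3 residuals")
    if np.ptp(resid) == 0:
        raise ValidationError("constant residuals: normality test undefined")
    stat, p = stats.shapiro(resid)
    if p <= 0.05:
        warnings.warn(
            f"residuals depart from normality (Shapiro-Wilk p = {p:.3g})",
            stacklevel=2,
        )
    return float(stat), float(p)


def ancova_screen(
    data: pd.DataFrame,
    responses: Sequence[str] = ("pH", "SSC", "Hue", "TA"),
) -> pd.DataFrame:
    """Screen variety, storage-time and interaction effects per response.

    Fits ``response ~ C(variety) * day`` by OLS and reports type-II
    F-tests for each term; terms with a single factor level are dropped
    with a notice row.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    n_var = data["variety"].nunique()
    n_day = data["day"].nunique()
    for resp in responses:
        col = resp if resp in data.columns else _SOURCE_COLUMN.get(resp, resp)
        if col not in data.columns:
            raise ValidationError(f"response column for {resp!r} missing")
        sub = data[[col, "variety", "day"]].dropna().rename(columns={col: "y"})
        terms = []
        if n_var > 1:
            terms.append("C(variety)")
        else:
            rows.append({"response": resp, "term": "variety", "F": math.nan,
                         "df": 0, "p": math.nan, "note": "single level, dropped"})
        if n_day > 1:
            terms.append("day")
        else:
            rows.append({"response": resp, "term": "day", "F": math.nan,
                         "df": 0, "p": math.nan, "note": "single level, dropped"})
        if len(terms) == 2:
            terms.append("C(variety):day")
        if not terms:
            continue
        fit = smf.ols("y ~ " + " + ".join(terms), data=sub).fit()
        table = anova_lm(fit, typ=2)
        rename = {"C(variety)": "variety", "day": "storage time",
                  "C(variety):day": "variety x time"}
        for term, r in table.iterrows():
            if term == "Residual":
                continue
            rows.append({"response": resp, "term": rename.get(term, term),
                         "F": float(r["F"]), "df": int(r["df"]),
                         "p": float(r["PR(>F)"]), "note": ""})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelComparison:
    """Ranked comparison of candidate models on one calibration dataset."""

    table: pd.DataFrame
    results: Mapping[str, StorageTimeResults]

    @property
    def best_label(self) -> str:
        return str(self.table.index[0])


def compare_models(
    data: pd.DataFrame,
    specs: Sequence[ModelSpec],
    validation: pd.DataFrame | None = None,
    response: str = "day",
) -> ModelComparison:
    """Fit every candidate and rank by AIC (ascending).

    Candidates whose design matrix is rank deficient (e.g. variety-level
    predictors on a single-variety dataset) are kept in the table with a
    note instead of aborting the comparison; other failures are raised
    with the candidate's label.
    """
    if len(specs) < 2:
        raise ValidationError("need at least two candidate specs")
    rows = []
    results = {}
    for spec in specs:
        try:
            res = fit_mlr(data, spec, response=response)
        except CollinearityError as err:
            rows.append({"label": spec.label,
                         "predictors": "+".join(spec.predictors),
                         "aic": math.inf, "r2": math.nan, "rmse": math.nan,
                         "mrd": math.nan,
                         "note": f"collinear: {', '.join(err.columns)}"})
            continue
        except Exception as err:  # propagate with the candidate's label
            raise type(err)(f"[{spec.label}] {err}") from err
        results[spec.label] = res
        row = {"label": spec.label, "predictors": "+".join(spec.predictors),
               "aic": res.aic(), "r2": res.rsquared, "rmse": res.rmse(),
               "mrd": res.mrd(), "note": ""}
        if validation is not None:
            val = res.metrics("validation", data=validation, response=response)
            row.update(r2_val=val.r2, rmse_val=val.rmse, mrd_val=val.mrd)
        for name, value in res.params.items():
            row[f"b_{name}"] = value
        rows.append(row)
    table = pd.DataFrame(rows).set_index("label").sort_values("aic")
    return ModelComparison(table=table, results=results)


def calibrate_validate(
    cal: pd.DataFrame,
    val: pd.DataFrame,
    spec: ModelSpec,
    response: str = "day",
) -> tuple[StorageTimeResults, FitMetrics, FitMetrics]:
    """Fit on the calibration campaign, evaluate on both campaigns.

    Fruit identifiers must be disjoint between campaigns.  Alpha-form
    validation uses the validation campaign's own harvest baselines, as
    the relative-value definition prescribes.
    """
    if val.empty:
        raise ValidationError("validation dataset is empty")
    shared = set(cal["fruit_id"]) & set(val["fruit_id"])
    if shared:
        raise LeakageError(f"fruit ids in both campaigns: {sorted(shared)[:5]}")
    res = fit_mlr(cal, spec, response=response)
    cal_metrics = res.metrics("calibration")
    val_baselines = (
        harvest_baselines(val) if spec.variable_form == "alpha" else None
    )
    val_metrics = res.metrics(
        "validation", data=val, baselines=val_baselines, response=response
    )
    return res, cal_metrics, val_metrics
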