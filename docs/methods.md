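# Methods

## Scope and model

The package predicts mango ripening storage time R_ST (days at
25 °C/86 % RH, the controlled condition "CC"; 29 °C/57 % RH is the ambient
control "CA") by multi-linear regression on pulp physicochemistry and
variety-level engineered variables. R_ST is treated as the ripeness index:
observations are tidy rows (fruit × storage day × replicate) with the day as
response. Observations are treated as independent rows; no mixed-effects
structure is modelled for the repeated pseudo-replicates, and no regularized
or nonlinear regression is offered.

Predictors:

- **pH, SSC (°Brix), Hue (degrees)** measured on blended pulp. Hue is the
  quadrant-correct two-argument arctangent of (a*, b*) in degrees; a naive
  one-argument arctan of b*/a* cannot produce the 97–100° hue of
  green-mature pulp (a* < 0) and is therefore not used.
- **α form**: each physicochemical predictor divided by its variety's
  harvest mean X_p(0), computed from day-0 rows per campaign. Only pH, Hue
  and SSC are α-transformed; varietal variables enter untransformed.
- **C_f = L_max·l_max/e_max** (dimensionless, cm-scale): variety value is
  the *mean of per-fruit ratios*, not the ratio of mean dimensions (the two
  differ by a Jensen gap of a few percent; fixture values follow the
  published per-fruit means).
- **C_c** (g/cm³): through-origin least-squares slope of fruit weight on the
  dimension product V = L·l·e, per variety.
- **C_tr** (%/day): through-origin slope of percent weight loss
  `100·(M(0)−M(t))/M(0)` on storage days.

Both through-origin fits share one kernel: slope `Σxy/Σx²`, with R² computed
about zero (`1 − RSS/Σy²`), matching the no-intercept model forms
`y = C_c·x` and `loss% = C_tr·t`. An R² convention about the mean would give
different (typically higher) values; published per-variety R² values are
therefore not comparison targets.

## Fitting and evaluation

OLS is solved exactly by orthogonal decomposition (`numpy.linalg.lstsq`);
there is no iterative tolerance. Rank-deficient designs raise a collinearity
error naming the dependent columns (the common case: variety-level
predictors on a single-variety dataset). Standard errors use
`σ² (XᵀX)⁻¹` with `σ² = RSS/(n−f)`; significance stars are two-sided
t-tests at n−f df with thresholds 0.05 / 0.01 / 10⁻⁴.

Metrics (f = number of coefficients including the intercept):

- `RMSE = √(Σ(R_ST − R̂)²/(n−f))` in days. The degrees-of-freedom
  correction follows the model-evaluation convention the pipeline was built
  around; the square root is applied (magnitudes of ~0.4–0.9 days on a
  0–12-day response at R² ≈ 0.97 are only consistent with the rooted form).
- `MRD = √(Σ((R_ST − R̂)/R_ST)²/(n−f))`, dimensionless. Day-0 observations
  have no defined relative error; they are excluded from the sum and n is
  reduced accordingly. Day-0 rows *are* kept for fitting and RMSE.
- `AIC = n·ln(RSS/n) + 2(f+1)`, the Gaussian-OLS form with the additive
  constant dropped: comparable only within one dataset; RSS = 0 maps to
  −∞. At fixed f the AIC ordering equals the RSS ordering.
- Validation R² is `1 − RSS/TSS` with TSS about the *validation* mean, and
  may be negative.

α/X duality: fitting the α form is algebraically identical to fitting the X
form with each physicochemical column divided by a constant (per variety),
so within one variety the intercept and R² coincide and coefficients map as
`β_α = β_X · X_p(0)`. This is assertable to 1e−10 and is used as an internal
consistency check. Validation of α-form models uses the validation
campaign's own harvest baselines — that is the point of the α form: a
harvest-period shift that scales a whole trajectory leaves the α trajectory
unchanged.

Protocol operations around the core fit: ANCOVA screening
(`response ~ C(variety)*day`, type-II F-tests via statsmodels) for variety,
storage-time and interaction effects; Shapiro–Wilk residual normality
(warning, not an abort, at p ≤ 0.05); calibration/validation with disjoint
fruit identifiers enforced; AIC ranking of the six multi-varietal candidate
sets {pH+Hue+SSC} ∪ {+C_tr+C_f+C_c, +C_f+C_c, +C_c, +C_f, +C_tr}.

Tukey compact letter displays: one-way ANOVA followed by Tukey HSD
(scipy's studentized-range p-values); letters are assigned in descending
order of group mean by a sweep over maximal windows of pairwise
non-significant groups. For non-interval non-significance patterns the
display can be conservative (two non-significant groups separated by a
significant one may not share a letter). Degenerate inputs (zero
within-group variance everywhere) raise instead of returning letters.

## Synthetic campaigns

The generator emulates the study design the models were developed on: two
campaigns (calibration 20 fruit/variety, validation 15), five varieties,
destructive sampling at days 0/4/8/12 with two pseudo-replicate assays per
fruit and day.

- **Harvest lots**: dimensions are truncated-positive normals at the
  published per-variety means/SDs (n = 40 caliber study); weight is
  `cc_true·L·l·e·(1+ε)` with relative noise ε (SD 0.03, consistent with the
  tight weight–volume relation of the pooled caliber data, R² ≈ 0.96).
  `cc_true` defaults to mean weight over the volume of mean dimensions
  (e.g. Boukodiekhal 469.7/(12.6·10.2·7.6) ≈ 0.481 g/cm³).
- **Weight series**: loss% = rate·t plus additive Gaussian noise (default
  SD 0.3 percentage points, consistent with the published per-variety SDs
  of ~1–2 points at day 12 over 5 fruits) with no noise at day 0, clipped
  to be non-decreasing so weights never increase.
- **Pulp trajectories**: monotone piecewise-linear interpolation between
  anchor values at days 0/4/8/12 — the simplest shape consistent with
  four-point trajectory data. Anchors reproduce the published harvest and
  ripe-stage values per variety (e.g. Diourou pH 2.81→6.01, Hue 100.3,
  SSC 8.93→15.55; Sewe SSC +42 % between days 8 and 12) and interpolate
  plausibly where only stage ranges were published. Intermediate-day SDs
  were not published; defaults use printed between-fruit SDs where
  available, else 5 % of the day-0 anchor, all overridable per profile.
- **Colour channels**: pulp data report Hue only, so a* and b* are
  back-computed from the generated hue at a fixed reference chroma
  (default 40), making the hue round-trip exact by construction.
- **Ambient condition**: CA changes only the weight-loss rate (published CA
  column); pulp chemistry trajectories are defined for CC only.
- The Kent reference profile carries caliber and weight-loss fixtures only
  (its pulp was not followed); campaigns including it emit empty pulp
  columns.

What the generator does **not** emulate: within-fruit correlation of
replicate assays beyond a shared interpolated mean, temperature dependence
beyond the two fixed conditions, season/harvest-period effects (except via
the explicit `scaled_anchors` shift used in the robustness tests),
respiration biochemistry, and any non-Gaussian measurement error. Passing
parameter-recovery tests therefore shows the estimation machinery is
correct under the stated statistical structure, not that real campaigns
satisfy that structure.

## Fixtures and numerical choices

- The published model bank stores the intra-varietal (per variety, X and α
  forms), the six multi-varietal candidates and the α-form multi-varietal
  model verbatim. Per-variety C_c values were published only as regression
  lines in a figure; the fixture derives them as mean weight ÷ product of
  mean dimensions (documented approximation; the worked example reproduces
  under it). The α-form model's +4.06 C_c coefficient is kept as published
  even though the X-form model 3 carries −18.698 (the sign flip under the α
  refit is not reconciled here).
- Size codes bin weights rounded to whole grams into A (200–350 g),
  B (351–550 g), C (551–800 g), else "unclassified" — rounding closes the
  350/351 g gap between the printed integer boundaries.
- Predicted storage days are reported both continuous and rounded to the
  nearest whole day, clamped at 0 with a warning for negative values.
- Model documents are versioned JSON; the loader rejects unknown versions.
  CSV ingest is comma-separated with period decimals; a `decimal=","`
  option accepts comma-decimal exports.
- Whether n in the evaluation metrics counts fruits or fruit×replicate rows
  is ambiguous in the source protocol; this implementation uses rows
  throughout and reports n alongside every metric.

## Problem sizes used by the shipped studies

The recovery and selection studies in `mangoripen.experiments` (also driven
by `scripts/acceptance.py` and the acceptance tests) use the study-design
sizes: 20 fruit/variety × 4 days for the noiseless refits (80 and 400 rows),
100 replicates of 5-fruit weight series for transpiration-slope recovery,
and 50 replicated five-variety campaigns (800 rows each, response generated
from the selected multi-varietal equation plus Gaussian noise of SD 0.73
days, the magnitude of that model's calibration RMSE) for the AIC
model-selection consistency study.

## Known limitations

- Published calibration/validation metrics of the real 2020 campaign are
  not reproducible without the raw data and are not targets anywhere.
- The published AIC values came from a commercial package whose additive
  constant is unknown; only AIC *orderings* are meaningful here.
- The compact-letter-display sweep is exact for mean-ordered interval
  non-significance structures, conservative otherwise.
- Extrapolation outside the calibration envelope is not guarded beyond the
  negative-prediction warning.
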