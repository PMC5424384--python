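# Methods

## The model

Movement behaviours over a 24-h day are compositional: the vector of
durations `x = (sleep, ST, LPA, MVPA)` carries only relative
information once the 1440-min total is fixed. All analysis therefore
happens in isometric log-ratio (ilr) coordinates `z = Ψᵀ ln x`, with
`Ψ` the `D×(D−1)` orthonormal, zero-sum contrast matrix of a sequential
binary partition (SBP). Each outcome `y` is modelled by ordinary least
squares as

    y = b0 + β·z + γ·covariates + ε,    ε ~ N(0, σ²),

with covariates sex (two-level factor, reference `boy`), age in years
(linear, not centred) and deprivation decile (unordered factor,
reference = lowest observed decile). Fitness models optionally add zBMI
as a covariate to separate the direct composition–fitness association
from the path through fatness.

A substitution of `t` minutes from behaviour A to B around baseline `C`
produces `C_t` (only parts A and B change; the total is preserved
exactly), and the predicted outcome difference is
`Δ = β·(ilr(C_t) − ilr(C))`. `Δ` is profile-independent (no
interactions are modelled), basis-invariant, exactly zero at `t = 0`,
baseline-dependent, and asymmetric in direction. Delta-method standard
errors and t-based 95% intervals for `Δ` are computed from the
coefficient covariance; the source analyses this package mirrors report
no intervals for substitution estimates, so these are an extension,
exact under the linear model.

## Choices where the design was open

* **SBP default.** Pivot balances in the fixed order (sleep, ST, LPA,
  MVPA): coordinate `k` contrasts part `k` against the geometric mean
  of the later parts. Since every orthonormal basis spans the same
  model space, the choice is a convention; means, fitted values, ANOVA
  tables, predictions and substitution grids are tested to agree across
  three different SBPs to 1e-8.
* **Type II tests, F primary.** Marginality (each term after all
  others) via `statsmodels.anova_lm(typ=2)`, the ilr block entering as
  a single 3-df term. The Wald chi-squared equivalent (`χ² = F·df`
  under OLS) is emitted alongside, since both conventions circulate for
  this analysis.
* **Deprivation decile as unordered factor.** A single slope would
  force a linear deprivation gradient; with 8 observed levels the
  factor term has 7 df, matching the reference analysis structure.
* **Zeros.** Log-ratios are undefined at zero. Zero durations are
  rejected by default; a multiplicative replacement (δ = 0.5 min,
  total preserved) is available by explicit opt-in and is logged
  loudly. Negative durations are always rejected at read time, with
  row numbers.
* **Variation matrix variance.** Sample variance (`ddof = 1`).
* **Covariate profile for absolute predictions.** Numeric covariates at
  the sample mean, factor dummies at observed proportions (the design-
  column-mean profile), so the prediction at the training compositional
  mean equals the mean fitted value. Substitution differences cancel
  the profile entirely.
* **Generality.** Nothing is hard-coded to D = 4; all primitives work
  for D ≥ 2 parts.

## Numerical policy

Algebraic identities (closure, ilr round trips, variation ↔ log-ratio
covariance) are held to 1e-9 relative; identities that pass through a
regression fit (basis invariance of predictions, grids, ANOVA) to 1e-8.
Reallocations leave untouched parts bit-identical rather than
re-closing, so `t = 0` is exactly the baseline. Infeasible grid cells
(`t ≥` the donor's minutes) are emitted as missing values flagged
`feasible=False`, never silently clamped. Rank-deficient designs raise
an error naming the collinear columns.

## The synthetic cohort generator

`codasub.simulate` draws compositions logistic-normally: ilr
coordinates are multivariate normal around each weight-status group's
mean composition, with a covariance obtained from the target pairwise
variation matrix via the double-centering bridge
`clr cov = −½·G·T·G`, `ilr cov = Ψᵀ(clr cov)Ψ`. Outcomes follow the
linear model above. Defaults are the study conditions the package is
built around:

* group sizes 15 / 115 / 39 (underweight / normal-weight /
  overweight-obese), n = 169 total;
* group compositional means in minutes, e.g. full-sample
  (548.6, 510.3, 354.8, 26.4);
* variation-matrix targets with sleep–ST 0.030 up to ST–MVPA 0.442;
* residual sds σ ≈ 1.23 (zBMI), 6.15 (%WHtR), 3.12 (VO₂ peak, direct),
  back-derived from the reference ANOVA mean squares;
* covariates: sex ≈ 50/50, age ~ N(10.3, 0.3), deprivation deciles
  concentrated in 1–3 (85%), heights ~ N(141.2, 6.2); waist is derived
  from the generated %WHtR and height so `100·waist/height` round-trips
  exactly;
* ilr effect vectors β obtained by least squares so the model-implied
  15-min substitution differences at the full-sample mean reproduce the
  published reference grid (12 ordered pairs, 3 unknowns; residual is
  rounding noise). The fitness β is calibrated from the zBMI-adjusted
  grid and coupled to fatness through `gamma_zbmi_on_vo2 = −1.5`.
  Covariate effects γ are plausible round numbers, not calibrated.

With this calibration the substitution differences at the
*overweight/obese* baseline (≈ +1.8 zBMI for 15 min MVPA → any other
behaviour) are genuine out-of-calibration predictions of the shared
model at a different baseline, which the acceptance script recomputes
by simulation and fitting.

What the generator does **not** emulate: measurement error and
day-to-day variability of accelerometry, non-normal tails or outliers,
any direct dependence of the weight-status label on the generated zBMI
(labels follow the generating group only), within-group covariance
shrinkage (all groups share the full-sample dispersion target, so the
pooled mixture is slightly over-dispersed relative to the target — the
moment-recovery check therefore samples a single population), or
missing data. Passing tests demonstrate the statistical machinery is
correct under its own assumptions, not that those assumptions hold in
any particular field dataset.

## Problem sizes

The default test run uses cohorts of n = 169; calibration checks use
500 replicates (coverage of the ilr coefficients and type-I error of
the marginality test), the generator's law-of-large-numbers check uses
n = 10⁵, and the acceptance script averages fitted substitution
differences over 40 replicate cohorts and runs 200 calibration
replicates — sizes at which Monte-Carlo error is several times smaller
than the bands being checked, while the whole suite runs in well under
a minute.

## Known limitations

* Cross-sectional predictions: a substitution difference contrasts
  *people* with different compositions, not a within-person change.
* Complete-case fitting per outcome model (dropped rows are counted and
  logged); no imputation.
* Strictly pairwise reallocation; no proportional or one-to-many
  schemes.
* The diagnostics report flags assumption violations at fixed
  thresholds (p < 0.01 for RESET/Jarque-Bera/Breusch-Pagan,
  Bonferroni-corrected p < 0.05 for outliers, leverage > 3p/n
  reported); it does not attempt remediation.
* Exact reproduction of the reference tables requires the original
  deposited participant spreadsheet, which is not distributed with the
  package; the acceptance test activates those checks only when a user
  places it at `data/study_data.xlsx`.
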