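# Methods

## Instrument scoring

**CLDQ-NASH.** 36 items on a 1–7 Likert scale, grouped into six domains
(abdominal, activity/energy, emotional, fatigue, systemic, worry). Each
domain score is the arithmetic mean of its items; the total is the mean
of the six domain scores. The item→domain assignment is a configuration
of the scorer: the bundled default (5/7/8/7/4/5 items per domain, in
column order) is sourced from the published instrument definition and
can be replaced by any JSON map covering all 36 items exactly once.

**EQ-5D-5L.** A health state is five levels, one per dimension
(mobility, self-care, usual activities, pain/discomfort,
anxiety/depression). The index is `1 − Σ decrements(dimension, level)`
using the bundled US societal value set; level 1 carries a zero
decrement by construction and the floor is *derived* from the table
(level-5 decrements sum to 1.573, so the all-5s state scores exactly
−0.573). The bundled set self-validates this at load; a corrupted table
refuses to score.

**Missing data.** Strict complete case per instrument: any missing CLDQ
item or EQ-5D dimension removes the record from scoring and fitting,
with per-instrument exclusion counts reported. No imputation.

## Candidate model space

All candidates share one contract: fit on training rows, predict the
EQ-5D index for unseen rows, never touching held-out outcomes.

- **Constant benchmark** — predicts the training mean.
- **OLS** and **GLMs** (gaussian, inverse-gaussian, gamma errors ×
  identity, log, power links). The power grid is −5 … 5 in steps of 0.1:
  101 nominal values, 100 usable after excluding p = 0, whose limit is
  the log link already in the grid; both counts are surfaced so the
  enumeration is auditable. For non-unit powers the working mean is
  floored at 1e−10 inside IRLS (μᵖ is undefined at μ ≤ 0); p = 1
  bypasses the clip and reproduces OLS to machine-level agreement.
  Gamma and inverse-gaussian likelihoods require y > 0, so a training
  fold containing index values ≤ 0 yields a *flagged* fit — excluded
  from ranking with its reason logged — rather than silently altered
  data.
- **Fractional logit/probit** — Bernoulli quasi-likelihood on the index
  affinely rescaled to [0, 1] (boundary values are legitimate); robust
  (HC0) covariance. Predictions are inverse-rescaled.
- **Local-linear regression** — product-kernel smoother with a
  Silverman rule-of-thumb bandwidth (configurable scale).
- **CART / random forest** — fixed, documented hyper-parameters (leaf
  sizes 10 / 5, 200 trees), seeded; no tuning, since selection is by CV
  RMSE across families, not within them.
- **Point-mass mixture** — two-part model: logistic regression for
  P(index = 1), plus an EM-fitted mixture of Gaussian linear regressions
  on the interior of the rescaled scale (default 2 components, 5 seeded
  restarts). The expected value combines both parts; the linear interior
  mean is clipped to [0, 1] to honour the bounded contract.
- **ALDVMM** — mixture of Gaussian linear regressions on the natural
  index scale with each component censored above at 1 and below at the
  floor (floor mass on by default; switchable). Constant mixing
  weights; maximum likelihood by L-BFGS with the analytic gradient and
  20 seeded restarts; label switching resolved by ordering components by
  fitted mean. Expected values integrate the censored components and so
  respect the bounds by construction.

**Covariates.** The CLDQ-NASH only: the total score or the six domain
scores, each optionally expanded by linear splines (2–4 knots, equally
spaced over the observed training range) or restricted cubic splines
(3–5 knots at Harrell's default quantiles: 10/50/90, 5/35/65/95,
5/27.5/50/72.5/95 percent). One spline spec applies to every covariate
of a model, keeping the grid finite and symmetric. Knots are placed on
**training folds only** during cross-validation (leakage-safe) and
stored with the fit so application reuses them bit-identically; placing
them on the full sample is possible by passing precomputed knots.

**Grid size.** Spline expansion is applied to regression-type families
but not to CART/forest/local-linear, where a monotone basis expansion is
inert or meaningless; the full default grid therefore enumerates to
4,361 models (printed with its per-family factorisation by
`describe_grid`). Published sweeps of this design report counts near two
thousand; the exact composition behind such counts is generally not
recoverable, so the package reports its own enumeration rather than
forcing a number.

## Cross-validation and ranking

Tenfold CV with balanced random folds (sizes differ by at most one;
reproducible from `(n, k, seed)`; 347 observations split 7×35 + 3×34).
Each fold is predicted by a model trained on the other nine; accuracy is
computed on the combined held-out predictions, so every observation is
predicted exactly once out of sample. Unbounded-family predictions are
clipped to [floor, 1] *at evaluation time only*, with clip counts
reported.

The panel reports RMSE overall; within three equal-width thirds of the
feasible range (cuts at −0.0487 and 0.4757, i.e. −0.049 / 0.476 at
printed precision), with membership by the **observed** index and
half-open intervals closed at 1; and within obese / non-obese and T2D /
non-T2D subgroups — always the same predictions stratified, never
refitted per stratum. Ranking is ascending by overall RMSE, ties broken
by fewer estimated parameters then a lexicographic spec key, so it is
invariant to evaluation order. Flagged (non-convergent or infeasible)
fits are listed separately with reasons; the audit trail matters in a
multi-thousand-model sweep.

MAE is not used for selection; the single criterion is lowest CV RMSE.

## Synthetic cohorts

One latent health factor `h ~ N(0, 1)` plus negative shifts for the
obese (−0.35 SD, prevalence 0.72) and T2D (−0.35 SD, prevalence 0.56)
subgroups drives both instruments: each CLDQ item discretises
`0.75·h + noise` into 7 levels; each EQ-5D dimension discretises
`−0.70·h + noise` into 5 levels, with the dimension noise inflated by
×1.25 per comorbidity flag — this extra outcome variability, not a mean
shift alone, is what makes the mapping genuinely harder in those
subgroups. BMI is drawn consistently with the obesity flag (≥ 30 kg/m²).

Thresholds are calibrated semi-analytically: conditional on `h`,
item-level moments are exact normal-CDF expressions, integrated over the
four-subgroup mixture by 48-node Gauss–Hermite quadrature; a 2-parameter
affine transform of equal-probability cuts is solved so the CLDQ total
hits mean 5.4 / SD 1.2, and the EQ-5D top cut is solved by monotone
root-finding so P(all dimensions at level 1) = 0.39. Unreachable targets
raise with the binding constraint named (e.g. the item-noise floor
bounds the attainable total-score SD). Everything is deterministic given
`(n, seed, params)`.

**What the generator does not emulate:** fibrosis-stage structure,
item-level heterogeneity (all items share one loading), correlation
between the obesity and T2D flags, and any instrument non-overlap beyond
independent ordinal noise. Passing tests on these cohorts show the
pipeline's mechanics and qualitative behaviour, not the numeric
performance to expect on real survey data; in particular the published
RMSE levels of the motivating study (benchmark 0.1980; best models
≈ 0.145) belong to its proprietary cohort and are quoted here as context
only.

The free choices (loadings, shift magnitudes, severity-threshold
offsets 0.9/1.7/2.4 above the calibrated top cut) were set once to what
a realistic outpatient NASH cohort looks like — mean index ≈ 0.87,
instrument correlation ≈ 0.7, subgroup contrasts in the published
direction — and are all exposed on `CohortParams`.

## Numerical choices

- Rescaling is the exact affine bijection `(y − floor)/(1 − floor)`;
  boundary values are kept (no epsilon-squeezing) because the bounded
  families accommodate them.
- Restricted cubic bases are normalised by the squared knot span
  (coefficients on comparable scales); the basis is linear beyond the
  boundary knots and twice continuously differentiable.
- Mixture EM stops on a 1e−8 log-likelihood increment with σ floored at
  1e−6; degenerate restarts (empty components) are discarded and the
  best finite restart wins; all-restart failure flags the fit.
- RMSE of an empty stratum is reported as undefined (NaN), never 0.
- Coefficient tables serialise full-precision floats; export → apply
  round-trips predictions to 1e−12. Nonparametric fits (trees, forest,
  kernel) have no coefficient representation and refuse export.

## Known limitations

- Only the US 5L value set is bundled; no 3L, no EQ-VAS, no other
  countries' tariffs.
- ALDVMM mixing weights are covariate-independent; multinomial-logit
  membership is a possible extension.
- The local-linear smoother and forest are ranked but cannot be
  published as coefficient tables — by design, since a cross-walk meant
  for reuse must be re-applicable from a printed table.
- Standard errors for the mixture families come from the observed
  information (numerical Hessian), adequate at the sample sizes used in
  the recovery checks but not a substitute for bootstrap inference on
  small cohorts.
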