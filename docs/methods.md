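# Methods

This note documents the statistical models, the synthetic-data design, and
the numerical conventions used throughout `physpref`.

## Study design being modelled

The reference data are a single-visit, cross-sectional survey of N = 324
adult neurosurgical outpatients. For each of five clinical scenarios
(consultation, examination, minor intervention, major operation, disclosure
of bad news) a respondent reports either *no preference* or a preference for
a *female* or *male* physician. Two outcomes per scenario follow:

1. **Any preference** — response ∈ {female, male}.
2. **Direction** — among preferrers, female vs male.

Covariates are patient gender, age group, disease category, education,
religion, relationship status, GP status, immigration background, visit
history, and four symptom-context flags (limits daily activities, worrying,
painful, embarrassing). Two items (gender of the last physician; whether
advice might have differed with another gender) are asked only of return
visitors: for first-time attendees they are **structurally inapplicable** —
a skip rule, not missingness, and never imputed.

## Missing data

- Covariate item nonresponse is sparse (0.0–1.3% in the reference survey)
  and is handled by **mode imputation** before modelling. Ties break by
  codebook category order (first listed wins) — deterministic and
  documented. Imputation is idempotent.
- Declared "no response" levels (education, religion, immigration) stay
  distinct rows in descriptive tables but are treated as missing (hence
  mode-imputed) when the variable enters a regression.
- Scenario preference responses are never imputed; a missing response
  reduces that scenario's valid denominator.
- On disk, missing cells are the sentinel `NA` (the reader also accepts
  empty cells); inapplicable cells carry the literal token `inapplicable`.

## Descriptive summaries

Per scenario: `n_valid`, `n_any`, `n_female_dir`, prevalence
`100·n_any/n_valid`, and direction `100·n_female_dir/n_any`. Percentages are
printed to one decimal with ties rounded **away from zero** (59/116 →
50.9%), matching the survey-report convention; Python's default banker's
rounding would disagree on exact halves. Wilson score 95% intervals
accompany every proportion — chosen for small-count stability; the reference
report printed no intervals for these quantities, so the bounds are
supplementary output only. Gender-diverse respondents are included in
descriptive output and prevalence (they are respondents) but excluded from
regression modelling because the reference cohort contained a single such
respondent.

## Logistic models with HC3-robust Wald inference

Each scenario gets a prespecified multivariable logistic model for any
preference; a secondary model among preferrers uses the same predictor
matrix for the female-vs-male direction. The core predictor set is patient
gender, age group, disease category, the four symptom flags, first-visit
status, prior specific-gender request, and immigration background;
categorical predictors are dummy-coded against fixed references (female,
age 20–39, disease "other"). An *expanded* option adds education, religion,
relationship status, and GP status.

Fitting is maximum likelihood via IRLS (statsmodels GLM; log-likelihood
tolerance 1e-8, at most 100 iterations). The reported covariance is the
**HC3 sandwich** at the MLE:

- bread: inverse expected information `(X'WX)^{-1}`, `W = μ(1−μ)`;
- meat: `Σ_i u_i u_i'` with `u_i = x_i (y_i − μ_i) / (1 − h_ii)` and
  leverage `h_ii = w_i x_i'(X'WX)^{-1} x_i` from the weighted hat matrix.

This is the standard HC3 generalization to binary-outcome GLMs and is
implemented in `physpref.models.hc3_sandwich`; the test suite pins it
against R's `sandwich::vcovHC(type = "HC3")` on a frozen fixture (agreement
to ~8 significant digits). Note that statsmodels' own
`GLM.fit(cov_type="HC3")` omits the leverage adjustment for GLMs (it falls
back to the plain HC0 score sandwich), which is why the covariance is
computed here rather than delegated.

Wald inference uses the fixed normal quantile 1.959964: `OR = exp(β)`,
`CI = exp(β ± 1.96·SE)`, two-sided p from the normal reference. No
multiple-testing adjustment is applied (the reference analysis reported
unadjusted p values). **Separation** is reported, never repaired: a fit with
any fitted probability within 1e-8 of 0/1 or any |coefficient| > 15 is
returned flagged with no inference values. Small-sample behaviour worth
knowing: HC3 is *conservative* at high-leverage sparse dummies — for the
age <20 indicator (17 of 324 exposed) the simulated type-I error of the
robust Wald test is ≈0.028 rather than 0.05, while the conventional Wald
test sits near nominal. This is a property of HC3, not of the
implementation.

## Power sensitivity

The power check simulates a univariable logistic design: balanced binary
exposure (P = 0.5), unexposed outcome probability `baseline` (default 0.4,
the approximate any-preference rate), exposed probability shifted by
log(OR). For a single binary predictor the logistic MLE is the saturated
2×2 fit, so the slope equals the empirical log odds ratio and its Wald SE is
`sqrt(1/a + 1/b + 1/c + 1/d)`; this exact closed form is evaluated
vectorised across replicates (replicates with an empty cell never reject).
Power is the rejection fraction at two-sided α = 0.05; a Monte Carlo
standard error accompanies each estimate. At n = 324 this design puts the
~80% power point near OR ≈ 1.8; because the reference report did not state
its power method, the package documents these assumptions instead of
asserting any particular printed value.

## Synthetic cohort generator

Defaults are calibrated to the published margins and are **not tuning
knobs**:

- covariate marginals = published valid-percentage vectors (n = 324; gender
  161/159/1 female/male/diverse; first visits 119/324, …);
- scenario intercepts = logits of the published any-preference prevalences
  (35.8, 42.3, 48.1, 42.9, 32.7%), so the default generator is the *null*
  model whose marginal prevalence matches the survey;
- direction probabilities = published female shares among preferrers
  (50.9, 49.6, 50.0, 48.2, 53.8%), drawn independently of covariates by
  default (the reference directional regressions found no significant
  effects); directional effects are configurable for power experiments;
- missingness rates = published item-nonresponse counts (gender 3/324, age
  4/324, disease 2/324), applied as independent masking after outcome
  generation.

Known simplifications, stated as such: covariates are drawn independently
(only marginals were published; a joint-sampler hook exists but ships
unused); the five scenario outcomes are independent across scenarios
(cross-scenario concordance was not reported); relationship status, GP
status, the last physician's gender, and the counterfactual-advice item have
no published margins and use uniform placeholder splits. Consequently,
passing tests demonstrate correct *mechanics and calibration to the printed
margins*, not recovery of the real joint distribution of respondents.

A deterministic exact-count fixture (`cohort_from_scenario_counts`) builds a
synthetic stand-in cohort whose per-scenario counts equal the published ones
exactly (covariates drawn from a hard-wired seed so every stratum is
populated without collinearity); it backs the summary-table reproduction
tests.

## Fulfilment model

With `p0` the female-direction share among preferrers and `f` the female
staffing share, expected fulfilment among preferrers is
`p0·f + (1−p0)·(1−f)` — affine in `f` with slope `2·p0 − 1`, symmetric under
`(p0, f) → (1−p0, 1−f)`, and exactly 0.5 at `f = 0.5` regardless of `p0`.
The Monte Carlo verifier simulates clinic sessions of 10,000 patients: each
patient is independently a preferrer with the scenario prevalence, each
preferrer requests a female physician with probability `p0`, and matching
succeeds with probability `f` (female request) or `1−f` (male request) —
the infinite-capacity assumption (matching depends only on gender mix; no
queueing or slot exhaustion). The outcome is matched preferrers / preferrers;
a session that draws zero preferrers has no defined outcome and is returned
flagged, not as 0. Physician gender is binary in this model. Prevalence only
scales the preferrer count, so fulfilment is independent of it in
expectation. Grid runs derive one seed per (scenario, f) cell from the base
seed via `SeedSequence`, so any cell can be regenerated alone.

A coding subtlety in the reference report: with `p0` defined as the
*female*-direction share, the bad-news scenario (p0 = 0.538) gives 47.7% at
f = 0.2, whereas the published staffing-mix table prints 52.7 — consistent
with the complementary (male-direction) coding. The implementation follows
the printed formula and definition as stated; quantitative comparisons
against the published simulated values are therefore made at f = 0.5, where
both codings coincide.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed and is bit-reproducible; the
report bundle writes a manifest with a SHA-256 hash per output table.
Default problem sizes, chosen as the package's own conventions: 10,000
patients per fulfilment session with 50 runs per grid cell (10 per curve
point); 1,000 power replicates per odds ratio; calibration checks in the
test suite use 50,000-record cohorts for law-of-large-numbers assertions,
1,000 null replicates for test calibration, and 500 replicates for coverage
and parameter recovery at the survey's n = 324.

## Limitations

- No reproduction of the reference multivariable odds ratios is possible
  without the respondent-level data; the regression machinery is instead
  validated by calibration, coverage, and parameter recovery on synthetic
  cohorts with known truth.
- No penalized (Firth) fallback for separation; separation is flagged.
- No capacity-constrained or preference-aware scheduling optimisation; the
  fulfilment model is the random-assignment baseline.
- Non-binary physician gender would need different matching rules and is out
  of scope, mirroring the binary model of the reference analysis.
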