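# Methods

## Model

All quantities live on the standardized scale. The latent world has three
true scores — socioeconomic background `TrSEB`, cognitive ability `TrCA`,
education `TrEdu` — drawn jointly multivariate normal with unit variances
and correlation matrix `rho_true`. Each trait is observed through the
classical error model

    X = rel_X · TrX + sqrt(1 − rel_X²) · ε,   ε ⟂ everything,

so `rel_X` is the true–observed correlation and `rel_X²` the classical
reliability. Throughout the package `rel` always denotes the **unsquared**
true–observed correlation; interfaces that accept classical reliability say
so explicitly (the `eqn1 --squared` flag). Independent errors imply the
attenuation product: `corr(X, Y) = rel_X · rel_Y · rho_true(X, Y)`.

Multivariate normality is a modeling choice, not an empirical claim: it
matches the standardized-regression framework being diagnosed and makes
every population quantity closed-form, so the generator can be verified
against exact oracles rather than against itself.

### The expected adjusted effect

For standardized variables, the OLS coefficient of predictor X on outcome Y
adjusting Z is `β = (r_XY − r_XZ·r_YZ)/(1 − r_XZ²)`. Applying this with
Y = `TrCA`, X = observed SEB, Z = observed CA under the error model above
(where the SEB–CA correlation is carried entirely by `TrCA`, so
`r_SEB,TrCA = r_SEB,CA / r_TrCA,CA`) gives

    E[β_SEB,TrCA·CA] = r_CA,SEB (1 − r²_TrCA,CA) / ( r_TrCA,CA (1 − r²_CA,SEB) ).

`bias.expected_adjusted_effect` returns this exactly;
`bias.population_partial_oracle` computes the same coefficient from the
full 6×6 latent/observed covariance by matrix algebra. The test suite holds
the two to 1e-10 over a 9×6 grid of latent correlations × reliabilities —
the grid is parameterized over *latent* quantities (`rho_true(SEB,CA)`,
`rel_CA`) so every grid point is a realizable world; a grid directly over
(`r_obs`, `r_true_obs`) would contain impossible combinations with implied
latent correlations above 1. The formula is strictly decreasing in
reliability and increasing in the observed correlation, which the suite
checks on a separate grid.

### Scenarios

- **residual_confounding** — `rho_true` is used as given. The calibrated
  default is a *chain*: `rho(SEB,Edu) = rho(SEB,CA)·rho(CA,Edu)`, i.e. no
  direct SEB→Edu path; any adjusted SEB effect on education in the observed
  layer is then pure measurement-error artifact.
- **discrimination** — `TrEdu` is built structurally:
  `TrEdu = a·TrCA + b·TrSEB + σ·ε` with `a` read from the
  `rho_true[CA, Edu]` entry, `b = direct_effect`, and `σ` chosen so the
  variance is exactly 1 (the spec entry `rho_true[SEB, Edu]` is ignored —
  it is implied as `b + a·rho_SC`). The construction is rejected if
  `a² + b² + 2ab·rho_SC > 1`. Parameterizing by paths rather than by a
  target correlation matrix keeps the hypothesis — a *direct* effect —
  explicit.

Note the discrimination sign prediction (a negative SEB→CA effect adjusting
education) is a collider phenomenon and holds only in part of the parameter
space (roughly, when `r_SC < r_SE·r_CE` in the observed correlations); the
adjudication rule tests the prediction, it does not guarantee a regime
where it is attainable.

### Calibration to an observed triad

`calibrate_to_observed` inverts the attenuation products for a chain world:
given observed `(r_SC, r_SD, r_CD)`, the chain forces
`rel_CA = sqrt(r_SC·r_CD / r_SD)` (≈ 0.754 for the published block
0.395/0.353/0.508), while `rel_SEB` and `rel_Edu` are free knobs (default
0.9 each) trading off against the latent correlations. The defaults give
latent `rho(SEB,CA) ≈ 0.582`, `rho(CA,Edu) ≈ 0.749`.

## Synthetic raw data

The raw survey-style generator emulates a youth-cohort triad with n = 8984
subjects by default:

- **Battery**: 12 subtests, one-factor by construction,
  `subtest_j = λ_j·F + sqrt(1−λ_j²)·noise`; default loadings evenly spaced
  on [0.6, 0.8], the range typical of a broad aptitude battery.
- **Income**: two annual incomes, jointly log-normal;
  `log Y_t = μ + σ·(λ·S + γ·shared + δ·unique_t)`. `μ, σ` solve the
  two-moment calibration so the two-year *average* has population mean 47.0
  and SD 45.4 (thousands of currency units, matching the published
  descriptives). Defaults: per-year SEB loading λ = 0.75 and year-to-year
  log correlation 0.8 — adjacent-year parental incomes are highly but not
  perfectly stable; nothing in the emulated study pins this value, so it
  was fixed once at a realistic level. A configurable fraction of each
  column is set to exact zero, MCAR (the zero mechanism in the real survey
  is unknown).
- **Degree**: ordinal 0–6 by thresholding at standard-normal quantiles of
  the cumulative category probabilities; the default probabilities are the
  published category counts 515/862/2692/598/1352/540/149 (n = 6708).
- **Missingness**: independent MCAR per instrument, with default fractions
  matching the published per-measure availability (battery 7008/8984,
  income 7302/8984, degree 6708/8984). Real missingness overlaps across
  measures and is not MCAR; consequently the default complete-case count
  (~4200) sits slightly below the published 4654.

Each instrument is driven by the **observed-score layer** of its trait
(`ca_obs`, `seb_obs`, `edu_obs`), not the true score: the `rel` degradation
represents the gap between the latent construct and the signal the
instrument taps (e.g. test-taking motivation), and the instrument adds its
own noise (subtest uniqueness, income volatility, coarsening) on top. The
composite reliabilities of the derived variables are therefore products:
with defaults, ≈ 0.9·0.96 for ability (factor-score validity 0.96),
≈ 0.9·0.79 for log-income SEB, ≈ 0.9·0.94 for the coarsened degree.

What the generator does **not** emulate: survey weights, panel attrition,
non-normal latent traits, non-random missingness, measurement
non-invariance. Tests passing on this generator show the estimators and
the adjudication logic are correct under the stated model — not that the
model describes any particular survey.

## Measurement

- Ability = regression-method (Thurstone) scores `Z R⁻¹ λ̂` on the first
  unrotated factor, fitted on complete battery rows; principal-axis
  extraction by default, maximum likelihood as an option (the two agree to
  score correlation > 0.99 on well-conditioned one-factor data). Scores are
  standardized on the scored subsample and signed to correlate positively
  with the subtest mean. A rank-deficient subtest correlation matrix falls
  back to the leading eigenvector (same first factor, defined weights);
  k = 1 degenerates to standardization with a warning. The closed-form
  validity oracle for a one-factor model is
  `corr(score, F) = sqrt(c/(1+c))`, `c = Σ λ²/(1−λ²)`.
- SEB = standardized natural log of mean two-year income; zero incomes are
  missing *before* averaging. Default policy keeps the non-zero year when
  exactly one year is zero (drops only all-zero subjects, preserving data);
  a strict `both_years` policy is available. The emulated study does not
  say which convention it used.
- Education = standardized ordinal degree treated as continuous.
- Difference score = `edu_std − ca_std`, **not** restandardized: the
  components are standardized, so the difference has natural variance
  `2 − 2ρ` and its regression on standardized SEB equals `r_SD − r_SC`
  exactly on the same sample.

## Analysis

All regressions run on one listwise complete-case sample; variables are
(re)standardized on that sample, making each adjusted effect algebraically
identical to the correlation-matrix closed form (asserted to 1e-10 in
tests). Confidence intervals: percentile bootstrap over subject resampling
(default B = 2000, seeded, restandardizing within each resample) or
analytic normal-theory intervals (`B = 0`), used where thousands of
replications are needed. Degenerate inputs — constant columns, perfectly
collinear predictor/adjuster pairs, < 10 complete cases — are rejected with
diagnostics rather than propagated.

Adjudication is a fixed CI-exclusion rule (no p-values):
*discrimination-consistent* iff the CA-on-SEB CI adjusting degree lies
entirely below 0 **and** the difference-score CI entirely above 0;
*residual-confounding-consistent* iff all six effect CIs lie entirely above
0 **and** the difference-score CI is not entirely above 0; otherwise
*inconclusive*. The decisive-contrast set and the use of 95% CI exclusion
are conventions of this package; the underlying argument is informal.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec/config dataclasses; identical specs give byte-identical CSVs.
- PSD checks tolerate eigenvalues down to −1e-10; singular latent
  correlation matrices (e.g. exact chains with unit entries) use an
  eigendecomposition square root instead of Cholesky.
- Monte-Carlo suite sizes: attenuation checks at n = 10⁶ (tolerance
  ±0.005), factor-score recovery at n = 5·10⁴ (±0.02), reversal-pattern
  reproduction at the emulated study's analysis n = 4654 over 200 seeds,
  null coverage over 500 seeds (93–97% band), bootstrap coverage at
  n = 1000 over 500 replications with B = 600. These sizes make the checks
  sharp at comfortably sub-minute cost each.

## Known limitations

- Classical, non-differential error only; correlated errors between traits
  and categorical-attenuation corrections are out of scope.
- The adjudication rule is a sign-pattern consistency check, not a causal
  identification strategy; an inconclusive verdict is the honest outcome
  whenever CIs straddle zero on decisive contrasts.
- The pairwise-deletion option affects descriptive correlations only; all
  regressions are listwise by design.
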