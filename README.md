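# resconfound

Diagnostics for **residual confounding** in covariate-adjusted regression —
the spurious adjusted association that survives when the confounder you
adjust for is measured with error — built around the triad *socioeconomic
background (SEB), cognitive ability (CA), educational attainment*.

A recurring observation in social epidemiology is that SEB predicts
educational attainment even after adjusting for measured cognitive ability,
which has been read as evidence of discrimination against people from
poorer backgrounds. `resconfound` implements the competing explanation and
the diagnostics that adjudicate between the two:

- **Bias algebra.** Under the classical error model (standardized observed
  score `CA = r·TrCA + √(1−r²)·ε`, with `r = r_TrCA,CA` the true–observed
  correlation), the expected standardized effect of observed SEB on *true*
  ability when adjusting for *measured* ability is

  ```
  E[β] = r_CA,SEB · (1 − r²_TrCA,CA) / ( r_TrCA,CA · (1 − r²_CA,SEB) )
  ```

  which vanishes only if `r_CA,SEB = 0` or `r_TrCA,CA = 1`. Otherwise
  observed SEB stays associated with everything true ability drives —
  including attainment — despite the adjustment. The package verifies this
  formula against an independent exact population-covariance oracle.
- **Synthetic data.** A seeded generator for subject-level datasets with
  exactly this latent structure: three correlated multivariate-normal true
  scores, trait-specific reliabilities, a 12-subtest one-factor ability
  battery, two skewed annual parental incomes (zeros as missing), and a
  7-category ordinal highest-degree variable — either in a pure
  residual-confounding world (no direct SEB→education path) or in a
  "discrimination" world with a structural direct path.
- **Measurement.** First-unrotated-factor ability scores
  (regression-method, principal-axis or ML), log mean two-year income as
  the SEB indicator, standardized continuous degree, and the
  education-minus-ability difference score.
- **Triad analysis.** All six directed standardized adjusted effects
  `β(outcome ~ predictor | adjuster)` with percentile-bootstrap or analytic
  CIs, residual–residual exports, the difference-score regression, and a
  sign-pattern **verdict**: a credible *negative* SEB→CA effect adjusting
  for degree plus a credibly *positive* difference-score effect is
  discrimination-consistent; all six effects credibly positive with a
  non-positive difference-score effect is residual-confounding-consistent.

## Worked example

```python
import resconfound as rc

# Published observed correlations for the triad (n = 4654)
triad = rc.CorrelationTriad(r_sc=0.395, r_sd=0.353, r_cd=0.508, n=4654)

# Latent chain world (no direct SEB->education path) whose *observed*
# correlations match the triad; identifies rel_CA = sqrt(r_sc*r_cd/r_sd)
spec = rc.calibrate_to_observed(triad, n=4654, seed=1)
data = rc.generate_latent_triad(spec).derived()

effects = rc.adjusted_effects_all(data, B=2000, seed=1)
diff = rc.difference_score_regression(data, B=2000, seed=1)
for e in effects.effects:
    print(f"{e.predictor:>4} -> {e.outcome:<4} | {e.adjuster:<4} "
          f"beta={e.beta:+.3f}  CI=({e.ci_low:+.3f}, {e.ci_high:+.3f})")
print(f"diff-score beta = {diff.beta:+.3f}  CI=({diff.ci_low:+.3f}, {diff.ci_high:+.3f})")
print(rc.adjudicate(effects, diff).verdict)
```

prints (seed 1):

```
 seb -> ca   | edu  beta=+0.228  CI=(+0.203, +0.254)
 seb -> edu  | ca   beta=+0.203  CI=(+0.177, +0.227)
  ca -> seb  | edu  beta=+0.267  CI=(+0.237, +0.298)
  ca -> edu  | seb  beta=+0.435  CI=(+0.412, +0.458)
 edu -> seb  | ca   beta=+0.234  CI=(+0.205, +0.263)
 edu -> ca   | seb  beta=+0.429  CI=(+0.405, +0.452)
diff-score beta = -0.016  CI=(-0.041, +0.011)
residual_confounding_consistent
```

Every pairwise adjusted effect is positive — including the *reversed* ones —
even though this simulated world contains **no** direct SEB→education path:
exactly the signature of residual confounding, and the same qualitative
pattern as the published study. Note the reversal logic: if a positive
SEB→education effect adjusted for ability meant discrimination against low
SEB, the equally positive SEB→ability effect adjusted for education would
have to mean discrimination against *high* SEB.

There is also a CLI for the same pipeline:

```
resconfound simulate --n 8984 --seed 1 --out raw.csv
resconfound derive raw.csv --out derived.csv
resconfound analyze derived.csv -B 2000 --seed 1 --out report.json
resconfound eqn1 --r-obs 0.395 --reliability 0.9 --squared   # -> 0.049334
resconfound run --outdir out --seed 1                        # all of the above
```

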