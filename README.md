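# ordstereo

Ordered stereotype regression for ordinal outcomes.

Ordinal scales — Likert items, symptom severities, knowledge scores — are
routinely analysed either as if the 1..q codes were continuous (ordinary
linear regression) or with the proportional odds model, which fixes the
relative spacing of the categories a priori.  The ordered stereotype model
estimates that spacing from the data.  For response `Y_i ∈ {1,…,q}` and
covariates `x_i`,

    log [ P(Y_i = k | x_i) / P(Y_i = 1 | x_i) ] = α_k + φ_k β'x_i ,   k = 2,…,q,

with the monotone score constraint `0 = φ_1 ≤ φ_2 ≤ … ≤ φ_q = 1`.  The
fitted scores `φ̂_k` tell you how far apart adjacent categories really are:
`φ̂_k = φ̂_{k+1}` means the covariates cannot distinguish the two levels (a
candidate for collapsing), and the rescaled scores `ν_k = 1 + (q−1)φ̂_k` put
the spacing back on the familiar 1..q axis.

The package provides, for biostatisticians and quantitative researchers
working with ordinal endpoints:

* constrained maximum-likelihood fitting with delta-method standard errors,
  Wald intervals, and a category-spacing report (`fit_stereotype`,
  `spacing_report`, `rescale_scores`);
* comparator fits under one contract — proportional odds, baseline-category
  logit, linear on the raw codes — with shared AIC/BIC (`fit_proportional_odds`,
  `fit_baseline_logit`, `fit_linear`, `coef_test`);
* goodness-of-fit: Pearson/deviance tests on covariate-pattern tables, a
  grouped Hosmer–Lemeshow-type statistic `S_{g1,g2}` for continuous
  covariates, and the ordinality likelihood-ratio test against the
  baseline-category logit (`pearson_deviance`, `hl_stereotype_test`,
  `ordinality_lrt`);
* a seeded simulation engine with the misspecification study cases —
  interaction-size distortion of the linear model, main-effect size/power,
  AIC model preference, robustness under a true linear model
  (`scenario_registry`, `run_rejection_experiment`, `run_aic_experiment`).

## Worked example

Fit a five-level Likert-style outcome (synthetic fixture with uneven true
spacing) and inspect the estimated category spacing:

```python
from ordstereo import (fixture_generator, fit_stereotype, fit_baseline_logit,
                       spacing_report, hl_stereotype_test, ordinality_lrt)

data, truth = fixture_generator("likert5_feedback_like", seed=0, n=500)
fit = fit_stereotype(data, seed=0)
print(fit.summary())
```

```
Model family: stereotype
Observations: 500   Parameters: 9
Log-likelihood: -713.2110   AIC: 1444.4219   BIC: 1482.3534
Converged: True

coef            estimate          SE                  95% CI
alpha2           -0.1074      0.1233       (-0.3491, 0.1344)
alpha3           -0.8845      0.1767      (-1.2309, -0.5381)
alpha4           -1.2234      0.2124      (-1.6397, -0.8070)
alpha5           -1.8755      0.2779      (-2.4203, -1.3307)
phi2              0.2687      0.0805        (0.1109, 0.4266)
phi3              0.6254      0.1105        (0.4088, 0.8420)
phi4              0.7544      0.1248        (0.5098, 0.9990)
x1                1.3739      0.1982        (0.9855, 1.7623)
x2                1.1324      0.3077        (0.5293, 1.7356)
```

The scores are estimated at (0, 0.27, 0.63, 0.75, 1) — categories 3 and 4
sit much closer together (gap 0.13) than the equal-spacing assumption
(0.25) would have it, close to the generating truth (0, 0.252, 0.748,
0.946, 1).  `spacing_report(fit)` tabulates the adjacent gaps with CI
overlap flags; here pairs 2–3 and 3–4 are flagged as not clearly
distinguishable at this sample size.

Model adequacy and the ordinality assumption:

```python
print(hl_stereotype_test(fit, data).summary())
print(ordinality_lrt(fit, fit_baseline_logit(data)).summary())
```

```
S_{2,5} grouped chi-square: statistic = 26.6160, df = 35, p-value = 0.8447
ordinality LRT (stereotype vs baseline-category logit): statistic = 0.7350, df = 3, p-value = 0.8649
```

Neither test finds lack of fit: the grouped statistic is consistent with its
chi-square reference, and the unrestricted multinomial model offers no
significant improvement over the ordinal structure.

The same workflow is available from the shell:

```bash
ordstereo fixtures --name likert5_feedback_like --seed 0 --out likert.csv
ordstereo fit likert.csv -y y --seed 0
ordstereo gof likert.csv -y y --method grouped --g1 2 --g2 5 --seed 0
ordstereo compare likert.csv -y y --seed 0
ordstereo simulate --case case1 --scenario-label "C1-S1-q3-b(1,4)" \
    --families linear,stereotype --reps 500 --seed 1
```

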