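# motionstack

**Who moves in the scanner — and can we tell in advance?** Head motion
during resting-state fMRI corrupts activity and connectivity measures even
after correction, and any systematic link between motion and variables of
interest biases group comparisons. `motionstack` implements a
machine-learning variance-partition analysis of this question: how much of
the between-subject variance in scan-average head motion is explained by
**physical** characteristics (weight, BMI, sex, age, …) versus
**psychological** state/trait measures (substance-use, impulsivity and
other self-report scales), and whether the psychological contribution is
anything more than shared variance with the physical one.

It is a library for methods researchers and neuroimaging QC analysts,
providing:

- **Motion metrics** from six rigid-body realignment parameters
  (AFNI `.1D`, SPM and FSL dialects): per-TR **ENORM**
  (L2 norm of the parameter differences) and **framewise displacement**
  (L1 norm), scan averages, and the log-transformed modelling outcome.
- **A stacked ensemble** of six base learners — elastic net, principal
  component regression, partial least squares, RBF support-vector
  regression, random forest and a conditional inference forest — tuned by
  random search with 10-fold inner cross-validation and the one-SE rule,
  combined by weights proportional to each learner's inner-CV expected
  out-of-sample R².
- **Repeated nested cross-validation**: pooled outer-fold
  R² = 1 − SS_res/SS_tot, repeated on fresh partitions (default 20), with
  95% confidence intervals (mean ± 1.96·SD of repeat-level values), plus
  stacked variable importance (per-learner VI min-max scaled to 0–100 and
  weight-averaged).
- **Residualization**: each psychological predictor replaced by its OLS
  residual on the physical block, isolating psychological variance not
  shared with physical characteristics.
- **A synthetic cohort generator** (n = 464, 15 physical + 105
  psychological predictors, ≤ 6.25% missingness per predictor, right-
  skewed motion outcome) whose single-latent-factor design reproduces the
  phenomenon under study — psychological variables predict motion only
  through their correlation with physical ones — with every generating
  parameter recorded for ground-truth recovery tests.

## Worked example

```python
from motionstack import (CohortSpec, CVPlan, generate_cohort, knn_impute,
                         make_learners, nested_cv, summarize)

cohort = generate_cohort(CohortSpec(n_subjects=200, n_physical=5,
                                    n_psych=10, n_drug_like=4, seed=2))
table = knn_impute(cohort.features, k=5)
learners = make_learners(overrides={
    "RF": {"n_trees": 150, "n_trees_tune": 30, "search_budget": 3},
    "CF": {"n_trees": 60, "n_trees_tune": 15, "search_budget": 2}})
plan = CVPlan(k_inner=10, k_outer=5, n_repeats=2, n_search=8, seed=7)
reps = nested_cv(table, cohort.outcome, plan, learners=learners,
                 subset="physical")
summary = summarize(reps)
print(summary.mean_r2, summary.ci_r2)
```

This is `examples/03_nested_cv.py`; it prints

```
true physical R2:      0.110
estimated R2:          0.079
95% CI across repeats: (0.055, 0.104)
```

The generating truth (11% of log-motion variance explainable from the
physical block) is recovered up to the estimation loss expected at
n = 200, and the CI reflects partition-to-partition variability of the
repeated nested CV. The other scripts in `examples/` walk through motion
metrics (`01`), the cohort generator and its ground-truth record (`02`),
the four-model physical/psychological/combined/residualized comparison
(`04`), and partial dependence of the stacked ensemble (`05`). A thin CLI
(`motionstack simulate|fit|report|motion-summary`) wraps the same calls
for file-based workflows.

On the full-size default cohort the pattern mirrors the analysis this
package reproduces: the physical model explains ~9–11% of variance, the
psychological model a small positive fraction, and after residualizing
psychological variables on the physical block the explained variance is
statistically indistinguishable from zero — psychological measures carry
no information about motion beyond what physical characteristics already
provide. `tests/test_acceptance.py` runs exactly these checks against the
generator's ground truth.

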