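# Methods

`motionstack` implements a variance-partition analysis of head motion
during resting-state fMRI: how much of the between-subject variance in
scan-average motion is explained by physical characteristics
(anthropometrics and demographics) versus psychological state/trait
measures, using a stacked ensemble of six regression learners evaluated by
repeated nested cross-validation. Because the motivating study's data are
not publicly deposited, a synthetic cohort generator reproduces the
statistical structure the analysis assumes; every claim the test suite
makes is therefore a claim about method behaviour under known truth, not
about any real cohort.

## Motion metrics

The input per subject is the T×6 rigid-body realignment time series (roll,
pitch, yaw in degrees; dS, dL, dP in mm — the AFNI column order; SPM/FSL
orderings are mapped on read, with radians converted to degrees). Motion
per TR is a norm of the backward first difference of that six-vector:
ENORM is the L2 norm, framewise displacement (FD) the L1 norm, so FD ≥
ENORM holds per interval and is preserved by scan averages. Degrees and
millimetres are summed without conversion, matching the AFNI convention.

The scan summary averages over the T−1 difference values; no leading zero
is padded. The alternative convention (include a zero for the first TR)
rescales the mean by (T−1)/T ≈ 0.996 at T = 240 — immaterial downstream
because the dependent variable is the natural log of mean ENORM, where the
convention enters as an additive constant. The log transform addresses the
strong right skew of scan-average motion across subjects. A zero-motion
scan has no defined log; such subjects are dropped from modelling with a
warning, never imputed.

## Synthetic cohort generator

Defaults mirror the emulated study: n = 464 subjects (≈ 37.5% male), 15
physical and 105 psychological predictors, 20 of the psychological
predictors "drug-like". One latent factor L ~ N(0,1) per subject drives
everything:

- continuous physical variables: X_j = a_j·L + N(0,1), loadings a_j drawn
  once per cohort with a hierarchical profile: two *dominant*
  (weight/BMI-like) variables draw from U[1.25, 1.45] and the remainder
  from U[0.3, 0.95]. Real anthropometric batteries show exactly this
  shape — a pair of strong motion correlates standing clearly above the
  other measures — and the separation is what makes importance-recovery
  checks well-posed: with exchangeable loadings the top order statistics
  differ by less than the correlation resolution of any estimator at
  n = 464;
- a binary sex-like variable with P(male | L) = logistic(0.3·L − 0.51);
- drug-like psychological variables: a shared substance-use factor
  D = ρ·L + √(1−ρ²)·ε with per-variable loading b = 0.7
  (`drug_cohesion`), giving pairwise correlations b² ≈ 0.49 within the
  drug block — the strong inter-correlation typical of nicotine/alcohol
  self-report instruments — and a per-variable correlation ψ = b·ρ = 0.46
  (`psych_loading`) with L;
- remaining psychological variables: independent noise;
- outcome (log-motion scale): y = −2.5 + c·L + N(0, 0.5²).

The outcome loading c is calibrated analytically so that the population R²
of the best linear function of the physical block equals `r2_physical`
(default 0.11): with g = Cov(X_phys, L) and Σ = Cov(X_phys), the projection
variance is ρ²_phys = gᵀΣ⁻¹g and c² = R²·σ²_e/(ρ²_phys − R²). The binary
variable's moments enter g and Σ via Gauss–Hermite quadrature, so no
simulation is involved; a requested R² at or above ρ²_phys raises a
configuration error. The same machinery yields the population R² of the
psychological block (≈ 0.05 at the defaults), of the combined block
(≈ 0.110), and hence of the residualized psychological block
(combined − physical ≈ 0.0004): psychological variance in motion is, by
construction, almost entirely shared with the physical block.

Two generator-design choices deserve notice:

- **Calibration targets.** The dominant loading range U[1.25, 1.45] puts
  the strongest physical predictor's population correlation with
  log-motion at ≈ 0.28, the BMI–motion benchmark the analysis is usually
  compared against; ψ and b were chosen so the psychological-block R² is
  ≈ 0.05.
- **Exact-moment draws.** The latent factor is standardized to sample mean
  0 / variance 1 and the outcome noise is orthogonalized against it
  ("fixed-score" simulation). A free draw at n = 464 would make each
  cohort's *realized* signal fluctuate around the calibrated R² with an SD
  of ≈ 0.03, which would swamp parameter-recovery tests; with exact
  moments the `truth` record is an accurate description of every cohort
  the generator emits, which is the record's purpose. Consequences for
  realism are confined to second-order alignment between L and the noise;
  predictor-side sampling noise is untouched.

Missingness is MCAR with exact counts: per predictor, a rate is drawn
uniformly on [0, 0.0625] and ⌊rate·n⌋ cells are blanked, so no predictor
ever exceeds the 6.25% cap (29 cells at n = 464). Missingness is
independent of the outcome by construction, and a permutation-style check
verifies this across seeds.

The drift-plus-spike motion model generates six-parameter series: each
parameter is a random walk with N(0, drift_sd²) increments plus transient
Laplace spikes (enter one TR, gone the next) arriving at a Poisson rate.
For a pure random walk the expected per-TR ENORM is drift_sd·E[χ₆],
E[χ₆] = √2·Γ(7/2)/Γ(3) ≈ 2.3500, which is how a target mean ENORM is
converted to a drift amplitude when motion series are attached to a
cohort (approximate once spikes are added). Cohort-level between-subject
amplitudes are lognormal, reproducing the right-skewed distribution of
scan-average motion; its natural log is near-symmetric.

## Preprocessing

Missing predictor cells are imputed once, globally, before any
cross-validation, by k-nearest neighbours (k = 5 by default; the
motivating analysis did not record k). Distances are Euclidean on z-scored
variables over the dimensions observed in common for each subject pair,
rescaled by the number of shared dimensions (the Gower-style normalisation
implemented by scikit-learn's `KNNImputer`, which backs this step); each
missing cell takes the mean of the k nearest subjects with that variable
observed; ties in distance break by subject order, which is deterministic.
The outcome is never used. Observed cells pass through bit-identically.

Global-once imputation, and residualization fitted on the full sample, sit
*outside* the cross-validation loops. Both reproduce the analysis
procedure being studied and both are mild leakage channels: held-out
subjects' predictor values influence imputed training cells and
residualization coefficients. They are retained deliberately, for
fidelity, and the audit hook in `nested_cv` fingerprints only what the CV
itself controls (no outer-validation row enters tuning, fitting or weight
computation).

Residualization replaces each psychological variable by its OLS residual
on an intercept plus all 15 physical variables and drops the physical
block; output columns are orthogonal to the physical block to ~1e−12. A
rank-deficient physical block is an error that names the collinear
columns.

## Learners and tuning

Six base learners sit behind one contract (fit / predict / hyperparameter
sampling / complexity order / variable importance): elastic net (ENET),
principal-component regression (PCR), partial least squares (PLS), RBF
support-vector regression (SVR), random forest (RF) and a conditional
inference forest (CF). ENET/PCR/PLS/SVR standardize predictors internally;
predictions return on the outcome scale.

Hyperparameter spaces (the motivating analysis recorded none):
ENET α ∈ logU[1e−4, 1], l1_ratio ∈ U[0, 1]; PCR/PLS components ∈
{1..min(30, p)} sampled log-uniformly (component counts act on a ratio
scale, and the informative settings are the small ones); SVR C ∈
logU[1e−2, 1e3], ε ∈ logU[1e−3, 1]; RF/CF mtry ∈ {√p .. p/3}, 500 trees by
default. Complexity orders for the one-SE rule: heavier penalty, fewer
components, smaller C (then wider ε-tube), smaller mtry = simpler.

Tuning is random search scored by 10-fold inner CV with fold-level
R² = 1 − SS_res/SS_tot and SE = SD/√10, followed by the one-SE rule:
the simplest setting whose mean R² is within one SE of the best; remaining
ties break on a deterministic hash. R² is used as the score throughout,
matching the outer-loop performance metric; with small validation folds
the fold-level score carries a mild negative offset (≈ −1/(n_fold−1) for a
null model) that is common to all settings and so does not distort
selection. The chosen setting is refit on the full outer-training set, and
its *stacking-weight input* — the expected out-of-sample R² — is computed
from the pooled inner-CV predictions (one held-out prediction per
outer-training row), which is free of the per-fold baseline offset and is
exactly the per-learner prediction set the stacked model combines. For the forests, the
tuning fits may use fewer trees than the final refit (`n_trees_tune` vs
`n_trees`): tree count is a variance knob, not a tuned hyperparameter, and
more trees only stabilize the refit.

Variable importance per learner: |standardized coefficients| (ENET);
|Vᵀγ|, the component loadings folded back into per-predictor standardized
coefficients (PCR, and the analogous coefficient magnitude for PLS);
out-of-bag permutation importance for RF/CF — per tree, the increase in
OOB MSE when one feature's OOB values are permuted (one shared permutation
per tree), averaged over trees, floored at 0, unscaled; and for SVR a
model-free filter: the R² of a loess fit of the outcome on each feature
alone. The loess is a tricube-weighted local quadratic (span 0.75, degree
2, both configurable), evaluated on a 25-point quantile grid and
interpolated — hand-written because the available lowess implementations
are local-linear only. RF OOB membership is reconstructed from each tree's
bootstrap seed via scikit-learn's private forest API, with a training-set
permutation fallback (warned) should that API move.

The conditional inference forest is hand-written (no Python implementation
exists): at each node the mtry-subsampled candidate feature with the
smallest association p-value is selected (Pearson-correlation test using
the asymptotic t reference — the large-sample limit of the permutation
null — Šidák-adjusted for the number of candidates), growth stops when no
candidate is significant at α = 0.05, and the cutpoint then minimizes
two-sided SSE. This separates variable selection from cutpoint search, the
defining idea of the method. An `engine="extratrees"` escape hatch
substitutes bagged extremely-randomized trees with a warning.

## Stacking, nested CV, confidence intervals

Stacking weights are each learner's expected out-of-sample R² from the
inner CV, clamped at zero and normalized; if every learner is non-positive
the weights fall back to uniform (a weighted mean with negative weights
has no interpretation). The stacked prediction is the weighted arithmetic
mean of base predictions. Stacked variable importance min-max scales each
learner's raw VI to [0, 100] per outer fold (a constant VI vector carries
no ranking information and contributes zeros), combines with the stacking
weights, then averages across outer folds within a repeat.

The outer loop (default 10 folds; the outer fold count was not recorded by
the motivating analysis and is configurable) pools held-out predictions
over the whole sample and computes R² = 1 − SS_res/SS_tot against the
observed outcome. The entire procedure repeats (default 20 times) on fresh
partitions; the reported estimate and 95% CI are the mean and mean ±
1.96·SD of the repeat-level values. (The source text calls this SD a
standard error of the repeat-level mean estimate; across 20 repeat-level
values the two readings coincide operationally, and mean ± 1.96·SD is what
is implemented.) A single repeat yields a degenerate CI and a warning.
Note the CI captures partition-to-partition variability only — not
cohort-level sampling variability.

Seeding: one master seed spawns per-repeat, per-fold and per-learner child
seeds via `numpy.random.SeedSequence`, so runs are bit-reproducible and
insensitive to evaluation order.

## The four-model report

`study_report` runs nested CV for the physical, psychological and combined
predictor sets and for the residualized psychological set, and adds the
mass-univariate comparison: per-variable Pearson r with log-motion,
Fisher-z 95% CIs, and Benjamini–Hochberg FDR-corrected p-values with the
family defined as all variables in the table. Signs are recorded for every
variable regardless of significance. Partial dependence sweeps one
predictor over a 20-point quantile grid (quantile, not uniform, to cover
skewed predictors) with all other predictors at observed values, averaging
the stacked prediction. Plots are conveniences; all tested surfaces are
tabular.

## Scaled-down test configuration

The statistical acceptance tests run the full procedure at reduced size:
5 outer folds; random-search budgets of 12/8/8/8/3/2 draws
(ENET/PCR/PLS/SVR/RF/CF); RF with 300 final / 40 tuning trees, CF with 80
final / 15 tuning trees; OOB permutation VI over at most 80 trees. Inner
CV stays 10-fold. Secondary model comparisons (psychological,
residualized) use 4 repeats where the assertion concerns means and CI
coverage; the physical-model run keeps 20 repeats because its
importance-recovery check counts per-repeat rankings. The null-calibration
check uses n = 200 and the monotonicity check n = 300 cohorts at truth
levels {0, 0.05, 0.11, 0.2}.

## Known limitations

- The generator's single-latent-factor world is far simpler than real
  phenotype batteries: no nonlinear motion relationships, no
  heteroscedasticity, no missingness beyond MCAR, no scanner or session
  effects. Passing recovery tests shows the pipeline is calibrated and
  unbiased *in this world*; it cannot certify behaviour under model
  misspecification.
- Global imputation and full-sample residualization leak modest
  information across CV folds, by design (fidelity to the emulated
  procedure). The combined effect is small at 3% average missingness but
  is not zero.
- The CF association test uses the asymptotic t approximation rather than
  exact permutation; at node sizes below ~20 the approximation is rough,
  which is mitigated by the minimum-split size (20).
- Fold-level R² on 10-fold inner CV is noisy; the one-SE rule therefore
  shrinks aggressively toward simple settings. This is a property of the
  procedure being reproduced, not a defect of the implementation.
- The 95% CIs quantify partition noise only; two cohorts of n = 464 drawn
  from the same population can legitimately yield estimates several R²
  points apart.
- On a predictor block with no true signal the stacked pooled R² is not
  centred at zero but at ≈ −0.02: every learner's expected out-of-sample
  R² is then negative, the uniform-weight fallback admits the overfit-
  prone learners' spurious prediction variance, and the SS-based pooled
  formula charges for it. Because the partition-only CI is narrow at
  large n (SD ≈ 0.006 at n = 464), such a null block is reported as a
  small but "significantly" negative R² rather than as zero; readers
  should treat estimates in the −0.03..0 band as indistinguishable from
  no signal.
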