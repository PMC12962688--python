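# Methods

## The model

`smokestatus` classifies blood-derived DNA-methylation profiles into three
self-reported smoking statuses — current, former, never — from Illumina
EPIC/EPICv2 beta values. The classifier is a symmetric 3-class multinomial
logistic regression with an L1 (LASSO) penalty on the CpG coefficients and
sex included as an unpenalized covariate. For sample *i* with beta values
*x* and sex *s* (female = 0, male = 1), the per-class log-odds are

    eta_k(x, s) = b0_k + sum_j w_kj (x_j - mu_j) + gamma_k s,   k in {current, former, never}

where *mu_j* is the training mean of CpG *j*. Posterior probabilities are
the softmax of the log-odds (computed with max-subtraction; they sum to one
by construction), and the call is the argmax — over all three classes in
3-class mode, or over {current, never} only in 2-class mode, where the
former-smoker posterior is ignored and self-reported former smokers are
excluded from evaluation. Ties break in the fixed order
current > former > never. Statuses carry a global ordinal coding
(current = 1, former = 2, never = 3) used for rank correlations against
continuous exposure measures.

**Centered parameterization.** Coefficients are stored for mean-centered
predictors. This makes the missing-data contract exact: a missing CpG is
imputed with its training mean, so its contribution to every class's
log-odds is identically zero, and a sample with *all* CpGs missing receives
the prior-plus-sex prediction. The softmax gauge (adding a constant to all
classes changes nothing) is fixed by centering the intercepts, the sex
coefficients and each CpG's coefficient row across the three classes at
serialization.

## Training pipeline

1. **Label categorization.** Questionnaire answers map to classes:
   daily/weekly smokers and quit-attempters (answers 1, 2, 4) are current
   smokers; has-quit (5) former; has-never-smoked (6) never. Occasional
   smokers (answer 3) are excluded as biologically ambiguous. Additional
   exclusions (passive smokers, inconsistent never smokers) are honored via
   an `exclude` sample-sheet column.
2. **Variance pre-filter.** Per-probe sample variance (n−1 denominator,
   missing values skipped) is computed; probes with variance strictly above
   the linear-interpolation empirical quantile (default 0.75) are retained.
   Probes with fewer than two observations are dropped with a warning.
3. **Penalized fit.** The objective is
   `(1/N) sum_n -log P_{y_n} + lambda * sum_{k,j} |w_kj|`
   with intercepts and sex unpenalized. Predictors are standardized
   internally so the penalty is comparable across CpGs; coefficients are
   back-transformed to the beta scale for storage. Standardization moments
   are computed once on the full training matrix (not re-estimated per CV
   fold) — only means and scales cross fold boundaries, a deliberate
   simplification.
4. **Penalty selection.** Geometric grid of 100 lambdas from lambda_max
   (the smallest penalty that zeroes every CpG coefficient, computed at the
   intercept+sex-only null fit) down to 0.001·lambda_max. 10-fold
   class-stratified cross-validation minimizes the total held-out
   multinomial deviance (-2 sum log P of the true class); ties break toward
   the larger (sparser) lambda. The minimum-deviance rule is used, not the
   1-SE rule.
5. **Serialization.** Versioned JSON storing only CpGs with a nonzero
   coefficient in some class, each with its three weights and training
   mean, plus intercepts, sex coefficients, lambda, the variance threshold
   and training metadata.

## Solver

The fit is proximal-gradient (FISTA) with gradient-scheme adaptive restart,
step size 1/L with `L = sigma_max([U X])^2 / 2N` (the multinomial Hessian
is bounded by I/2), soft-thresholding giving exact zeros, and convergence
declared when the KKT subgradient residual falls below tolerance
(default 1e-6). Lambda paths run warm-started with the sequential strong
rule: at each lambda only predictors whose gradient at the previous
solution exceeds `2*lambda - lambda_prev` (plus the active set) enter the
subproblem, and full KKT conditions are verified afterwards, readmitting
any violators — a pure speed optimization that leaves solutions unchanged
at the same tolerance (asserted in tests against unscreened fits and
against an independent convex-optimizer oracle using the exact
split-variable reformulation solved by L-BFGS-B). Unpenalized coordinates
have a flat gauge direction; FISTA converges to one representative and the
gauge is fixed afterwards by centering.

## Prediction with missing probes

`predict` composes harmonize → align → impute → log-odds → softmax →
assign. EPICv2 probe ids carry replicate suffixes after an underscore;
harmonization strips the suffix and collapses replicate rows by the mean of
non-missing values (idempotent; an explicit design choice, since replicate
handling for cross-platform scoring is not standardized). Alignment
reorders rows to the model CpG set, marks absent CpGs missing, drops
non-model probes and reports per-sample missing fractions; a warning is
emitted above 10% missingness, the envelope within which the robustness
protocol shows only marginal degradation.

## Synthetic cohorts

Restricted access to real training cohorts motivates a first-class
generator. Background CpG *j* draws a baseline mean m_j ~ U(0.05, 0.95);
values follow Beta(m·c, (1−m)·c) with concentration c (default 50, giving
beta-value noise with SD ≈ 0.03–0.07 — typical array-level replicate
variability). At signal CpGs, current smokers are hypomethylated by
delta·d_i with a pack-years-linked dose factor d_i in [0.5, 1.5] (mean 1);
former smokers recover exponentially with time since cessation
(`exp(-cessation_years/tau)`, tau = 10 y by default, matching the
decade-scale reversion of smoking-associated methylation); never smokers
sit at baseline. Means are clipped to [0.02, 0.98] before sampling. Sex
CpGs shift by delta_sex (0.10) in males. Cotinine is log-normal per class
(medians ≈ 150 / 4.5 / 1 ng/ml for current/former/never), pack-years
log-normal for ever-smokers, cessation time uniform on (0.5, 30) years.
Entry-level missingness at a configurable rate (default 7%); whole-probe
masking is available separately and is what the robustness protocol uses.

Defaults are 300 samples per class, 5,000 probes, 30 signal CpGs,
delta = 0.12 — sized so a fitted model is accurate but imperfect, keeping
tests sensitive to regressions while finishing a full train/evaluate cycle
in a few CPU-minutes. The generator does **not** emulate probe chemistry
(type I/II, dye bias), batch effects, cell-composition heterogeneity or
meQTL structure; passing tests therefore demonstrate correctness of the
statistical machinery, not field performance on real cohorts.

## Robustness protocol

Given a trained model and an evaluation set, `missingness_sweep` masks
`round(f·p)` whole probes uniformly at random at each fraction
f ∈ {8, 9, 10, 15, 20, 30, 50}%, on top of any missingness already in the
input, repeats this over independent iterations (default 50; the bundled
end-to-end checks use 20), classifies, and records 3-class and 2-class
overall accuracy against the unmasked baseline. Per-iteration seeds derive
deterministically from the base seed and the (fraction, iteration) cell,
so the whole sweep is bit-reproducible. Failed iterations (e.g. no model
CpG left) are recorded as NaN, never dropped silently.

## Evaluation

Metrics follow the standard confusion-matrix arithmetic: one-vs-rest
sensitivity TP/(TP+FN), specificity TN/(TN+FP), balanced accuracy their
mean, overall accuracy trace/total. Undefined metrics (empty reference
class) are reported as missing with a warning rather than coerced to 0.
The 2-class block removes self-reported former smokers before
cross-tabulating current vs never. Spearman correlations use midrank ties
with the standard large-sample two-sided p-value (via scipy); the 10 ng/ml
cotinine recency threshold is carried in reports as an annotation constant
only. Sex-stratified evaluation reuses the generic `--group-by` filter of
the CLI rather than a bespoke routine.

## Numerical and degenerate-input choices

- Beta values are validated strictly in [0, 1]; M-values are rejected.
- Missingness encodings accepted on read: empty, `NA`, `NaN`; `NA` written.
- Training requires a complete matrix — imputation is deliberately a
  prediction-time concern only, mirroring the asymmetry between a
  quality-controlled training cohort and partially missing field data.
- Constant probes cannot enter the fit (zero variance is always at or
  below the filter threshold, and standardization would divide by zero).
- Posterior normalization holds to 1e-12; softmax uses max-subtraction.
- CV requires every class in every training fold and errors otherwise.

## Known limitations

- Former smokers are intrinsically heterogeneous (cessation time, prior
  intensity); 3-class accuracy is bounded by this overlap, which the
  generator reproduces via the exponential-recovery model.
- Penalty selection, fold assignment and the solver are deterministic
  given seeds, but bit-reproducibility is only guaranteed within one
  BLAS/platform configuration.
- The variance filter's strict-inequality retention can drop marginally
  fewer than (1−q) of probes under ties.
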