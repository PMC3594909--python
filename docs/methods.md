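# Methods

`metaboclass` benchmarks four binary classifiers — a unit-vote random forest
(RF), partial-least-squares discriminant analysis (PLS-DA), regularised
linear discriminant analysis (LDA) and a linear soft-margin support-vector
machine (SVM) — on metabolomic peak-area tables, and compares their variable
rankings for putative biomarker selection. Because the clinical urine GC-MS
dataset the evaluation design emulates (65 healthy, 67 preoperative and 63
postoperative colorectal-cancer samples; 187 variables, 35 identified
metabolites) is not publicly available, all empirical behaviour is
established on synthetic tables with known ground truth.

## Synthetic data generator

Each sample's latent profile is multivariate Gaussian with unit variances
and block-diagonal equicorrelation: consecutive blocks of `block_size`
variables (default 10) share pairwise correlation `block_rho` (default
0.5), emulating co-regulated metabolite clusters. The first `n_informative`
variables carry a group-1 mean shift of `effect_size` latent standard
deviations, so `effect_size` is Cohen's d on the latent (log) scale. Shifts
alternate in sign across the informative variables: real disease signatures
contain both elevated and depleted metabolites, and the balance prevents the
class effect from being absorbed into each sample's total intensity, which
would otherwise let row normalisation inject spurious anti-effects into
every null variable at small panel sizes. Latent values are added to a
per-variable baseline drawn uniformly on [2, 6] (natural-log peak area) and
exponentiated, giving strictly positive, right-skewed intensities.

Default dimensions mirror the emulated study design (65 + 67 samples, 187
variables, 35 flagged as identified); `generate_three_group` adds a
post-treatment group (default 63 samples) whose informative shift is half
the disease shift, emulating partial metabolic normalisation after surgery.
Ground-truth informative flags are carried on the table but never consumed
by any evaluation stage — they exist solely so tests can score recovery.

What the generator does *not* emulate: missing values, retention-time
drift, batch effects, heteroscedastic technical noise, non-Gaussian latent
dependence, and any specific metabolite identities. Passing tests therefore
demonstrate correctness and calibration of the evaluation machinery under a
clean generative model, not performance on real clinical data.

## Pretreatment

The fixed chain is: normalisation of each sample row to its total intensity
(compensating extraction/injection/volume variability), mean centring, and
unit-variance scaling with the sample (n−1) standard deviation. Centring
and scaling statistics are always estimated on the training partition of a
split and replayed on held-out samples; nothing in any cross-validation
loop sees test-fold data at fit time. Zero-variance columns (possible after
permutation or subsetting) scale to all-zeros with a warning rather than
erroring.

## Classifiers

All four methods expose `fit(X, y)`, a continuous class-1 score in [0, 1],
a hard prediction (score strictly above 0.5 — ties go to class 0), and a
variable-importance ranking. Ranking compares importances *across*
variables, so it should be computed on pretreated data.

* **RF** — 200 unpruned CART trees, each grown on a bootstrap resample of
  the training set, trying `floor(sqrt(p))` randomly chosen variables per
  node, with terminal nodes of at least 2 samples. Each tree casts a unit
  vote; the score on new data is the class-1 vote fraction. On the training
  table the score is the *out-of-bag* (OOB) vote fraction — only trees whose
  bootstrap excluded the sample vote — which makes the training-set score an
  internally cross-validated quantity. With 200 trees each sample is OOB in
  about 200/e ≈ 74 trees; a sample that is never OOB raises an error
  advising more trees. Importance is the mean decrease in Gini impurity
  averaged over trees, affinely rescaled to [1, 100] (the "Gini score"); the
  implementation is a thin bagging loop over scikit-learn decision trees
  because vote semantics and bootstrap bookkeeping must be explicit.
* **PLS-DA** — scikit-learn `PLSRegression` on the 0/1 response with 2
  latent components by default (binary discrimination rarely supports more,
  and a fixed default keeps runs deterministic); internal autoscaling is
  disabled since pretreatment already scales. Scores are predictions clipped
  to [0, 1]. Importance is the conventional VIP,
  `VIP_j = sqrt(p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a)` with
  `SS_a = q_a² t_aᵀt_a`; by construction `Σ_j VIP_j² = p`. Requested
  components are capped at `min(n−1, p)` so elimination can run to one
  variable.
* **LDA** — pooled-covariance linear discriminant with diagonal loading
  (shrinkage toward a scaled identity, Ledoit–Wolf by default), required
  because plain LDA is singular when p exceeds n (187 variables against at
  most 132 samples). Importance is the absolute discriminant coefficient.
* **SVM** — linear kernel, C = 1 (a weight vector is required by RFE; the
  margin penalty is exposed as configuration). Importance is SVM-RFE:
  repeatedly refit, remove the variable with the smallest squared weight,
  one per iteration; rank is reverse elimination order.

LDA and SVM decision values are mapped to [0, 1] by a logistic of the
signed distance so all methods share ROC and thresholding machinery; the
map is monotone, so rankings and AUC are unaffected by its shape. All
importance ties break lexicographically on the variable id, which keeps
rankings reproducible across platforms.

## Evaluation

**Cross-validation.** Stratified k-fold (k = 7 and 10 in the default
schedule) with the pooled misclassified fraction as the error, and repeated
stratified holdout at fractions 0.10 / 0.15 / 0.33 with 100 repeats,
reporting mean, SD and box-plot statistics over repeats. Holdout sizes
round half up on the total and on the positive-class quota (one third of a
65 + 67 design gives 22 + 22 = 44 held-out samples). When a class is
smaller than k, stratification is impossible and folds degrade to plain
shuffled near-equal folds with a warning.

**R²/Q².** With labels y ∈ {0,1} and continuous fitted scores s,
`R² = 1 − Σ(y_i − s_i)² / Σ(y_i − ȳ)²`; Q² is the same with leave-one-out
(LOO) predictions. Scores, not thresholded classes, enter the sums —
squared deviations of hard labels degenerate into error counts. For
PLS/LDA/SVM the fitted scores are resubstitution predictions and Q² does n
exact refits (pretreatment refit per fold). For RF the fitted score is the
OOB vote fraction (the forest's score on its training data is OOB by
definition), so RF's R² is already cross-validated; its Q² defaults to the
same OOB predictions — each tree that excludes sample i is a bona fide
model trained without i, the classical forest surrogate for LOO — and an
exact n-refit LOO is available as `rf_q2="refit"` (a test verifies the two
agree to within 0.15 at n = 40). The default exists because the exact
variant costs (n+1) forest fits per evaluation, which the permutation
diagnostic multiplies by the permutation count.

**Permutation diagnostic.** Labels are randomly permuted `n_perm` times
(100 in interactive use; the Monte-Carlo suites use 20 as a problem-size
choice); each permutation is placed at x = |Pearson correlation between
permuted and actual labels| with its R²/Q², and the actual model sits at
x = 1. The regression line of each statistic joins the actual point to the
centroid of the permuted cloud (not a least-squares fit over all points —
the two-point construction is the documented definition). A classifier is
judged valid when (1) every permuted R² and Q² is below the actual values
and (2) the Q² line's vertical intercept is negative. Under a pure null the
actual model is exchangeable with the permutations, so criterion 1 fails
with probability ≈ n_perm/(n_perm+1); the test suites verify this
calibration and, under a d = 2 effect, that the forest passes both criteria.

**ROC/AUC.** Threshold sweep over the unique scores with trapezoidal AUC;
this equals the pairwise concordance probability with ties counted one
half, which the tests verify against a brute-force oracle to 1e-10. ROC
curves in the pipeline use pooled held-out scores from a 7-fold pass, so
the displayed AUC is cross-validated rather than resubstitution.

**Recursive variable elimination.** From the full table down to one
variable: re-rank the survivors with the method's own importance (refit at
every step, since removing a variable changes the remaining importances),
record the k-fold CV error (k = 7 by default; the error metric of the
variable-count curve is configurable), drop the lowest-ranked variable.
`min_variables_for_error` scans the curve for the smallest panel whose
error is strictly below a cap.

## Rank consistency and biomarker selection

The two-sample pooled-variance Student's t-test rank (ascending P, Welch
optional) is the univariate reference. Consistency between two methods is
the Pearson correlation of their integer rank vectors — a Spearman-type
statistic, used because rank lists rather than raw importances are the
compared objects. At the identified-metabolite level each ordering is
restricted to the identified subset and ranks are recomputed within it, so
both vectors remain full permutations of the same set.

The biomarker screen intersects three strict-inequality filters: t-test
P < 0.05 (raw P by default; Benjamini–Hochberg optional), VIP > 1 and
scaled Gini > 50. On synthetic data with five clear markers (d = 2.5) at
the emulated study scale (132 × 187) the intersection recovers at least
four of five in the large majority of replicates; at much smaller panel
sizes the min-max Gini scale becomes unstable because impurity importance
concentrates on whichever of several redundant discriminators trees pick
first.

## Orchestration and reproducibility

`run_pipeline` executes simulate/load → per-classifier evaluation (five CV
schemes, permutation diagnostic, ROC, optional elimination) → rankings,
consistency matrices and biomarker sets, writing tidy CSV/JSON artifacts
plus a manifest; plots are optional artifacts, never the contract. Every
stochastic stage draws a child seed from SHA-256 of the master seed and the
stage name, so schedules can be edited without perturbing other stages, and
identical config + seed reruns are byte-identical (tested at file level).

## Problem sizes used by the test and acceptance suites

Monte-Carlo conditions: null and signal calibration use n = 100 (50/50),
p = 30, blocks of 5 at ρ = 0.3, 6 informative at d = 2 (signal) or none
(null), 20 replicates, 20 label permutations per diagnostic; the biomarker
screen uses the emulated study scale 65/67 × 187 with 5 informative at
d = 2.5. These sizes are the package's own choices for routine runs; all
machinery accepts larger values.

## Known limitations

* The OOB form of RF's Q² makes R² and Q² coincide for the forest in the
  default mode; use `rf_q2="refit"` when the distinction matters.
* LDA coefficient magnitudes are a weak importance measure when p ≫ n,
  even with shrinkage; rankings for LDA should be read cautiously there.
* The logistic score map for LDA/SVM is uncalibrated; scores are ordinal,
  not probabilities.
* Only binary cases are supported; three-group designs are analysed as
  assembled pairs.
* The generator's latent-Gaussian, block-equicorrelated structure is a
  stand-in, not a claim about any real dataset's distribution.
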