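# Methods

This note documents the statistical procedures stacksurv implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's numerical
conventions and limitations.

## Survival core

All partial-likelihood computations use the **Breslow** tie convention; the
workflow's inputs are continuous follow-up times where ties are rare, and
Breslow keeps every derivative closed-form. `fit_cox` maximizes the partial
likelihood by Newton–Raphson with step-halving (the penalized
log-likelihood never decreases across iterations), declaring convergence at
max |score| < 1e-8 or 50 iterations. The covariance is the inverse observed
information. A coefficient escaping |beta| > 15 is treated as a monotone
likelihood (perfect separation): it is capped, flagged and reported with a
warning rather than an error. An optional per-covariate ridge penalty
stabilizes degenerate columns (an all-zero covariate fits to exactly 0).

Survival functions derived from raw risk scores (survival SVM, XGBoost
margins) use a Breslow baseline cumulative hazard after a univariate Cox
refit on the standardized score; the refit learns orientation and scale, so
backends whose score convention is anti-concordant with risk need no
special casing.

## Screening

Spearman Rs is computed as Pearson correlation of average ranks (ties
mid-ranked) with the two-sided t-approximation
t = Rs·sqrt((n−2)/(1−Rs²)) on n−2 df. A gene passes against the seed panel
if it passes versus **any** seed gene — the maximal-sensitivity reading,
consistent with the large pass counts the workflow expects. No
multiple-testing correction is applied in either screen (raw thresholds are
part of the procedure being reproduced; this is deliberate, not an
oversight). The univariate Cox screen runs on raw log-scale expression by
default, so hazard ratios are per unit log-expression; z-scoring is
available behind `standardize=True`. Constant genes are flagged and
skipped, never fatal.

## Spike-and-slab lasso signature

The selector places a mixture double-exponential prior on each coefficient:
spike scale s0, slab scale s1 (default 1), prior inclusion probability
theta (default 0.5 — an uninformative default; sensitivity is a config
field). EM alternates (E) the posterior slab probability p_j of each
coefficient with (M) a weighted L1-penalized Cox update with per-coefficient
scale S_j = (1−p_j)·s0 + p_j·s1, i.e. penalty rate 1/S_j, solved by
cyclic coordinate descent (coordinate-wise Newton plus soft-thresholding,
per-update step capped at 5). The outer loop stops at |Δbeta|∞ < 1e-4 or
200 iterations. At s0 = s1 the EM collapses exactly to a fixed-penalty
lasso-Cox fit — the test suite verifies this against an independent
proximal-gradient (ISTA) solver to 1e-6.

s0 is chosen on a grid (default 16 log-spaced values in [0.005, s1]) by the
Verweij–van Houwelingen cross-validated partial log-likelihood
CVPL = Σ_k [l(beta_(−k); full) − l(beta_(−k); minus fold k)], averaged over
replicates of event-stratified folds (stratification prevents event-free
folds under heavy censoring). Within each fold the grid is descended from
the weakest spike with warm starts. An empty selection is a reported
outcome, not an error.

Stepwise refinement is bidirectional AIC (−2·loglik + 2k) starting from the
full selected set, ties broken toward the smaller model; returned
coefficients are the final unpenalized fit. The risk score is the exact
linear combination Σ beta_i·Exp_i with no standardization.

The proportional-hazards check is the Grambsch–Therneau score test on
Breslow Schoenfeld residuals against the Kaplan–Meier transform
g(t) = 1 − KM(t) (identity and log transforms available): per-covariate
chi-square on 1 df using the marginal information, global chi-square
uᵀ·cov·u·d/Σ(g−ḡ)² on p df. It is advisory — reported, never auto-dropping
covariates. Null simulations in the test suite confirm a type-I error
within [0.02, 0.09] at nominal 0.05.

## Stacking

Folds are balanced, event-stratified, and required to contain at least one
event each (resampled up to 100 attempts). Fixed published signatures have
no fold dependence and are evaluated directly; refittable sub-models are
retrained K times and evaluated out-of-fold only, a discipline asserted
structurally in the tests. The meta-fit maximizes the Cox partial
likelihood of the outcome on the stacked out-of-fold columns under
w_m ∈ [0, 10M], by L-BFGS-B with the analytic score as gradient, projected
gradient tolerance 1e-6, start w = 1/M. Weights are normalized to sum to 1
by default (the published weight vectors do). The meta-model is the
**linear** Cox fit on the stacked columns — the form whose output is one
weight per sub-model; smooth per-column calibration was considered and left
out because it does not yield a single weight per sub-model. Deployment-time
linear predictors come from sub-models refit on the full training data;
out-of-fold values serve only to estimate the weights.

## Final model

Four learners sit behind one adapter contract (fit / predict_risk /
predict_survival): random survival forest and gradient boosting
(scikit-survival, native survival functions), survival SVM
(scikit-survival, Cox-calibrated) and XGBoost with the Cox objective
(Cox-calibrated margins). Step survival functions are extended as constants
outside their training domain (S = 1 before the first event). FAB is
one-hot encoded with the largest category as reference; age enters in years
untransformed.

Learner selection scores each candidate by pooled out-of-fold
time-dependent AUC at the evaluation horizons (default 1/2/3 years,
365·k days) using the first grid cell — crude performance decides the
winner, which is then tuned by K-fold (default 10) grid search maximizing
Harrell's concordance and refit on all data. Ties break toward the earlier
learner in registry order. Bootstrap internal validation resamples n with
replacement, refits, and evaluates on the out-of-bag samples (resubstitution
would be optimistic for flexible learners); replicates without usable OOB
cases/controls are skipped and counted. Default B is 1000; the test suite
and examples use 30–50 purely as a problem-size choice.

## Evaluation

Time-dependent ROC is cumulative/dynamic: cases have events by t, controls
survive beyond t. The default estimator is the nearest-neighbour
conditional KM with span 0.25·n^(−0.20) (symmetric window in marker
percentile space), which is monotone by construction and invariant to
strictly increasing marker transforms; a naive subgroup-KM variant is
available (`method="km"`) and reduces exactly to the Mann–Whitney AUC on
uncensored data. Which of the two estimators produced any given published
curve is generally unstated, so both are first-class.

The optimal cut-point maximizes the absolute standardized two-group
log-rank statistic over all admissible midpoints (both groups ≥ minprop·n,
default 0.1), scanning exhaustively. The p-value of a log-rank test at the
selected cut is optimistically biased by the selection; the function always
warns about this and reports the statistic, not a corrected p. One property
worth knowing: near the optimum the statistic is almost flat, so with two
well-separated risk groups the argmax can sit a few order statistics inside
a group's marker support — the selected cut still reproduces the true
grouping to within a couple of per cent of samples, and that is the
property the tests assert.

Kaplan–Meier curves and k-group log-rank tests are delegated to lifelines
(with a fast numpy product-limit path inside the ROC estimator, verified
against lifelines to 1e-12). Calibration pairs mean predicted survival with
the KM estimate at the horizon, either within quantile bins (default 5, for
Cox-type models) or for the whole population (the form appropriate for
opaque machine-learning models). Bonferroni control is the plain threshold
alpha/m (0.05/3 ≈ 0.017 for three pairwise comparisons).

## Regrouping

The ELN2017 × model-risk grid collapses to three groups:
(Favorable, low) → low; (Intermediate, low) and (Adverse, low) →
intermediate; all three model-high cells → high. The clause assigning every
model-high subgroup to high risk is the only reading that yields exactly
three such subgroups, so it is the default; the alternative reading that
keeps (Favorable, high) low is available via `favorable_high_to="low"`.

## Synthetic cohorts

The generator emulates the features the pipeline relies on, with defaults
chosen to mirror the AML training-cohort conditions the workflow targets:
553 patients, 26.6% censoring, median survival near one year, age
≈ N(54.9, 14.8) years, FAB proportions from an observed AML case mix
(8 levels, 0–7), ELN2017 frequencies ≈ 22/57/21%, per-gene means in 5–12
and SDs in 0.25–2.3 on the log scale, and causal coefficient magnitudes in
[0.08, 0.76], the range of published signature coefficients.

Mechanics: one latent Gaussian factor per seed gene; each seed gene is its
own factor; correlated genes load on an assigned factor with loading
U(0.55, 0.85), putting population Spearman around 0.5–0.8 so
screen-passing genes exist by construction. Survival times are sampled from
an exponential-baseline Cox model with hazard proportional to
exp(true lp); the baseline rate is anchored at the cohort-mean hazard so
the day scale stays plausible whatever the (uncentered) linear-predictor
level. Censoring times are exponential with the rate tuned by bisection to
the target censoring fraction — independent of event times by construction.
Clinical missingness is MCAR only. Age carries small FAB-dependent shifts
(e.g. FAB M3 skews younger) and the ELN label probabilities tilt with age;
this realistic dependence is what gives random-forest imputation signal to
beat mean imputation, and is the only inter-covariate structure present.

Not emulated: probe-level microarray artifacts, batch structure beyond
location/scale shifts, informative censoring, or covariate-dependent
missingness. Passing tests therefore demonstrate correctness of the
statistical machinery under a well-specified proportional-hazards world,
not robustness to those real-data violations.

Sub-model signatures of informativeness a ∈ [0, 1] contain round(a·k)
randomly chosen causal genes with their true coefficients plus disjoint
noise genes with N(0, sd(beta)) coefficients; a = 1 reproduces the causal
signature exactly, a = 0 is disjoint noise.

## Numerical conventions and degenerate inputs

- Quantile normalization maps every sample onto the mean sorted profile,
  ties interpolated at average ranks; idempotent on tie-free data to 1e-9.
- Clinical imputation is missForest-style round-robin random forest
  (regression for age, classification for FAB/ELN), initialized by
  mean/mode, swept least-missing first until relative change < 1e-3 or 10
  sweeps; observed cells are never altered; deterministic under seed.
- Years convert to days as 365·k.
- All randomness flows through explicit integer seeds; simulation,
  imputation, folds, learners and bootstrap are bit-reproducible under a
  fixed seed and backend versions.
- Degenerate inputs fail loudly and specifically: duplicate identifiers,
  non-positive times, events outside {0,1}, categories outside their
  domains, empty gene intersections, fully missing columns, markers
  without an admissible split, horizons without cases or controls.

## Problem sizes in the test suite

Replicated experiments run at n = 150–2000 with tens of genes and
10–200 replicates per claim; the bootstrap uses B = 30–50 and learner grids
of one to four cells. These are the package's chosen experiment sizes for
its own verification; the procedures themselves default to the full-scale
settings (16-point s0 grid, 10×10 CV, B = 1000, 10-fold grids).

## Known limitations

- Breslow ties only; heavily tied (e.g. integer-day) data will differ
  slightly from Efron-based implementations.
- The per-covariate PH statistic uses the marginal information
  approximation; strongly collinear covariates shift power between the
  per-covariate and global tests.
- The NNE ROC estimator's span is fixed at the conventional rate rather
  than cross-validated.
- The stacking meta-fit assumes sub-model linear predictors on comparable
  (log-hazard) scales when weights are interpreted as relative importance;
  the fit itself is scale-equivariant, as the tests verify.
- ELN2017 labels are consumed as given; the genetic classification itself
  is out of scope.
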