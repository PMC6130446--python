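# Methods

`connectokin` implements a familiality/heritability analysis of model-based
functional connectomes ("connectotypes") and a synthetic cohort generator
that makes every stage testable against planted ground truth.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic world does and does not establish.

## The connectotype model

For a scan with M parcellated ROI time courses, each ROI's prewhitened
signal r_i(t) is modeled as a weighted sum of all the others:

    r̂_i(t) = Σ_{j≠i} b_{ij} r_j(t)

The M×M zero-diagonal matrix B = (b_{ij}) is the connectotype.  Each row is
a least-squares regression of column i on the remaining columns, solved
through the pseudoinverse of the predictor matrix truncated to its top-k
singular values (TSVD).  The interesting regime is underdetermined (more
ROIs than frames); there the truncation rank k is the regularizer.

Choices:

* **One shared rank k across all M row regressions**, selected by
  cross-validation over contiguous frame blocks (default 4 folds), loss =
  held-out squared error summed over ROIs.  Contiguous blocks respect
  temporal autocorrelation; squared error is the natural loss for a
  least-squares model.  Ties break toward the smaller rank (more
  regularization).
* **Exact per-ROI refit**: the SVD is computed per (fold, ROI) on the data
  with column i removed, so coefficients equal the brute-force TSVD
  solution entrywise (tested to 1e-8 against an independent oracle).  All
  candidate ranks are evaluated incrementally from one factorization per
  (fold, ROI), so a larger rank grid is essentially free.
* Default rank grid: 10 log-spaced integers in [2, min(M−1, frames−1)].

For multivariate Gaussian data with precision matrix Θ the population
regression is b_{ij} = −θ_{ij}/θ_{ii}; this identity is the recovery target
for the generator's ground truth.

## Preprocessing

Two preset profiles:

* **oregon** (motion-censored pediatric style): frames with FD > 0.2 mm are
  censored, surviving runs shorter than 5 frames removed, scans with under
  150 s of usable data flagged for exclusion; nuisance regression
  (intercept + linear trend + supplied regressors, least squares); 1st-order
  Butterworth band pass 0.009–0.080 Hz; AR(1) prewhitening per ROI
  (Yule–Walker), first `order` frames dropped to keep alignment.
* **hcp** (pre-denoised style): no censoring, no prewhitening (order 0).

Numerical choices: the filter runs forward–backward (zero phase) on the
full uncensored series, and the censor mask is applied afterwards, so the
filter never bridges concatenated gap edges.  Regression precedes
filtering (the order is not pinned by convention; it is switchable).  The
AR order for prewhitening defaults to 1 — minimal prewhitening that removes
the dominant lag-1 dependence without discarding frames.  AR coefficients
with |φ| ≥ 1 are clipped to 0.99 with a logged warning.  After censoring,
retained frames are treated as contiguous for the AR fit; at FD thresholds
that retain long runs this bias is negligible at the scales used here.

## Pair comparisons

All S² ordered scan pairs (model scan → target scan) are scored: the model
scan's connectotype multiplies the target scan's time courses; per-ROI
Pearson correlations between predicted and observed series form the
comparison's similarity profile, and their mean (Fisher-z transformed where
distributions are compared) is the scalar similarity.  Self comparisons on
the same scan split the retained frames into two contiguous halves — fit on
the first, predict the disjoint second — so the model always predicts fresh
data.  Odd frame counts give the extra frame to the evaluation half.
Comparisons are directional; group statistics count (A→B) and (B→A)
separately, which reproduces the S² bookkeeping of the printed rosters.
Group contrasts use Welch's t on Fisher-z values plus Cohen's d.

## Sibling classification

Feature vector of a comparison = its M per-ROI prediction correlations
(anatomy variant: signed per-ROI differences of thickness/sulcal depth,
optionally head-size-normalized or -regressed).  Per run:

1. draw a holdout — either whole families (`family_holdout`; families
   containing twins never enter training) or sibling scan-pairs
   (`scanpair_holdout`; both directions held out together);
2. draw a class-balanced unrelated sample (fresh each run, without
   replacement);
3. rank features on training rows only by the two-sample KS statistic and
   keep the top p (default 100);
4. standardize on training rows; tune a linear SVM's C over
   {1e−3 … 1e3} by exact leave-one-out CV on training rows (ties → smaller
   C, i.e. stronger regularization);
5. score the held-out rows; permutation nulls rerun 1–5 with training
   labels shuffled.

Numerical choices worth knowing:

* LOOCV is computed exactly but cheaply: removing a non-support vector
  leaves the SVM solution unchanged and the point is correctly classified
  outside its margin, so only support vectors are refit (verified against
  brute-force LOOCV in the tests).
* libsvm iterations are capped at 2,000.  On permuted-label (null) training
  sets, large C values otherwise iterate for minutes; an under-converged
  large-C fit simply loses the LOOCV selection, leaving the null at chance.
* A linear kernel is used throughout: high feature dimension, small n, and
  interpretability of the per-ROI selection tallies.

### Why the null's width depends on dimensionality

A classifier trained on permuted labels still inherits ~1/√n of the true
signal axis (the permutation's chance imbalance), with a random sign, and a
random hyperplane in M dimensions has expected alignment ~1/√M with any
fixed axis.  With few ROIs the null accuracy distribution is therefore
wide no matter how strong the planted signal is; the tightness of a
permutation null in this design rests on the high-dimensional feature
space (hundreds of ROIs with top-100 selection).  For this reason the
classifier experiments in the acceptance suite run at M = 100 with
sibling-rich 60-family cohorts, while cheaper stages (fingerprinting,
identity recovery) use M = 30.

## Heritability

Outcomes: each subject pair's per-ROI prediction correlations, averaged
over the two comparison directions (the pair, not the direction, is the
analysis unit).  Factors: shared environment (related vs unrelated) and
shared genetics (MZ vs DZ-or-sibling vs unrelated), with ROI as the
within-pair repeated measure.  Outcomes are rank-inverse-normal
transformed per ROI — Φ⁻¹((rank − 0.5)/n), average ranks for ties — within
each ANOVA's pair subset.

The two pair-level factors are aliased by construction (environment is a
coarsening of genetics).  Sequential (Type-I) sums of squares with ROI
entered first, environment second, genetics third is the only ordering
under which both main effects are estimable: genetics then captures
exactly the MZ vs DZ/sibling contrast beyond relatedness, and with no MZ
pairs its SS is exactly 0 (flagged "aliased").  Interactions are pooled
into the residual.  h² = SS_genetics/SS_total, c² = SS_environment/SS_total.

Because every pair is observed at every ROI, the design is balanced and the
ROI factor is exactly orthogonal to the pair-level factors; the sequential
SS is therefore computed in closed form from ROI means and pair means
(O(P·R)) and verified in the tests against nested statsmodels OLS fits.
(A single rank-deficient formula fed to a Type-I ANOVA routine attributes
the aliased degree of freedom unpredictably; nested RSS differences are
the unambiguous oracle.)

Repeated estimation: each of n_anovas (default 1,000; 100–200 in scaled
runs) draws a fresh matched subset of unrelated pairs (default 58), and
h²/c² are summarized by their mean and 2.5/97.5 percentiles.  Factor
significance is an F test against the residual; ROI-level p-values are
Bonferroni-corrected by default (Benjamini–Hochberg available).

## The synthetic cohort

The generator states a world; it is not tuned per experiment.

* **Structure** (shared "brain"): a sparse symmetric edge support (density
  0.15) with base weights ~N(0, 0.1²), drawn from `structure_seed`.  Two
  cohorts sharing `structure_seed` share support and base weights — ROI j
  means the same thing in both — which is what makes cross-dataset
  transfer meaningful.  Optionally the familial signal is restricted to
  edges incident to a declared ROI subset (`familial_rois`), emulating
  network-localized familiality.
* **Subjects**: per-subject edge weights w_s = base + 0.3·dev_s with
  dev_s = √g2·G_s + √c2·C_f + √e2·E_s, where G is a Gaussian edge field
  with corr(G_a, G_b) = kinship (MZ 1, DZ/sibling 0.5, unrelated 0,
  realized as √0.5·family + √0.5·individual with MZ twins sharing the
  individual part), C_f is family-shared, E_s unique.  Defaults
  g2/c2/e2 = 0.4/0.2/0.4.  The subject-to-base amplitude ratio (0.3 vs
  0.1) makes individual fingerprints dominate the common backbone,
  consistent with strong self-identification.
* **Precisions**: Θ_s assembled symmetric with unit diagonal and loaded to
  minimum eigenvalue 0.1; if the required loading exceeds 5, the density is
  halved and the draw repeated (logged).  B_s = −θ_{ij}/θ_{ii}.
* **Scans**: frames drawn from N(0, Θ_s⁻¹) and AR(1)-filtered in time
  (φ = 0.3, marginal covariance preserved) so prewhitening is exercised.
  Defaults M = 30 ROIs, 240 frames (the average frame count surviving
  censoring in a 3×5-minute pediatric protocol), TR 2.5 s.
* **Families**: the default mix reproduces the adult reference sample's
  structure — 70 one-, 49 two- and 10 three-descendant families = 198
  subjects carrying 10 MZ + 11 DZ + 58 nontwin sibling pairs.
* **FD traces**: lognormal (median 0.1 mm, σ = 0.5) with an optional
  per-family median shift, the positive/negative control for motion
  familiality.
* **Anatomy**: per-ROI thickness/sulcal depth with their own g2/c2/e2
  structure plus a head-size confounder (head size ~N(1, 0.1), slope 0.5),
  so the head-size adjustments are testable.
* **Pair outcomes with planted SS fractions** (`make_pair_outcomes`): for
  heritability recovery the planted "whole-brain genetic fraction" is
  planted directly at the outcome level via closed-form group means
  (unrelated 0, DZ/sib d, MZ d+m with m = √(2·h2·T), d+m/2 = √(1.5·c2·T),
  T = 3/(1−h2−c2), unit noise), because the mapping from time-series g2 to
  the SS fraction of prediction correlations has no closed form.  With
  c2 = 0 the related-group mean equals the unrelated mean by construction.

What a green test does **not** establish: the generator has no hemodynamics,
no scanner noise spectra, no spatially structured motion artifacts, no
age/site effects, and Gaussian marginals throughout; real-data accuracies
and h² values are not reproduced here (the source datasets are
restricted), only the machinery's calibration and its parameter-recovery
behavior on a stated world.

## Known limitations

* The exact SVM kernel/hyperparameter space and the CV loss of the original
  analysis are not public; linear kernel + LOOCV over a log C grid and
  squared-error rank selection are explicit stand-ins.
* Sensitivity/specificity are computed per run, then summarized (matching
  distribution plots), not pooled over runs.
* Session "dates" may be ordinals; interval analyses then use ordinal
  differences.
* ANOVA p-values summarize per-resample F tests by their median; permutation
  p-values are available as a cross-check but are not the default.
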