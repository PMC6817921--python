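# Methods

## Scope and model

`kboost` addresses binary classification with skewed class frequencies.
The pipeline has three stages: (1) K-means boundary-instance selection,
(2) exact class balancing of the selected subset, (3) an AdaBoost.M1
ensemble of gain-ratio decision trees fitted on the balanced subset. The
rejected remainder of the data is the natural held-out evaluation set for
the holdout protocol; a stratified 10-fold cross-validation protocol with
in-fold resampling is also provided.

The premise of stage 1 is geometric: instances far from their cluster
centroid sit near the cluster border, and for data whose clusters align
with classes the cluster border approximates the inter-class decision
boundary. Interior instances are redundant for discriminative learning;
boundary instances carry the margin information. Selection never consults
labels — only the balancing step counts them.

## K-means

Lloyd iteration: assign each point to its nearest centroid (Euclidean,
ties to the lowest cluster index), recompute centroids as cluster means,
stop when membership stabilizes, the maximum centroid shift falls below
`tol` (default 1e-6), or `max_iter` (default 300) is reached. An emptied
cluster is re-seeded with the point currently farthest from its centroid.
Initial centroids are K distinct data rows drawn with the seeded
generator; because that initialization can land in local optima even on
tiny inputs, the fit runs `n_init = 10` restarts and keeps the
lowest-inertia model. k-means++ initialization is available as an option.

Reported `inertia` is by default the sum of *unsquared* Euclidean
distances to the assigned centroid, consistent with the square-root form
of the average-distance statistic the selector uses; `objective="squared"`
switches to the classical squared sum. Note the analytical asymmetry: the
mean-update iteration is a descent method for the squared objective only.
On adversarial tiny configurations a converged partition may therefore
differ from the exhaustive minimizer of the unsquared sum; the test suite
asserts exhaustive-optimum equivalence on the squared objective and checks
the unsquared objective on separated clouds where both optima coincide.

## Selection threshold and balancing

For each point, the threshold base is its cluster's mean centroid
distance (`scope="per_cluster"`, default) or the global mean distance
(`scope="global"`). Under `rule="boundary"` (default) a point is a
candidate when its distance ≥ η × base; `rule="interior"` inverts the
predicate (both directions appear in descriptions of this family of
methods; the boundary direction matches the method's stated motivation via
border prototypes, so it is the default, and both are implemented and
tested). Clustering is on the pooled data by default
(`cluster_on="all_data"`, K = 2); per-class clustering is available.

Balancing modes:

* `trim` (default): both classes are reduced to the smaller candidate
  count, dropping least-informative points first (smallest distance under
  the boundary rule, largest under interior; ties broken by row index).
  η is halved — at most twice — only if a class has *no* candidate at the
  current threshold. An earlier design relaxed η for the deficient class
  before trimming in every unbalanced case; measurement showed the η/2
  pass routinely pulls nearly the entire minority class into the training
  subset, leaving a test remainder with almost no positives and making
  held-out minority metrics meaningless. Trimming alone already
  guarantees exact balance, so relaxation is reserved for the degenerate
  empty-candidate case.
* `relax_eta`: the literal relaxation strategy — η halved for the
  deficient class, at most twice, then the larger class capped to the
  smaller count. Guarantees equal counts.
* `none`: raw thresholding, no balancing (used by the monotonicity and
  enrichment properties; η = 0 with the boundary rule selects everything,
  making the downstream pipeline coincide with plain AdaBoost).

A selection that leaves a class empty raises a degenerate-selection error
naming the η that caused it. η accepts 0 (identity selection under the
boundary rule); useful values in practice span roughly 0.25–1.6.

## Weak learner and boosting

The tree is C4.5-flavoured: binary numeric splits at midpoints between
consecutive distinct sorted values, scored by gain ratio (information gain
over split information) on *weighted* class frequencies, requiring
strictly positive gain and at least `min_leaf = 2` unweighted samples per
side. Ties break toward the lowest feature index, then lowest threshold.
Postpruning is error-based: a subtree collapses to a leaf when the leaf's
pessimistic error estimate (binomial upper confidence limit at
`pruning_cf = 0.25`, Clopper–Pearson form) does not exceed the sum of its
children's estimates. This stands in for the proprietary C5.0 tree: the
boosted-tree contract treats the base learner as a black box with a trials
knob, and any faithful boosted gain-ratio tree satisfies it. (The C4.5
average-gain eligibility heuristic was evaluated and selected identical
splits on all tested inputs, so the plain maximum-gain-ratio rule is
kept.)

AdaBoost.M1 with `trials` rounds (default 10): uniform initial weights;
per round fit a weighted tree, compute weighted error ε_t on the original
training set, stop on ε_t ≥ ½ (trial discarded), keep a perfect trial
(ε_t = 0) with its vote weight capped at ½ ln((1−10⁻¹⁰)/10⁻¹⁰), otherwise
α_t = ½ ln((1−ε_t)/ε_t) with exponential reweighting and renormalization.
Prediction is the α-weighted vote; the score is the α-weighted share of
positive votes, in [0, 1], thresholded at ½ with ties to negative. If the
very first learner fails (ε₁ ≥ ½) the ensemble is empty and predicts the
training-majority class at score ½ rather than admitting a failed learner.

RUSBoost and SMOTEBoost run the identical loop, but each round's tree is
fitted on a resampled view of the weighted training set (fresh random
undersample / fresh SMOTE per round, seeded from the boosting generator);
ε_t and the reweighting always use the original instances. RUS-resampled
weights are the originals renormalized; SMOTE synthetics inherit their
base point's weight.

SMOTE follows the classic percentage convention: `over`/100 synthetic
points per minority point, each interpolated uniformly along the segment
to one of its `k_neighbors = 5` nearest minority neighbours, and
`under`/100 × (number of synthetics) majority rows retained. The reference
setting over = 100, under = 300 turns (10 minority, 60 majority) into
(20 minority, 30 majority).

## Metrics and rank statistics

Sensitivity, specificity, accuracy, G-mean, ROC AUC (Mann–Whitney rank
form, tied scores rank-averaged — identical to the trapezoidal ROC area),
and MCC, with the conventional value 0 when an MCC marginal is zero. An
absent class yields NaN rates with an explicit flag rather than a silent
zero; without scores, AUC falls back to (sens + spec)/2 and is flagged.

The Friedman test uses the tie-corrected χ² approximation with k−1 degrees
of freedom (Iman–Davenport F variant available). Mean ranks are reported
with k = best — matching the benchmark-table convention where the best of
four methods carries rank 4 — with a polarity flag for the literature's
1 = best convention. The Nemenyi critical difference is
q_α(k)·√(k(k+1)/(6n)) from the tabulated studentized-range q values
(α ∈ {0.05, 0.10}, k ≤ 10). Cross-validation cells pool the per-fold
confusion matrices and compute metrics once on the pooled matrix
(micro-averaging), chosen for determinism over macro-averaging.

## Synthetic data

`make_imbalanced` draws each class from a Gaussian mixture with unit
within-component standard deviation. Class counts are fixed
deterministically (minority = round(n/(1+IR))), so requested imbalance
ratios are realized exactly at the count level rather than sampled. The
majority class is centred at the origin; the minority mean sits at
Euclidean distance `separation` (in within-class σ units) along a seeded
random direction; `n_subclusters` > 1 jitters component centres around the
class mean. Defaults (n = 600, IR = 5, 8 features) sit at the small end of
the benchmark regimes the package targets (ratios ~1.1–16, 8–30
features).

What this emulates — and does not: Gaussian geometry makes the boundary
structure analytically predictable, which is what the selector's
enrichment and monotonicity properties are verified against. Real tabular
data with heavy tails, discrete or correlated attributes, and
non-ellipsoidal classes is not emulated, so passing tests certify the
algorithmic contracts, not field performance on any particular dataset.
Features are used unscaled by default (K-means is scale-sensitive; an
optional min-max switch exists because attribute units vary in real data).

## Known limitations

* On cleanly separable data the balanced boundary subset is usually
  separable too, so the first tree reaches ε = 0 and boosting stops with a
  single tree — the prescribed ε = 0 rule forecloses ensemble averaging
  exactly where variance reduction would help most. On the synthetic
  recovery benchmark (n = 600, IR = 5, separation 6) the median held-out
  MCC over ten seeds is ≈ 0.94–0.96 depending on the seed set, with the
  residual errors being false positives from single-tree axis-aligned
  generalization; an independent reference tree implementation trained on
  the same subsets scores the same, so this is a property of the method,
  not of this implementation.
* The selection threshold interacts with dimensionality: in higher
  dimensions centroid distances concentrate, so η near 1 keeps roughly
  half of each cluster regardless of geometry.
* Multi-class problems, categorical attributes, sparse matrices and
  cost-sensitive weighting are out of scope.
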