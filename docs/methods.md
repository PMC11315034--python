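# Methods

## Model

`kgcascade` implements a sequential (cascade) ensemble for binary
classification of large numeric tables. Write d for the number of raw
features and N for the cascade depth.

**Training.** The (cleaned, scaled, class-balanced) training set is
partitioned into N disjoint subsets of near-equal size by a seeded shuffle
with round-robin assignment; subset i belongs to level i. For level
i = 1…N:

1. the subset's raw features are *augmented* through the already-trained
   levels 1…i−1: each earlier level maps the current matrix through its own
   expansion → projection → classifier and its prediction is appended as
   one new feature, so level i sees d + i − 1 columns;
2. the augmented matrix is expanded with a full second-degree
   Kolmogorov–Gabor polynomial — all linear terms, then all products
   x_i·x_j with i ≤ j in lexicographic order; width d′ + d′(d′+1)/2 for
   input width d′. The constant term is excluded: it has zero variance, is
   annihilated by PCA centering, and the classifier intercept carries it;
3. PCA is fitted on the expanded subset and the smallest leading component
   set whose cumulative explained-variance ratio reaches the threshold
   (default 0.95) replaces the expanded columns;
4. a linear classifier fitted by SGD (logistic loss by default) is trained
   on the reduced representation; when a hyperparameter grid is supplied it
   is tuned by seeded stratified 5-fold cross-validated macro F1 on the
   level's own subset.

**Application.** An observation is pushed through the levels in order;
each level *reuses* its stored centering vector, component matrix and
classifier — nothing is refitted — and appends its prediction. The last
level's prediction is the output class. Because every level's quadratic
expansion acts on the previous level's output, the realized decision
boundary is implicitly a polynomial of order 2^N while every fitted model
stays linear.

The per-level PCA is the efficiency device: on compressible data the
quadratic expansion of d′ columns (hundreds wide) collapses to a few
dozen components at the 95% threshold, which both shortens SGD training
and removes low-variance directions that would otherwise erode
generalization.

### Assumptions

- binary labels, numeric features only (categorical encoding is out of
  scope);
- the training set is cleaned (no duplicates/missing cells), scaled, and —
  for imbalanced problems — balanced before fitting;
- each of the N subsets contains both classes (violations raise an error
  advising fewer levels or rebalancing, rather than silently fitting a
  constant classifier);
- the feature distribution is compressible, i.e. the expanded covariance
  has a dominant low-dimensional part; with an incompressible matrix the
  reduction step simply retains more components.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_levels` (N) | — | cascade depth = number of training subsets |
| `variance_threshold` | 0.95 | minimal cumulative explained-variance ratio retained per level; 1.0 disables reduction (full rank) |
| `loss` | logistic | SGD loss (`logistic` or `hinge`) |
| `alpha` | 1e-4 | SGD regularization strength (l2 by default) |
| `max_iter`, `tol` | 1000, 1e-3 | SGD stopping rule |
| `augmentation_signal` | label | what a level appends for its successors: hard 0/1 label or raw decision score |
| `seed` | 0 | drives partitioning and each level's SGD (level i uses seed + i − 1) |

Preprocessing defaults: standard (z-score) scaler fitted on the training
split only; 80/20 train/test split; SMOTE with 5 interpolation neighbors;
NearMiss version 1 (majority rows with smallest mean distance to their 3
nearest minority rows). The hybrid balancing rule is symmetric in the
per-class target m: any class below m is SMOTE-oversampled to m, any class
above m is NearMiss-undersampled to m, so the output is always exactly
m + m rows. The per-class target is chosen by `balance_search`: each grid
value is evaluated by balancing the 80% fit-portion of the training data,
fitting the cascade's base SGD learner, and scoring macro F1 on the
balanced rows and on the untouched 20% validation portion; the winner
maximizes validation F1, ties broken by smaller |train − validation| gap,
then smaller m. For survey-scale data (hundreds of thousands of rows) the
conventional grid is 50,000…150,000 in steps of 25,000
(`FULL_SCALE_BALANCE_GRID`); the test-bed uses proportionally scaled-down
grids. Balancing is applied *after* scaling (the scaler never sees
synthetic rows); users porting pipelines that balance first should note
the order.

Depth selection (`depth_scan`) fits one cascade per candidate depth
(default grid 1–6) with a shared seed and picks the depth maximizing test
F1, ties broken by smaller |train − test F1 gap| then smaller depth;
depths where test F1 exceeds train F1 are flagged as the
overfitting-pattern regime. Metrics default to macro averaging (unweighted
mean over the two classes), which is informative under imbalance; plain
accuracy is deliberately not reported.

## Synthetic data generator

The generator emulates the statistical shape of a large risk-factor
survey extract: n rows of d observed features produced as X = Z·W + ε,
where Z is n × r independent standard normal (r = `latent_rank` ≪ d), W a
seeded r × d mixing matrix, and ε isotropic noise with σ = 0.1 — so the
sample covariance has ≈ r dominant directions and both the raw matrix and
its quadratic expansion are strongly PCA-compressible. The true label is
the sign of a seeded random polynomial (all monomials up to
`boundary_degree`, default 2) in the *latent* factors, thresholded at a
quantile; optional label noise flips labels independently. Because
symmetric flips pull the positive rate toward 1/2, the quantile is set at
the noise-compensated level p = (m − ν)/(1 − 2ν) for requested minority
fraction m and flip probability ν, so the realized rate matches m in
expectation. Duplicate rows are appended as exact copies and missing
cells (NaN; empty CSV fields) are injected *before* duplication so that
appended rows remain exact duplicates.

What the generator does **not** emulate: categorical/ordinal codings,
survey weights, missingness that is informative rather than random,
heavy-tailed or mixed-type marginals, and label noise correlated with the
features. Passing tests therefore demonstrate the mechanics and the
designed properties (compression, nonlinear gain) on well-specified
low-rank data, not performance on any particular real survey.

## Numerical choices

- PCA via thin SVD of the centered matrix; sample covariance uses the
  n − 1 denominator (ratios are scale-free either way). Component count is
  the smallest k with cumulative ratio ≥ threshold (equality tolerated at
  1e-12), capped at the numerical rank; an all-constant matrix yields a
  k = 0 reducer with a warning.
- Zero-scale (constant) columns transform to 0 under either scaler.
- Duplicate detection compares full rows (all features + the label) for
  exact equality after parsing.
- Level classifiers are stored as weight vector + intercept; prediction is
  the sign of the affine decision function, identical to the fitted SGD
  estimator's rule. Model archives (`kgc-1`) are zip containers of raw
  array blobs plus JSON metadata with pinned entry timestamps, so
  identical fits serialize to byte-identical files; fit wall-times are
  reported in experiment outputs but never stored in archives.
- All selection rules (balancing target, depth, grid search) break ties
  deterministically (gap, then the smaller candidate), so every result is
  a pure function of data + seed. The CLI fans one global seed out to the
  pipeline stages by fixed documented offsets.

## Design choices

- During training-time propagation of subset i through earlier levels the
  stored reducers are **reused**, not refitted: refitting would change the
  input space the earlier classifiers were trained on. The application
  algorithm makes this reuse explicit, and the training algorithm is
  interpreted consistently with it.
- The cascade has exactly N levels, level i trained on subset i; there is
  no additional held-out synthesis subset and depth is fixed rather than
  stopped adaptively.
- The appended prediction feature defaults to the hard class label;
  appending the decision score is available via `augmentation_signal`
  since downstream quadratic terms can exploit its magnitude. Appended
  0/1 labels are left unscaled next to z-scored features — they are
  already bounded.
- The "no-PCA" comparison arm runs the same code path with
  `variance_threshold = 1.0` (full-rank retention), isolating the effect
  of the reduction step from everything else.
- The full quadratic expansion includes the linear block; a 29-attribute
  input thus expands to 464 columns (29 + 29·30/2).

## Test-bed problem sizes

The packaged experiments run at desk scale: the quadratic-boundary
benchmark uses n = 20,000 rows (d = 20, r = 5, 30% positives, depth 3),
the compression study d = 30, r = 5 at n = 4,500, and the depth scan
n = 8,000, keeping the full test suite under a minute on one core. The
method itself has no size-dependent logic; scaling up changes only wall
time.

## Known limitations

- Binary classification only; no regression or multi-class variant.
- Levels train strictly in sequence (each consumes its predecessors'
  outputs), so the scheme does not parallelize across levels.
- Explicit expansion is quadratic only; higher-degree nonlinearity comes
  from depth, not from higher-order terms.
- NearMiss version 3 uses a shortlist construction that can fall back to
  the version-1 ranking when the shortlist is smaller than the target.
- SMOTE requires at least `oversampler_neighbors + 1` members in any class
  that must be oversampled; tiny minorities need a smaller neighbor count
  or a smaller target.
- Very deep cascades on small data fail loudly (single-class subsets)
  rather than degrading gracefully; this is intentional.
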