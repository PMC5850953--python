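# Methods

This note documents the models and procedures implemented in `phylocnn`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Tree metric and embedding

Features are the leaves of a rooted phylogeny with nonnegative branch
lengths.  The patristic distance d^Tree(i, j) is the path sum of branch
lengths between leaves; it is an additive tree metric, verified by the
four-point condition at a relative tolerance of 1e-9 (floating-point path
sums drift, so an exact check would false-alarm).  Unrooted Newick input
is rooted arbitrarily — patristic distances are invariant to root
placement.  Polytomies are accepted; nothing downstream needs a binary
tree.  Missing branch lengths are an error unless the caller explicitly
supplies a default: silently substituting one corrupts distances.

The square root of an additive tree metric is Euclidean: the
doubly-centred Gram matrix B = −½ J (√d)∘² J is positive semidefinite.
`euclidean_certificate` checks this by eigendecomposition, declaring the
metric Euclidean when the minimum eigenvalue is ≥ −tol · λ_max
(tol = 1e-8): a strictly-nonnegative test would reject genuinely PSD
matrices through rounding alone.

Because the metric is provably Euclidean, the embedding uses classical
(Torgerson) MDS — deterministic, closed-form, exact at full rank — rather
than iterative stress majorisation.  Default dimension is the effective
rank (eigenvalues > 1e-9 λ_max); negative eigenvalues (numerical noise)
are clipped to zero.  Each eigenvector's largest-magnitude entry is made
positive, so embeddings are reproducible bit-for-bit without a seed.  The
stress diagnostic is the root of (residual sum of squares over Σ d_ij);
it is 0 for an exact embedding and 1 for all-zero coordinates.

Optional sparsification applies the SCAD threshold (concavity a = 3.7,
the standard recommendation) elementwise to the coordinate matrix, with
the penalty chosen by cross-validation: the upper-triangle distance
entries are partitioned into 5 folds and the penalty minimising the mean
held-out squared reconstruction error is selected.  The objective to
sparsify (scores, loadings, or both) was genuinely open; thresholding the
coordinates directly with held-out-entry CV is the simplest scheme that
is exactly reproducible and reduces to the identity at penalty 0.
Sparsification is off by default — the plain MDS embedding is the
documented baseline path.

## The Phylo-Conv network

A Phylo-Conv layer gathers, for every meta-leaf, its k nearest meta-leaves
by embedded Euclidean distance (self first, at distance 0; ties broken by
ascending index for determinism) and convolves the gathered values with a
filter bank.  Two genuinely open design points:

- **Neighbour of a meta-leaf.**  Meta-leaves are linear combinations of
  leaves, but the combination weights change during training.  Coordinates
  are therefore propagated as the *unweighted centroid* of the k gathered
  neighbours, fixed before training: neighbour indices become
  data-independent and are computed once per layer.  A weight-aware update
  would force neighbour recomputation every optimisation step; it is left
  as an extension point.
- **Self-inclusion.**  The centre leaf is its own first neighbour;
  excluding it would discard the leaf's own abundance from its filter.

Architecture defaults: 2 Phylo-Conv layers, 16 filters, k = 16
neighbours, max-pool window 2 stride 2 along the meta-leaf axis, a dense
layer of 64 units (128 in domain-adaptation runs) with 0.25 dropout,
SELU activations in the convolutional and dense stages, a softmax output
head (sigmoid single-unit head for the binary adaptation variant), Adam
at learning rate 5e-4, categorical (or binary) cross-entropy.  Epochs and
batch size default to 100 and 32 with early stopping on validation loss
(patience 10) when a validation set is supplied; pool size, pooling
remainder handling (truncation) and the hidden-dense activation follow
the common conventions where no value was prescribed.  The network is
implemented directly in NumPy (explicit forward/backward passes and an
Adam optimizer); one integer seed drives weight initialisation, shuffling
and dropout, so identical seeds give bit-identical weights.

Domain adaptation replaces the output layer with a freshly initialised
head for the new task and freezes every other parameter; the optimizer
simply never updates frozen arrays, so they remain bit-identical — a
contract the tests assert — and the trainable parameter count is exactly
(dense_units + 1) × n_head_outputs.

## Compositional generator

Samples are points of the Aitchison simplex.  All Gaussian machinery
operates in ilr coordinates under a fixed Helmert-type orthonormal basis
(coordinate j is √(j/(j+1)) · ln(gm(x₁..x_j)/x_{j+1})): any orthonormal
basis gives an isometry, and fixing one makes every number reproducible.
Zeros in real count data are handled by multiplicative replacement with a
configurable pseudo-fraction (default 1e-6) before the transform.

Given two classes' ilr statistics (mean μ_C, covariance Σ_C with the n−1
denominator, class size n_C), the separation construction is:

- u = μ_A − μ_B (used unnormalised);
- σ² = [Σ_A (proj)² + Σ_B (centred proj)²] / (n_A + n_B), where the sums
  of squared class-centred projections onto u are evaluated exactly as
  (n_C − 1)·uᵀΣ_C u — identical to the raw-sample sums, which the tests
  verify against a direct sample computation;
- midpoint μ = (μ_A + μ_B)/2 and shifted means
  m_C = μ + α σ μ_C/‖μ_C‖, so α = 0 collapses both means onto μ exactly;
- per class, n samples from N(m_C, Σ_C) in ilr space, mapped back by the
  inverse ilr; class A rows first, one seeded generator.

The self-contained fixture (`random_fixture`) emulates a two-class gut
cohort without external data: a random binary topology with exponential
branch lengths (mean 0.1), unit-norm random class means, and low-rank-
plus-diagonal class covariances that share a common backbone with a 10%
class-specific component.  The shared backbone matters: both classes of a
real cohort come from the same community, so their covariances are
similar.  Fully independent covariances would let a classifier separate
the classes even at α = 0 — different ilr covariances induce different
composition-space means through the nonlinear inverse ilr — destroying
the construction's defining property that α = 0 is chance level.  With
these defaults the linear-classifier CV MCC profile is ≈ 0 / 0.55 / 0.91
/ 0.98 at α = 0/1/2/3, mirroring the intended steady increase in class
separation.

What the generator does **not** emulate: sequencing-depth and count
noise, zero inflation, real taxon-abundance marginals, and any
correlation between the tree and the class signal (the phylogeny and the
class statistics are drawn independently).  Passing tests therefore show
the machinery is correct and the protocol unbiased — not that the network
will rank as it does here on real cohorts, where the tree-signal coupling
is exactly what the architecture is meant to exploit.

## Data analysis protocol

Stratified 80/20 external split; 10 repetitions of stratified 5-fold CV
on the training part; ANOVA-F feature ranking computed inside each
training fold only; models at 25/50/75/100% of the features active
(non-constant) on the training part, counts rounded up; MCC (Gorodkin
multiclass generalisation, degenerate denominators → 0) as the score;
Borda fusion (score = list length − 0-based position, ties by ascending
feature id) of the 50 per-fold rankings; external validation by refitting
on the whole training part at each fraction of the fused list.  Internal
estimates carry 95% studentized bootstrap (bootstrap-t) intervals over
the 50 fold MCCs, 1000 resamples, seeded; zero-variance inputs collapse
to the point estimate, and the interval is clamped to contain the
estimate (the raw bootstrap-t interval can exclude it under extreme
skew).  Classes smaller than the fold count are rejected up front with
the offending class named.  The comparison classifiers (linear SVM,
random forest, MLP) run behind the same factory interface, so the
protocol code is identical across learners.

Randomisation checks: `random-labels` permutes labels before the whole
protocol; `random-features` replaces the in-fold ranking by a seeded
random permutation.  An unbiased pipeline gives mean MCC ≈ 0 under random
labels; under random features at the full feature fraction the signal
survives, since only selection — not the data — was randomised.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use deliberately compact
problem sizes chosen to exercise every claim at comfortable
Monte-Carlo resolution: trees up to 50 leaves for metric exactness;
p = 64 features, 500 samples and 10 seeds for the separability profile;
5000 samples per class for parameter recovery (3·SE coordinatewise);
20 epochs at p = 64, n = 500 for the end-to-end CNN run (internal 5-fold
CV MCC ≈ 0.8–0.9 at α = 2); pretraining on 2000 samples and adapting on
40 for the domain-adaptation comparison (10 seeds, adapted minus scratch
MCC ≈ +0.07 to +0.5 depending on the fixture draw, always positive).
Chance-level assertions are made on means over seeds, since a single
external split of a few hundred samples has an MCC standard error near
0.07.

## Known limitations

- Neighbour search is exact O(m²); very large trees would want a spatial
  index or landmark MDS, both out of scope.
- The SCAD penalty is tuned against reconstruction of the embedding
  distances, not downstream classification.
- The network trains on one CPU; there is no GPU path.
- Alternative tree metrics (UniFrac-style, topology-only) are not
  implemented; the patristic distance is the only metric offered.
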