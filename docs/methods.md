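# Methods

This note describes the model and procedure the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Problem setting

Given a small set of labelled protein sequences (a few hundred, several
disease classes), the goal is to find a compact subset of
tripeptide-composition features that discriminates the classes well.
The pipeline has six stages: encode sequences as tripeptide frequencies,
estimate pairwise feature dependence with mutual information, cluster
features by their dependence profiles, run a binary grey wolf search
inside each cluster with a cross-validated wrapper objective, pool the
per-cluster selections, and score the pooled set with One-vs-Rest
multiclass classifiers on held-out data.

## Tripeptide composition (TPC)

A sequence of length `L` over the 20 canonical residues has `L - 2`
overlapping windows of length 3.  The encoding is

    alpha_i = D_i / (L - 2),   i = 1 ... 8000,

where `D_i` counts windows equal to the i-th tripeptide.  The index map
is lexicographic over the residue order `ACDEFGHIKLMNPQRSTVWY`
("AAA" -> 1, "YYY" -> 8000) and is exposed 1-based everywhere so that
selected-feature reports are stable across runs.  With a fully canonical
sequence the entries sum to exactly 1.  In permissive mode, windows
containing a non-canonical residue (B, J, O, U, X, Z) contribute to no
count while the denominator stays `L - 2`; row sums may then fall below
1.  This keeps the formula verbatim at the cost of normalisation, and is
the documented deviation of permissive mode.

Preprocessing applies, in order: drop empty sequences, drop sequences
shorter than 20 residues (length exactly 20 is kept), drop exact
duplicate sequences keeping the first occurrence (labels are ignored for
the comparison), and under the default strict policy drop sequences with
non-canonical residues.  The order makes the filter idempotent and the
removal report unambiguous.

## Mutual information

Feature dependence is estimated with the discrete plug-in estimator in
bits.  Continuous frequencies are discretised by equal-frequency binning
with `n_bins = 5` (default): sample ranks are cut into bins of equal
occupancy, and tied values all take the lowest bin their tie group
touches, so the transform is deterministic and a constant column maps to
a single code.  Five bins is a deliberate small-sample choice — with of
the order of 150–250 sequences, finer binning makes the joint tables too
sparse for a stable plug-in estimate.  No bias correction is applied.

Three algebraically identical forms of MI (direct double sum, entropy
identity, expected pointwise MI) are implemented and cross-checked to
1e-10 in the tests; the matrix path uses the factorisation

    I_ij = S_ij / n + log2 n - P_i / n - P_j / n,
    S_ij = sum_ab C_ab log2 C_ab,

so only the `S` term needs computation per feature pair, done as one
bin-indicator matrix product per bin pair (float32 accumulator).  The
result is symmetrised as `(M + M^T) / 2` to remove BLAS summation-order
round-off, entries are clipped at 0, and the diagonal then equals the
per-feature plug-in entropy up to single-precision round-off (~1e-5
bits; the small-matrix tests verify agreement with the exact per-pair
estimator).  Columns that are zero in every sample are screened out
before the pair computation — they carry zero information and, for small
datasets, are the majority of the 8000 columns; the index map back to
original coordinates is kept.

Feature-to-label MI ("relevance") is computed the same way and is
reporting-only by default.  Setting `prefilter_top_fraction < 1` keeps
only the most relevant fraction before clustering; the default of 1.0
(off) reflects that no relevance cut-off is part of the core procedure.

## Feature clustering

Features are clustered by k-means on their MI-profile rows: feature `i`
is represented by the vector of its MI against every retained feature,
so the clustering geometry is determined entirely by the dependence
structure.  Lloyd's algorithm is implemented directly with the exact
conventions the pipeline relies on:

- initial centroids are `K` distinct data points drawn uniformly
  (no k-means++);
- nearest-centroid ties break to the lowest cluster id;
- a cluster emptied during assignment is reseeded with the point
  farthest from that cluster's previous centroid, taking distinct
  points and never emptying a donor cluster;
- the within-cluster sum of squares is checked to be non-increasing at
  every iteration (a violation raises);
- `n_restarts = 10` independent initialisations, best WCSS wins;
  `max_iter = 300`, convergence when the largest centroid shift falls
  below `tol = 1e-6`.

The default cluster count is `K = max(2, round(sqrt(d_retained)))`,
recorded in every result file.  No automatic K selection is attempted.

## Binary grey wolf search

Within each cluster, candidate subsets are bit vectors.  Per iteration
and wolf, each of the three best solutions so far (alpha, beta, delta)
proposes a candidate: with `a` decaying linearly from 2 to 0 over the
iterations and fresh uniform draws `r1, r2` per dimension,

    A = 2 a r1 - a,   C = 2 r2,   D = |C x_leader - x_wolf|,
    cstep = 1 / (1 + exp(-10 (A D - 0.5))),
    bstep = [cstep >= rand],
    candidate = leader OR bstep,

and the three candidates are merged by a stochastic crossover that takes
each bit from one of them with probability 1/3.  All-zero candidates
are repaired by flipping one uniformly chosen bit (an alternative mode
leaves them to the fitness's defined worst value).  The draw order is
fixed and documented, so a seed reproduces a run bit for bit.

Two design points deserve emphasis:

- **Leader distinctness.**  The leader triple is kept pairwise distinct
  as bit patterns.  The leader step is an OR, so it can only add bits;
  bits are removed solely by crossover across *different* leaders.  If
  all three leaders collapse onto one multi-bit pattern the search can
  never shed a bit again.  Admitting a duplicate leader adds nothing to
  the crossover and creates exactly this trap, so duplicates are skipped
  when leaders are updated (measured on an enumerable objective, this
  raises the rate of reaching the true optimum from ~92% to ~97% of
  runs).
- **Wrapper fitness.**  `fitness = lambda (1 - CV accuracy) +
  (1 - lambda) (n_selected / d)` with `lambda = 0.99`, stratified 3-fold
  cross-validation with folds fixed per cluster, and a nearest
  class-centroid rule as the inner classifier (a linear decision rule,
  refit tens of thousands of times per run; logistic regression, linear
  SVC and SGD are available by configuration).  Lower is better; an
  all-zero candidate scores `lambda` and is flagged, never raised.
  At `lambda = 0.99` one extra feature is kept only if it changes at
  least one cross-validated prediction.

Defaults `pop_size = 10` and `n_iterations = 30` keep a full run on ~80
clusters of ~80 features in the order of a minute on one CPU; both are
exposed as flags.

Single-feature clusters skip the search: the singleton is kept iff its
fitness beats the empty-set baseline `lambda`.

The final selection is the union of the per-cluster alpha bit sets,
mapped back to original 1-based indices; the per-cluster maps partition
the retained features, so the union size equals the sum of per-cluster
counts.

## Leakage control and seeding

Selection runs on a stratified 70% training split; the 30% balance is
touched only by the final evaluation.  Every stage seed (split, k-means,
per-cluster optimizer, per-cluster CV folds, evaluation) derives from
one master seed through a fixed spawn-key scheme, making the whole fit a
pure function of (data, configuration) and each stage individually
reproducible.  With `K = 1` the pipeline provably reduces to a plain
binary grey wolf search over the full retained set, bit-identical under
shared seeds (a test asserts this).

## Evaluation

Five classifiers are fitted on the selected columns behind an explicit
One-vs-Rest reduction: gradient boosting, Gaussian process, linear SVC,
logistic regression, and an SGD linear classifier (scikit-learn, library
defaults, fixed seeds).  Metrics come from per-class confusion counts:
accuracy, precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F1 = 2PR/(P+R)`, macro-averaged over classes (micro by flag); AUC is
the trapezoidal area under the per-class ROC curve with tied scores
grouped into single threshold steps (equivalent to the tie-corrected
rank statistic), macro-averaged.  A zero denominator defines the metric
as 0 with a logged flag.  Macro averaging is a deliberate choice for a
small multi-class problem where per-class errors matter equally.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes:
multi-class sets of sequences over the canonical alphabet in which each
class is enriched for a small set of class-specific tripeptides.  Each
class gets `motifs_per_class = 3` motifs, disjoint across classes;
each sequence draws its length uniformly from 72–120 residues, fills
with uniform background residues, and receives Poisson(8) motif
insertions (each a uniformly chosen class motif) at distinct
tripeptide-aligned slots, which guarantees non-overlap with placement
capacity `floor(L/3)`.  The length floor of 72 makes
demand-exceeds-capacity (an error) practically unreachable at the
default rate.  Motif length 3 maps each motif to exactly one feature, so
selections are scored by plain set arithmetic (recovery recall and
precision).  The default study conditions are 4 classes of 60 sequences.

What the benchmark does *not* emulate: real amino-acid composition
biases, hydrophobicity runs, homology between sequences within a class,
or correlated feature blocks from longer motifs (a longer-motif mode is
the natural extension).  Passing recovery tests therefore shows the
pipeline finds planted compositional signal at realistic sample sizes,
not that it resolves the weaker, correlated signals of real proteomes.

A property worth knowing when interpreting recovery numbers: motifs of
the same class have high mutual MI and co-cluster, and the per-cluster
search drops a motif that rescues no cross-validated prediction given
its partners (the sparsity term breaks the tie).  Exhaustive
enumeration inside such clusters confirms these drops are exact optima
of the wrapper objective — redundancy removal working as designed — so
single-draw recovery at the default conditions fluctuates between about
9/12 and 12/12 depending on which sequences happen to lack which
motifs; the acceptance suite asserts the mean over a fixed replicate
ensemble.

## Numerical conventions

- MI in bits (base-2 logs) everywhere, recorded in matrix metadata.
- `0 log 0 = 0`; zero-denominator metrics are 0 with a flag.
- Equal-frequency binning clamps `n_bins` to the sample count with a
  warning.
- The MI matrix and k-means run in float32 (the 6000^2-scale matrices
  would otherwise dominate memory and time); all small-scale paths and
  the per-pair estimator are float64.  Known consequence: "exact" zeros
  and symmetric identities hold to ~1e-6 on the matrix path.
- k-means WCSS uses the mean-centroid identity
  `sum ||x||^2 - sum_k n_k ||mu_k||^2` during iterations and a direct
  float64 recomputation for the reported final value.
- Ranking ties (selected-feature reports) break by ascending feature
  index; nearest-centroid ties break to the first class in sorted
  order.

## Known limitations

- The plug-in MI estimator is biased upward for sparse joint tables;
  with ~170 training samples and 5 bins this bias is material for
  near-zero MI values, but the pipeline only uses MI comparatively
  (clustering geometry, relevance ranking), where a shared bias is
  mostly harmless.
- The wrapper objective at `lambda = 0.99` barely penalises subset
  size; big uninformative clusters keep roughly half their features
  because removing them is fitness-neutral within the iteration budget.
  Selected fractions are therefore far larger than what a
  sparsity-oriented configuration (smaller lambda, larger budget) would
  give.
- The Gaussian process classifier is O(n^3) in training samples and the
  gradient boosting classifier is the slowest of the five on wide
  selections; both are fine at the few-hundred-sequence scale the
  package targets.
- Problem sizes in the shipped tests and the acceptance script (240
  sequences, ~6000 retained features, 10 restarts, pop 10 x 30
  iterations) are the package's default study scale, chosen to keep a
  complete desk run in minutes on one CPU.
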