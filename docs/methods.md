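# Methods

## The classification model

The Decision Forest implemented here is a consensus of a fixed number of
binary classification trees fitted on mutually exclusive descriptor pools.
Its assumptions are those of threshold-based tree models generally: the
activity signal is expressible as axis-aligned cuts on individual
descriptors, and descriptors are comparable after min-max scaling to [0, 1]
(the scaling is monotone, so tree structure is in fact invariant to it; it
is retained because the standard preprocessing pipeline applies it and
serialized models record it).

### Tree fitting

Splits are scored by the two-class Gini diversity index
`G(node) = 1 − p₁² − p₀²`; the accepted split maximizes the weighted
impurity decrease `G(parent) − (n_L·G(L) + n_R·G(R))/n` over every
candidate descriptor and every threshold placed at the midpoint between
consecutive distinct sorted values. Rows with value equal to the threshold
route to the left ("meets criterion") child; the convention is fixed so
that fitted models are reproducible. Splitting stops at pure nodes, nodes
smaller than `min_split_size` (default 10 chemicals), and nodes where no
split decreases impurity by more than 1e-12 (the epsilon guards against
float round-off manufacturing splits on effectively pure nodes).

Tie-breaks are deterministic: among equal-decrease splits the lowest
descriptor column index wins, then the smallest threshold. Two fits on
identical input produce byte-identical serialized models.

### Pruning

Pruning is bounded and misclassification-guided: only splits whose subtree
height in the *grown* tree is at most `max_prune_levels` (default 3) may be
collapsed into a leaf, so at most that many bottom levels can be removed.
Among all admissible pruned trees (including no pruning) the one with the
fewest misclassified training compounds is returned; ties go to the tree
with fewer nodes, so a split that does not improve training classification
is always collapsed. Because collapse decisions in disjoint subtrees are
independent and a collapsed parent makes its descendants irrelevant, a
post-order dynamic program finds the exact optimum in one pass. The bound
is evaluated against heights in the grown tree rather than re-evaluated as
pruning proceeds; re-evaluation would let cascaded collapses remove more
than `max_prune_levels` levels.

The phrase "maximum levels to be pruned" admits a second reading — prune
the tree down *to* depth 3 — which was rejected because the published
five-tree model has trees with eight to ten terminal nodes, i.e. deeper
than 3.

### Forest construction and consensus

Tree 1 is grown and pruned on the full descriptor pool; each subsequent
tree on the pool minus every descriptor used by earlier trees. This is the
mechanism that makes the combined trees heterogeneous and wraps variable
selection inside model construction. Fitting stops early when the pool
empties or the next tree degenerates to a bare leaf (a constant tree only
dilutes the consensus); the first tree is kept even if it is a bare leaf so
a forest always predicts.

The consensus probability is the unweighted arithmetic mean of the trees'
leaf binder *proportions*, not their hard 0/1 labels: five hard votes would
quantize p to six values, whereas proportions preserve a continuum, which
the confidence score needs. A hard-vote mode is available
(`ForestFitConfig(vote="hard")`) for comparison. The call threshold is
`p ≥ 0.5` (the boundary value itself is a binder call, with confidence 0).

A consequence of disjoint pools worth knowing: when the data contain only
one strongly informative descriptor, trees 2..5 are fitted on noise and
dilute the consensus, so a forest can score *below* a single tree on such
data. This is by design — the consensus buys robustness on data with many
weakly informative, partially redundant descriptors, the regime molecular
descriptor tables live in.

## Preprocessing

Descriptors constant across all training chemicals are removed, then each
survivor is min-max scaled to [0, 1] using training-set extremes. Scaling
parameters are frozen with the model; external chemicals outside the fitted
range extrapolate linearly (values outside [0, 1]) rather than being
clipped, since clipping is an unstated extra transformation and trees are
threshold-based. Missing descriptor values are rejected at load time: the
upstream descriptor software emits complete tables, and silent imputation
would be an unstated modelling step.

Inside cross-validation the cleanup and scaling are refitted on each
training split by default, so no information from the held-out fold leaks
into preprocessing. A `global` mode preprocesses once on the full table
before splitting, reproducing the original single-pass order of operations;
the two modes differ negligibly on the synthetic regime but the leakage-free
default is the defensible one.

## Validation protocol

Cross-validation divides the chemicals at random into `n_folds` (default 5)
near-equal portions (unstratified by default, matching the plain "randomly
divided" protocol; a stratified option exists). Each portion is predicted
once per repeat by a forest trained on the rest; the five fold-level metric
reports are averaged into one per-repeat report and the run summary is the
mean ± standard deviation over repeats. Undefined fold metrics (a fold with
no actual positives) are skipped in the fold average rather than coerced
to 0; with 125 chemicals and 53 binders such folds essentially never occur.

The permutation test shuffles the label vector (preserving the class
multiset), runs one full k-fold CV per permutation and collects the
fold-averaged metrics as the chance null. The empirical p-value uses the
add-one rule `(1 + #{null ≥ observed}) / (1 + n_permutations)`, which
cannot report an impossible p = 0.

The five metrics are accuracy, sensitivity, specificity, Matthews
correlation coefficient and balanced accuracy, computed from TP/TN/FP/FN.
MCC is 0 by convention when a denominator factor vanishes; sensitivity,
specificity and balanced accuracy are reported absent (None/NaN) when the
relevant class is missing, rather than silently 0, to avoid misleading
aggregates. Reports round to 3 decimals; internal values keep full
precision.

### Confidence profile

Pooled CV predictions are placed into 20 even bins of
`confidence = |p − 0.5| / 0.5`: bins `[i/20, (i+1)/20)` for i = 0..18 and
the closed bin `[0.95, 1.0]` last, so confidence 1.0 is counted. Per-bin
accuracy is `n_correct / n_predictions`, absent for empty bins.

### Informative descriptors

A descriptor's frequency is the number of fitted models (forests) that used
it anywhere — once per model regardless of how many splits. CV frequencies
are compared against the permutation-background frequencies: the cutoff is
the smallest frequency f such that at most α (default 5%) of the
permutation frequencies strictly exceed f, and a descriptor is informative
when its CV frequency *strictly* exceeds the cutoff. With ties this flags
at most α of a null universe. The cutoff is a quantile across descriptors
of the permutation frequency distribution; the alternative reading (the
frequency of the descriptor at the 5% rank) coincides up to tie handling.

## Synthetic data

The generator emulates the statistical shape of a competitive-binding
training table, not chemistry: 125 chemicals × 777 raw descriptors, 265
constant columns (512 survive cleanup), 16 informative descriptors and a
53:72 binder:non-binder split by default. Each column gets a random
location and scale (heterogeneous raw ranges, normalized away by scaling).
Informative columns are class-conditional location shifts of a unit-normal
core: binder and non-binder means differ by `signal_strength` pooled
standard deviations, with alternating sign. Noise columns come in blocks of
`correlation_block_size` (default 4) sharing a latent factor at correlation
0.5, mimicking the heavy redundancy of real 2D descriptor sets. Labels can
be flipped with probability `label_noise` after the descriptors are drawn.

Defaults and why:

- `signal_strength = 1.0` — a one-SD shift makes each informative
  descriptor alone a weak classifier (optimal single-threshold accuracy
  ≈ 0.69), the moderate per-descriptor signal regime the original assay
  data displays; the forest combining several reaches ≈ 0.75 CV accuracy.
- `label_noise = 0.0` — competitive-assay binder calls are treated as
  reliable; class overlap already comes from descriptor noise. The flip
  option exists for robustness studies.
- Column structure (which columns are constant/informative, their
  locations and scales) derives from the spec seed alone, so an external
  set generated with a second seed shares the training set's descriptor
  universe exactly.

What passing tests on this generator do **not** show about real data:
descriptors here are (blockwise) Gaussian and the class signal is purely
additive per descriptor, whereas real 2D descriptors are discrete, skewed
and interact; recovery and separation results on synthetic data are
demonstrations of the machinery, not performance claims for any assay.

## Problem sizes and numerical choices

The shipped validation runs use 100 CV repeats and 100 permutations (500
models per arm) for the statistical checks, and 50/50 in the acceptance
script; these sizes give Monte-Carlo error well below the margins tested
while keeping a full run in the order of a minute. The full published
protocol (1000 repeats, 1000 permutations) is a parameter change.

Seeding is hierarchical: one master seed derives independent streams for
fold assignment, permutation shuffles and per-permutation CVs via numpy
`SeedSequence`, so every run is exactly reproducible and permutation i does
not depend on how many permutations precede it being inspected.

CSV round trips are bit-exact: floats are written as `%.17g` and parsed
with pandas' round-trip parser.

## Known limitations

- The pruning semantics of the original Decision Forest software are not
  fully documented; the bounded bottom-up collapse here is a reasoned,
  deterministic reconstruction.
- No applicability-domain geometry beyond the confidence score; no
  ROC/AUC or probability calibration.
- Descriptor computation from structures (Mold² or otherwise) is out of
  scope — the package consumes tabular descriptor exports. SDF files are
  not parsed.
- Trees handle only real-valued descriptors with binary labels; no
  multiway splits, categorical features or in-tree missing-value handling.
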