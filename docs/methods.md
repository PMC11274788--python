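# Methods

## Model and assumptions

`fcakit` classifies instances described by binary presence/absence
attributes. The model assumes that class membership is carried by
*combinations* of present attributes: each formal concept groups the
training images that share a set of attributes (the intent), and the
class profile of that group is what the classifier consults. No feature
independence, distributional, or linearity assumption is made; the cost
is that the concept count can grow up to 2^min(|G|,|M|), so the method is
intended for small attribute sets (tens, not thousands) such as the
bottleneck layer of an embedding network.

Prediction is nearest-intent in Hamming distance over labeled concepts
only. Concepts with empty extents (always the lattice bottom when no
training image carries every attribute) have no class profile and are
excluded as candidates. This makes the classifier a prototype method
whose prototypes are *closed* attribute sets — every prototype is
exactly the set of attributes shared by an actual group of training
images, which is what makes the if–then rule reading faithful.

## Binarization

Continuous features are mapped to attributes in two steps: per-feature
normalization, then one global threshold shared by all features.

- **Normalization** (default `minmax`): rescale each feature to [0, 1]
  using the training minimum and maximum. Held-out values are clipped to
  [0, 1] before thresholding, so test data can never leak statistics
  into the transform. `zscore` (threshold read on the z-scale) and
  `none` (threshold on raw values) are offered as options. Min-max is
  the default because it is the only choice under which a *single*
  threshold has the same meaning for every feature.
- **Threshold** (default 0.5): a value is an attribute-presence `1` iff
  it **strictly exceeds** the threshold after normalization. 0.5 is the
  midpoint of the normalized range; the strict inequality makes
  behaviour at ties reproducible (the training minimum, which maps to
  exactly 0, is never "present" even at threshold 0). The resolved
  threshold and normalization are logged on every run and stored in the
  model file.
- **Constant training features** carry no information; their bits are
  forced to 0 for all objects and a warning names them.

The normalization statistics are fitted once and immutable, so the
identical transform applies to training and held-out data.

## Enumeration and canonical order

Concepts are enumerated by Close-by-One (CbO) over attributes in file
order: starting from the top concept (G, G″), each step adds one
attribute, closes, and recurses only if the closure introduces no
attribute earlier than the one added. This generates each concept
exactly once in O(concepts × |M| × closure) time, comfortably fast for
16-attribute contexts where the naive closure of all 2^|M| subsets is
already borderline. The naive enumerator is retained as
`brute_force_concepts` (refusing min(|G|,|M|) > 16) and serves as the
independent oracle in the test suite: both enumerators must agree as
sets on randomized contexts.

Canonical concept order — used for indices, tie-breaks, and all exports —
is lexicographic on the intent's ascending attribute-index sequence, so
the top concept is always index 0 and two runs over the same context
number concepts identically. Lattice figures elsewhere may number
concepts differently; the package fixes its own order rather than
matching any figure.

The covering (Hasse) relation is the transitive reduction of extent
inclusion, computed by a direct bitset algorithm (for each concept,
accept a strict superset as a cover iff no already-accepted cover lies
below it). It is computed lazily: fitting and prediction never need it,
only the DOT/JSON exports do.

## Tie-breaking

The training and prediction procedure meets two genuinely arbitrary
choices; both are made deterministic and audited rather than randomized:

- **Majority ties** (a concept's extent has equal top class counts): the
  smallest class label in canonical order wins (labels sorted by their
  string form). Every such concept index is recorded in
  `TrainedModel.tie_log`.
- **Distance ties** (several labeled concepts at the minimal Hamming
  distance): the concept with the larger extent wins (more supporting
  objects), then the smaller canonical index. Each prediction reports
  `n_tied`, the number of concepts at the minimal distance, so users can
  audit how often the tie-break mattered.

Class tallies are duplicate-aware: deduplication collapses identical
training vectors but keeps every duplicate's label, so a concept's count
reflects images, not unique vectors, and the tally at the top concept
always equals the training-set size.

## Metrics

`evaluate` reports accuracy, sensitivity (TP/(TP+FN)), specificity
(TN/(TN+FP)) and F1 (2TP/(2TP+FP+FN)) as percentages, with the positive
class designating "malignant" (`"1"`) by default. A rate with a zero
denominator is reported as `None`/`undefined`, never silently 0.
Multi-class input is scored as overall accuracy plus one-vs-rest metrics
per class. The formulas are cross-checked against scikit-learn in the
test suite; scikit-learn is deliberately not used as the implementation
so the cross-check stays independent.

## Synthetic data

The generator emulates the regime the classifier targets: a two-class
image set described by 16 binarized high-level features (the width of a
small embedding head), each class owning a disjoint *signature* subset
of attributes (the attribute range split evenly by default). Within a
class, signature attributes fire with probability `p_signal` (default
0.9) and all others with `p_noise` (default 0.05). Continuous mode draws
Gaussians (mean 0.8 on signature features, 0.2 elsewhere, sd 0.15) so
the normalize-then-threshold step is exercised end to end; at the
default threshold the binarized output approximates the Bernoulli
pattern. All randomness flows through a single seed.

What it does *not* emulate: correlated features, class imbalance,
within-class substructure, and the covariance of real CNN embeddings.
Passing the recovery tests therefore shows the pipeline is correct and
that well-separated attribute signatures are recovered — not that any
particular accuracy transfers to real histopathology data, which would
additionally require the out-of-scope feature-extraction stage.

The recovery check fitted 200 training and 100 test rows over 12
attributes across 10 seeds per noise level — sizes chosen so the whole
suite stays interactive while keeping binomial noise on the accuracy
estimate around a percent.

## Numerical and degenerate-input choices

- Extents and intents are bitsets (Python integers) over canonical file
  order; Hamming distance and intersections are single word operations.
- A context with an all-zero row/column, a single object, or no
  attribute sharing is handled: the lattice always has exactly one top
  and one bottom (they coincide for single-concept contexts).
- An empty training set, non-binary vectors, feature-name mismatches,
  and NaN/Inf feature values are rejected with explicit errors; a
  single-class training set warns and predicts that class everywhere.
- Model files are versioned JSON (`fcakit-model/1`) containing the
  deduplicated context, tallies, labels, covering edges, tie log, and
  the fitted binarizer, so a saved model is fully inspectable.

## Known limitations

- Concept enumeration is exponential in the worst case; the intended
  operating range is ≲ 20 attributes.
- The lattice is static: adding training data means refitting. No
  incremental insertion procedure is provided.
- Predictions are hard labels; confidences attach to rules (concepts),
  not to individual predictions, and are not calibrated probabilities.
- Binarization discards within-feature magnitude beyond the threshold;
  features informative only in their continuous values lose that
  information.
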