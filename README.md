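# fcakit

Concept lattices and interpretable nearest-intent classification for
binarized image features.

Deep networks classify histopathology images well but give little insight
into *why* a tissue image is called benign or malignant. `fcakit`
implements the alternative route: take a small set of high-level features
(for example a 16-dimensional CNN embedding — feature extraction itself is
out of scope here, any numeric matrix works), binarize them with one
global threshold, and use **formal concept analysis (FCA)** to turn the
resulting objects × attributes table into a classifier whose every
decision can be read off a lattice diagram.

## The model

A *formal context* is a triple (G, M, I): objects G, binary attributes M,
and an incidence relation I. The derivation operators

- B′ = { g ∈ G : g has every attribute in B },
- A′ = { m ∈ M : every object in A has m }

form a Galois connection; a *formal concept* is a pair (A, B) with
A′ = B and B′ = A. All concepts, ordered by extent inclusion, form a
complete lattice whose Hasse diagram is the interpretability surface.

Training and prediction:

1. **Fit** — deduplicate the binary training vectors (keeping every
   duplicate's class label), enumerate all concepts of the deduplicated
   context with Close-by-One, and label each concept with a non-empty
   extent by the majority class of the images in its extent
   (ties → smallest class label, logged).
2. **Predict** — for a test vector x, compute the Hamming distance
   between x and the indicator vector of every labeled concept's intent;
   the nearest concept's class is the prediction (distance ties → the
   concept with the larger extent, then the smaller canonical index; the
   tie multiplicity is reported).
3. **Explain** — every labeled concept reads as a rule
   *IF all attributes of the intent THEN the majority class*, with
   duplicate-aware support and confidence; per-attribute class
   associations and attribute co-occurrence tables summarize the lattice.

## Worked example

The package ships a six-image context (objects `1`–`6`, attributes
`a`–`d`) small enough to trace by hand:

```python
from fcakit.datasets import demo_context, demo_labels
import fcakit as fk

ctx = demo_context()
print(ctx.derive_extent(["a", "b"]))     # ('2', '3', '4', '5')
print(ctx.derive_extent(["a", "b", "c"]))  # ('5',)

lat = fk.build_order(ctx)
print(len(lat), len(lat.covering_edges))  # 6 7

y = demo_labels()  # {'1': 0, '2': 1, '3': 1, '4': 1, '5': 1, '6': 0}
model = fk.fit(fk.TrainingSet(ctx.incidence, [y[o] for o in ctx.objects],
                              attributes=ctx.attributes, object_ids=ctx.objects))
print(fk.predict(model, [[1, 1, 0, 0], [1, 0, 1, 0]]))
```

prints

```
('2', '3', '4', '5')
('5',)
6 7
[Prediction(object_id='0', label=1, concept_index=1, distance=0, n_tied=1),
 Prediction(object_id='1', label=0, concept_index=5, distance=0, n_tied=1)]
```

The six concepts have intents {a}, {a,b}, {a,c}, {a,b,c}, {a,b,d} and
{a,b,c,d}. The test vector (1,1,0,0) lands at distance 0 on the concept
with intent {a,b}, whose four supporting images are all class 1, so it is
classified 1 with full confidence. The vector (1,0,1,0) hits the concept
with intent {a,c}, whose extent holds one image of each class; the
recorded 1:1 majority tie was resolved to class 0 (smallest label), and
`model.tie_log` shows exactly where that arbitrariness entered.

The same pipeline from the shell, on generated data:

```sh
fcakit synth --mode continuous --n-per-class 100 --seed 1 \
       --out-features X.csv --out-labels y.csv
fcakit fit --features X.csv --labels y.csv --model model.json --threshold 0.5
fcakit predict --model model.json --features X.csv --out preds.csv
fcakit evaluate --truth y.csv --predictions preds.csv --positive 1
fcakit rules --model model.json
fcakit export-dot --model model.json --out lattice.dot
```

`evaluate` prints the conventional benchmark columns
(Accuracy % / Sensitivity % / Specificity % / F1 Score %), with malignant
(`1`) as the default positive class.

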