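"""Lattice-based nearest-intent classification and rule extraction.

Training builds a concept lattice over the *unique* training vectors:
duplicate rows are collapsed but every duplicate keeps its class label, so
a concept's class tally counts images, not unique vectors.  Each concept
with a non-empty extent is labeled by the majority class of the images in
its extent; concepts whose extent is empty (typically the bottom of the
lattice) stay unlabeled.  A new instance is classified by computing the
Hamming distance between its binary feature vector and the indicator
vector of every labeled concept's intent and taking the label of the
nearest concept.

Both tie situations the procedure can meet are resolved deterministically
and audited:

* majority ties — the smallest class label in canonical (sorted) label
  order wins; the concept index is recorded in ``TrainedModel.tie_log``;
* distance ties — the concept with the larger extent (more supporting
  objects) wins, then the smaller canonical concept index; the number of
  concepts tied at the minimal distance is reported per prediction as
  ``Prediction.n_tied``.

Every labeled concept also reads as an if–then rule: IF an image has all
attributes of the intent THEN it belongs to the concept's majority class,
with duplicate-aware support and confidence.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .context import Binarizer, ContextError, FormalContext, iter_bits
from .lattice import ConceptLattice, FormalConcept, build_order, enumerate_concepts

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "TrainedModel",
    "Prediction",
    "Rule",
    "fit",
    "hamming",
    "predict",
    "extract_rules",
    "feature_class_summary",
    "FeatureClassSummary",
]

MODEL_SCHEMA = "fcakit-model/1"


def _label_sort_key(label: Hashable) -> str:
    # Canonical label order: lexicographic on the string form, so mixed
    # int/str label sets still sort deterministically.
    return str(label)


def _as_binary_matrix(vectors) -> np.ndarray:
    arr = np.asarray(vectors)
    if arr.ndim != 2:
        raise ContextError(f"expected a 2-D binary matrix, got shape {arr.shape}")
    if arr.size and not np.isin(arr, (0, 1, False, True)).all():
        raise ContextError("feature vectors must be binary (0/1)")
    return arr.astype(np.uint8)


@dataclass
class TrainingSet:
    """Binary training vectors with per-row class labels.

    ``attributes`` names the feature columns (defaults to ``f0..f{m-1}``);
    ``object_ids`` names the rows (defaults to row numbers) and is used to
    identify the representative of each group of duplicate vectors.
    """

    vectors: np.ndarray
    labels: Sequence[Hashable]
    attributes: tuple[str, ...] | None = None
    object_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.vectors = _as_binary_matrix(self.vectors)
        self.labels = list(self.labels)
        n, m = self.vectors.shape
        if n == 0:
            raise ContextError("training set is empty")
        if len(self.labels) != n:
            raise ContextError(
                f"{len(self.labels)} labels for {n} training vectors"
            )
        if self.attributes is None:
            self.attributes = tuple(f"f{j}" for j in range(m))
        else:
            self.attributes = tuple(self.attributes)
            if len(self.attributes) != m:
                raise ContextError("attribute names do not match vector width")
        if self.object_ids is None:
            self.object_ids = tuple(str(i) for i in range(n))
        else:
            self.object_ids = tuple(str(o) for o in self.object_ids)
            if len(self.object_ids) != n:
                raise ContextError("object_ids do not match vector count")
        if len(set(self.labels)) < 2:
            warnings.warn(
                "training set has a single class; every prediction will "
                "return that class", stacklevel=2,
            )


@dataclass(frozen=True)
class Prediction:
    """One classified instance: label, winning concept, and tie audit."""

    object_id: str
    label: Hashable
    concept_index: int
    distance: int
    n_tied: int


@dataclass(frozen=True)
class Rule:
    """IF all attributes of ``intent`` THEN ``label`` (majority class).

    ``support`` counts the training images in the concept's extent
    (duplicate-aware); ``confidence`` is the majority share of that count.
    """

    intent: tuple[str, ...]
    label: Hashable
    support: int
    confidence: float
    concept_index: int


@dataclass
class TrainedModel:
    """A fitted lattice classifier (deduplicated vectors, tallies, labels)."""

    attributes: tuple[str, ...]
    unique_vectors: np.ndarray
    unique_ids: tuple[str, ...]
    label_multisets: tuple[tuple[Hashable, ...], ...]
    lattice: ConceptLattice
    concept_labels: tuple[Hashable | None, ...]
    concept_counts: tuple[dict, ...]
    tie_log: tuple[int, ...]
    label_order: tuple[Hashable, ...]
    binarizer: Binarizer | None = None

    @property
    def n_training_rows(self) -> int:
        return sum(len(ms) for ms in self.label_multisets)

    def labeled_concepts(self) -> list[FormalConcept]:
        return [
            c for c in self.lattice.concepts
            if self.concept_labels[c.index] is not None
        ]

    def concept_label_map(self) -> dict[int, Hashable]:
        """Concept index → class label, for annotated lattice exports."""
        return {
            i: lbl for i, lbl in enumerate(self.concept_labels) if lbl is not None
        }

    # -- persistence -----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "schema": MODEL_SCHEMA,
            "attributes": list(self.attributes),
            "unique_ids": list(self.unique_ids),
            "unique_vectors": self.unique_vectors.astype(int).tolist(),
            "label_multisets": [list(ms) for ms in self.label_multisets],
            "label_order": list(self.label_order),
            "concept_labels": list(self.concept_labels),
            "concept_counts": [
                sorted(c.items(), key=lambda kv: _label_sort_key(kv[0]))
                for c in self.concept_counts
            ],
            "tie_log": list(self.tie_log),
            "edges": [list(e) for e in self.lattice.covering_edges],
            "binarizer": self.binarizer.to_dict() if self.binarizer else None,
        }

    @classmethod
    def from_json(cls, d: Mapping) -> "TrainedModel":
        if d.get("schema") != MODEL_SCHEMA:
            raise ValueError(f"unsupported model schema: {d.get('schema')!r}")
        attributes = tuple(d["attributes"])
        unique_vectors = np.asarray(d["unique_vectors"], dtype=np.uint8)
        unique_vectors = unique_vectors.reshape(len(d["unique_ids"]), len(attributes))
        ctx = FormalContext(d["unique_ids"], attributes, unique_vectors)
        lattice = build_order(ctx)
        lattice._covering_edges = [tuple(e) for e in d["edges"]]
        return cls(
            attributes=attributes,
            unique_vectors=unique_vectors,
            unique_ids=tuple(d["unique_ids"]),
            label_multisets=tuple(tuple(ms) for ms in d["label_multisets"]),
            lattice=lattice,
            concept_labels=tuple(d["concept_labels"]),
            concept_counts=tuple(dict(c) for c in d["concept_counts"]),
            tie_log=tuple(d["tie_log"]),
            label_order=tuple(d["label_order"]),
            binarizer=Binarizer.from_dict(d["binarizer"]) if d["binarizer"] else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))

    # -- convenience -----------------------------------------------------

    def predict(self, test, attributes=None, object_ids=None) -> list[Prediction]:
        return predict(self, test, attributes=attributes, object_ids=object_ids)


def fit(train: TrainingSet, binarizer: Binarizer | None = None) -> TrainedModel:
    """Fit the lattice classifier.

    Deduplicates rows preserving first-occurrence order, accumulates the
    label multiset of each unique vector, builds the concept lattice over
    the deduplicated context, and labels every non-empty-extent concept
    with the majority class of the images in its extent (majority ties go
    to the smallest class label in canonical order and are logged).
    """
    seen: dict[bytes, int] = {}
    unique_rows: list[np.ndarray] = []
    unique_ids: list[str] = []
    multisets: list[list[Hashable]] = []
    for row, label, oid in zip(train.vectors, train.labels, train.object_ids):
        key = row.tobytes()
        at = seen.get(key)
        if at is None:
            seen[key] = len(unique_rows)
            unique_rows.append(row)
            unique_ids.append(oid)
            multisets.append([label])
        else:
            multisets[at].append(label)

    unique = np.vstack(unique_rows)
    ctx = FormalContext(unique_ids, train.attributes, unique)
    lattice = build_order(ctx, enumerate_concepts(ctx))

    label_order = tuple(sorted(set(train.labels), key=_label_sort_key))
    concept_labels: list[Hashable | None] = []
    concept_counts: list[dict] = []
    tie_log: list[int] = []
    for c in lattice.concepts:
        counts: Counter = Counter()
        for i in iter_bits(c.extent_bits):
            counts.update(multisets[i])
        concept_counts.append(dict(counts))
        if not counts:
            concept_labels.append(None)  # empty extent: no images, no class
            continue
        best = max(counts.values())
        winners = sorted(
            (lbl for lbl, n in counts.items() if n == best), key=_label_sort_key
        )
        if len(winners) > 1:
            tie_log.append(c.index)
        concept_labels.append(winners[0])

    logger.info(
        "fitted lattice classifier: %d images -> %d unique vectors, "
        "%d concepts (%d labeled, %d majority ties)",
        len(train.labels), len(unique_ids), len(lattice),
        sum(l is not None for l in concept_labels), len(tie_log),
    )
    return TrainedModel(
        attributes=train.attributes,
        unique_vectors=unique,
        unique_ids=tuple(unique_ids),
        label_multisets=tuple(tuple(ms) for ms in multisets),
        lattice=lattice,
        concept_labels=tuple(concept_labels),
        concept_counts=tuple(concept_counts),
        tie_log=tuple(tie_log),
        label_order=label_order,
        binarizer=binarizer,
    )


def hamming(x: Sequence[int], intent: Sequence[str], attributes: Sequence[str]) -> int:
    """Hamming distance between a binary vector and an intent's indicator.

    ``x`` is read over the full attribute list ``attributes``; ``intent``
    is the subset of attributes present in the concept.
    """
    x = np.asarray(x).ravel()
    if len(x) != len(attributes):
        raise ContextError(
            f"vector length {len(x)} does not match {len(attributes)} attributes"
        )
    attr_set = set(intent)
    unknown = attr_set - set(attributes)
    if unknown:
        raise ContextError(f"intent attributes not in attribute list: {sorted(unknown)}")
    indicator = np.array([a in attr_set for a in attributes])
    return int((x.astype(bool) != indicator).sum())


def predict(
    model: TrainedModel,
    test,
    attributes: Sequence[str] | None = None,
    object_ids: Sequence[str] | None = None,
) -> list[Prediction]:
    """Classify each row of ``test`` by its nearest labeled intent.

    Distances are computed to every *labeled* concept (empty-extent
    concepts cannot supply a class and are excluded).  Ties at the minimal
    distance are broken toward the larger extent, then the smaller
    concept index, and the tie multiplicity is reported per row.
    """
    X = _as_binary_matrix(test)
    if X.shape[1] != len(model.attributes):
        raise ContextError(
            f"test vectors have {X.shape[1]} columns, model expects "
            f"{len(model.attributes)}"
        )
    if attributes is not None and tuple(attributes) != model.attributes:
        raise ContextError(
            "test attribute names/order do not match the fitted model"
        )
    if object_ids is None:
        object_ids = tuple(str(i) for i in range(X.shape[0]))
    candidates = [
        (c.intent_bits, c.extent_bits.bit_count(), c.index,
         model.concept_labels[c.index])
        for c in model.lattice.concepts
        if model.concept_labels[c.index] is not None
    ]
    if not candidates:
        raise ContextError("model has no labeled concepts; cannot predict")

    weights = 1 << np.arange(X.shape[1], dtype=object)
    out: list[Prediction] = []
    for oid, row in zip(object_ids, X):
        xbits = int((row.astype(object) * weights).sum())
        best: tuple[int, int, int] | None = None  # (distance, -extent, index)
        best_label = None
        n_tied = 0
        for intent_bits, extent_size, index, label in candidates:
            d = (xbits ^ intent_bits).bit_count()
            key = (d, -extent_size, index)
            if best is None or d < best[0]:
                best, best_label, n_tied = key, label, 1
            elif d == best[0]:
                n_tied += 1
                if key < best:
                    best, best_label = key, label
        out.append(
            Prediction(
                object_id=str(oid),
                label=best_label,
                concept_index=best[2],
                distance=best[0],
                n_tied=n_tied,
            )
        )
    return out


def extract_rules(model: TrainedModel) -> list[Rule]:
    """One if–then rule per labeled concept, sorted by confidence then
    support (descending), with the concept index as final tie-break."""
    rules = []
    for c in model.lattice.concepts:
        label = model.concept_labels[c.index]
        if label is None:
            continue
        counts = model.concept_counts[c.index]
        support = sum(counts.values())
        confidence = counts[label] / support
        rules.append(
            Rule(
                intent=c.intent,
                label=label,
                support=support,
                confidence=confidence,
                concept_index=c.index,
            )
        )
    rules.sort(key=lambda r: (-r.confidence, -r.support, r.concept_index))
    return rules


@dataclass
class FeatureClassSummary:
    """Per-attribute class associations over the labeled concepts.

    ``association`` counts, for each attribute, the labeled concepts whose
    intent contains it, split by the concept's class; ``cooccurrence``
    counts labeled concepts whose intent contains both attributes of a
    pair; ``never_cooccur`` lists attribute pairs that share no labeled
    intent — candidates for mutually exclusive features.
    """

    association: pd.DataFrame
    cooccurrence: pd.DataFrame
    never_cooccur: list[tuple[str, str]]


def feature_class_summary(model: TrainedModel) -> FeatureClassSummary:
    attrs = model.attributes
    labels = model.label_order
    assoc = pd.DataFrame(0, index=list(attrs), columns=list(labels))
    cooc = pd.DataFrame(0, index=list(attrs), columns=list(attrs))
    for c in model.lattice.concepts:
        label = model.concept_labels[c.index]
        if label is None:
            continue
        for a in c.intent:
            assoc.loc[a, label] += 1
            for b in c.intent:
                cooc.loc[a, b] += 1
    never = [
        (attrs[i], attrs[j])
        for i in range(len(attrs))
        for j in range(i + 1, len(attrs))
        if cooc.iloc[i, j] == 0
    ]
    return FeatureClassSummary(association=assoc, cooccurrence=cooc, never_cooccur=never)
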