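"""Formal contexts, derivation operators, and feature binarization.

A *formal context* is a triple (G, M, I): a finite set of objects G, a
finite set of attributes M, and a binary incidence relation I between them
recording which objects carry which attributes.  The two derivation
(prime) operators

* ``derive_extent(B)`` — the objects that share *all* attributes in B, and
* ``derive_intent(A)`` — the attributes shared by *all* objects in A,

form a Galois connection between the powersets of G and M.  Their
composition is a closure operator on attribute sets; the closed attribute
sets are exactly the intents of the formal concepts enumerated in
:mod:`fcakit.lattice`.

The module also handles the preprocessing step that turns a real-valued
feature matrix (e.g. an embedding produced by a convolutional network)
into a formal context: per-feature normalization followed by a single
global threshold, so that each binary attribute records the presence or
absence of one high-level feature.

Extents and intents are represented internally as Python integers used as
bitsets — bit ``i`` of an extent is object ``i`` in canonical (file) order,
bit ``j`` of an intent is attribute ``j``.  All public functions speak in
object identifiers and attribute names.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContextError",
    "ParseError",
    "FormalContext",
    "FeatureMatrix",
    "Binarizer",
    "fit_binarizer",
    "binarize",
    "read_context",
    "write_context",
    "parse_context_csv",
    "parse_context_cxt",
    "context_to_csv",
    "context_to_cxt",
    "read_feature_matrix",
    "read_labels",
]


class ContextError(ValueError):
    """Invalid formal context, feature matrix, or derivation argument."""


class ParseError(ContextError):
    """Malformed context or feature file; the message names line/column."""


def _check_unique(names: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ContextError(f"duplicate {kind} identifier: {n!r}")
        seen.add(n)


def iter_bits(bits: int):
    """Yield the indices of the set bits of ``bits``, ascending."""
    while bits:
        low = bits & -bits
        yield low.bit_length() - 1
        bits ^= low


class FormalContext:
    """An objects × attributes binary incidence table.

    Parameters
    ----------
    objects : sequence of str
        Unique object identifiers; their order is the canonical object
        order used for all deterministic tie-breaking downstream.
    attributes : sequence of str
        Unique attribute names, in canonical order.
    incidence : array-like of 0/1, shape (len(objects), len(attributes))
    """

    __slots__ = (
        "objects",
        "attributes",
        "incidence",
        "_obj_index",
        "_attr_index",
        "_row_bits",
        "_col_bits",
        "_all_objects_bits",
        "_all_attributes_bits",
    )

    def __init__(
        self,
        objects: Sequence[str],
        attributes: Sequence[str],
        incidence,
    ) -> None:
        objects = tuple(str(o) for o in objects)
        attributes = tuple(str(a) for a in attributes)
        _check_unique(objects, "object")
        _check_unique(attributes, "attribute")
        inc = np.asarray(incidence)
        if inc.ndim != 2 or inc.shape != (len(objects), len(attributes)):
            raise ContextError(
                f"incidence shape {inc.shape} does not match "
                f"{len(objects)} objects x {len(attributes)} attributes"
            )
        if inc.size and not np.isin(inc, (0, 1, False, True)).all():
            raise ContextError("incidence entries must be exactly 0 or 1")
        self.objects = objects
        self.attributes = attributes
        self.incidence = inc.astype(bool)
        self._obj_index = {o: i for i, o in enumerate(objects)}
        self._attr_index = {a: j for j, a in enumerate(attributes)}
        self._row_bits = [
            int(sum(1 << j for j in np.flatnonzero(self.incidence[i])))
            for i in range(len(objects))
        ]
        self._col_bits = [
            int(sum(1 << i for i in np.flatnonzero(self.incidence[:, j])))
            for j in range(len(attributes))
        ]
        self._all_objects_bits = (1 << len(objects)) - 1
        self._all_attributes_bits = (1 << len(attributes)) - 1

    # -- basic properties ------------------------------------------------

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FormalContext):
            return NotImplemented
        return (
            self.objects == other.objects
            and self.attributes == other.attributes
            and np.array_equal(self.incidence, other.incidence)
        )

    def __repr__(self) -> str:
        return (
            f"FormalContext({self.n_objects} objects, "
            f"{self.n_attributes} attributes, "
            f"{int(self.incidence.sum())} incidences)"
        )

    # -- name <-> bitset conversions -------------------------------------

    def attrs_to_bits(self, attrs: Iterable[str]) -> int:
        bits = 0
        unknown = []
        for a in attrs:
            j = self._attr_index.get(a)
            if j is None:
                unknown.append(a)
            else:
                bits |= 1 << j
        if unknown:
            raise ContextError(f"unknown attribute name(s): {sorted(unknown)}")
        return bits

    def objs_to_bits(self, objs: Iterable[str]) -> int:
        bits = 0
        unknown = []
        for o in objs:
            i = self._obj_index.get(o)
            if i is None:
                unknown.append(o)
            else:
                bits |= 1 << i
        if unknown:
            raise ContextError(f"unknown object identifier(s): {sorted(unknown)}")
        return bits

    def bits_to_attrs(self, bits: int) -> tuple[str, ...]:
        return tuple(self.attributes[j] for j in iter_bits(bits))

    def bits_to_objs(self, bits: int) -> tuple[str, ...]:
        return tuple(self.objects[i] for i in iter_bits(bits))

    # -- derivation operators on bitsets ---------------------------------

    def extent_bits(self, intent_bits: int) -> int:
        """Objects sharing every attribute in ``intent_bits``."""
        e = self._all_objects_bits
        for j in iter_bits(intent_bits):
            e &= self._col_bits[j]
        return e

    def intent_bits(self, extent_bits: int) -> int:
        """Attributes shared by every object in ``extent_bits``."""
        m = 0
        for j, col in enumerate(self._col_bits):
            if extent_bits & col == extent_bits:
                m |= 1 << j
        return m

    # -- derivation operators on names -----------------------------------

    def derive_extent(self, attrs: Iterable[str]) -> tuple[str, ...]:
        """Objects whose rows have a 1 for every attribute in ``attrs``.

        The empty attribute set derives the full object set.
        """
        return self.bits_to_objs(self.extent_bits(self.attrs_to_bits(attrs)))

    def derive_intent(self, objs: Iterable[str]) -> tuple[str, ...]:
        """Attributes common to every object in ``objs`` (all, if empty)."""
        e = self.objs_to_bits(objs)
        return self.bits_to_attrs(self.intent_bits(e))

    def closure(self, attrs: Iterable[str]) -> tuple[str, ...]:
        """Double derivation B'' — the smallest intent containing ``attrs``."""
        b = self.attrs_to_bits(attrs)
        return self.bits_to_attrs(self.intent_bits(self.extent_bits(b)))


# Module-level aliases matching the functional surface.

def derive_extent(ctx: FormalContext, attrs: Iterable[str]) -> tuple[str, ...]:
    return ctx.derive_extent(attrs)


def derive_intent(ctx: FormalContext, objs: Iterable[str]) -> tuple[str, ...]:
    return ctx.derive_intent(objs)


def closure(ctx: FormalContext, attrs: Iterable[str]) -> tuple[str, ...]:
    return ctx.closure(attrs)


# ---------------------------------------------------------------------------
# Context file I/O
# ---------------------------------------------------------------------------

def parse_context_csv(text: str) -> FormalContext:
    """Parse the CSV context dialect.

    Header row ``object,<attr1>,...,<attrM>``; one row per object; cells
    strictly ``0`` or ``1``.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise ParseError("empty context file")
    header = [c.strip() for c in lines[0].split(",")]
    if not header or header[0] != "object":
        raise ParseError("line 1: header must start with 'object'")
    attributes = header[1:]
    objects: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} cells, got {len(cells)}"
            )
        objects.append(cells[0])
        row = []
        for col, cell in enumerate(cells[1:], start=2):
            if cell not in ("0", "1"):
                raise ParseError(
                    f"line {lineno}, column {col}: non-binary cell {cell!r}"
                )
            row.append(int(cell))
        rows.append(row)
    try:
        return FormalContext(objects, attributes,
                             np.array(rows, dtype=int).reshape(len(objects), len(attributes)))
    except ContextError as exc:
        raise ParseError(str(exc)) from exc


def context_to_csv(ctx: FormalContext) -> str:
    buf = io.StringIO()
    buf.write("object," + ",".join(ctx.attributes) + "\n")
    for i, o in enumerate(ctx.objects):
        bits = ",".join("1" if v else "0" for v in ctx.incidence[i])
        buf.write(o + ("," + bits if ctx.n_attributes else "") + "\n")
    return buf.getvalue()


def parse_context_cxt(text: str) -> FormalContext:
    """Parse a Burmeister CXT file.

    Line 1 ``B``, a blank line, object and attribute counts, then the
    object names, attribute names, and one ``.``/``X`` row per object.
    """
    lines = text.splitlines()
    if not lines or lines[0].strip() != "B":
        raise ParseError("line 1: Burmeister file must start with 'B'")
    # Tolerate blank separator lines anywhere in the header block.
    body = [(i + 1, ln) for i, ln in enumerate(lines[1:], start=1) if ln.strip() != ""]
    if len(body) < 2:
        raise ParseError("missing object/attribute counts")
    try:
        n_obj = int(body[0][1].strip())
        n_attr = int(body[1][1].strip())
    except ValueError as exc:
        raise ParseError(f"line {body[0][0]}-{body[1][0]}: counts must be integers") from exc
    need = 2 + n_obj + n_attr + n_obj
    if len(body) < need:
        raise ParseError(
            f"expected {need} non-blank lines after 'B', got {len(body)}"
        )
    objects = [ln for _, ln in body[2 : 2 + n_obj]]
    attributes = [ln for _, ln in body[2 + n_obj : 2 + n_obj + n_attr]]
    rows = []
    for lineno, ln in body[2 + n_obj + n_attr : need]:
        if len(ln) != n_attr:
            raise ParseError(
                f"line {lineno}: incidence row has {len(ln)} symbols, expected {n_attr}"
            )
        row = []
        for col, ch in enumerate(ln, start=1):
            if ch == "X":
                row.append(1)
            elif ch == ".":
                row.append(0)
            else:
                raise ParseError(
                    f"line {lineno}, column {col}: symbol {ch!r} is not '.' or 'X'"
                )
        rows.append(row)
    try:
        return FormalContext(objects, attributes,
                             np.array(rows, dtype=int).reshape(n_obj, n_attr))
    except ContextError as exc:
        raise ParseError(str(exc)) from exc


def context_to_cxt(ctx: FormalContext) -> str:
    out = ["B", "", str(ctx.n_objects), str(ctx.n_attributes)]
    out.extend(ctx.objects)
    out.extend(ctx.attributes)
    for i in range(ctx.n_objects):
        out.append("".join("X" if v else "." for v in ctx.incidence[i]))
    return "\n".join(out) + "\n"


def _detect_format(source: str) -> str:
    return "cxt" if source.lstrip().startswith("B\n") or source.strip() == "B" else "csv"


def read_context(path_or_text: str | Path, format: str | None = None) -> FormalContext:
    """Read a formal context from a CSV or Burmeister CXT file (or literal text).

    ``format`` may be ``"csv"`` or ``"cxt"``; when omitted it is inferred
    from the file suffix, falling back to content sniffing.
    """
    p = Path(path_or_text) if not isinstance(path_or_text, Path) else path_or_text
    try:
        is_file = p.is_file()
    except OSError:  # text blobs with newlines are not valid paths
        is_file = False
    if is_file:
        text = p.read_text(encoding="utf-8")
        if format is None:
            format = "cxt" if p.suffix.lower() == ".cxt" else "csv"
    else:
        text = str(path_or_text)
        if format is None:
            format = _detect_format(text)
    if format == "cxt":
        return parse_context_cxt(text)
    if format == "csv":
        return parse_context_csv(text)
    raise ValueError(f"unknown context format: {format!r}")


def write_context(ctx: FormalContext, path: str | Path, format: str | None = None) -> None:
    p = Path(path)
    if format is None:
        format = "cxt" if p.suffix.lower() == ".cxt" else "csv"
    text = context_to_cxt(ctx) if format == "cxt" else context_to_csv(ctx)
    p.write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# Feature matrices and binarization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureMatrix:
    """A real-valued objects × features matrix (e.g. CNN embeddings)."""

    objects: tuple[str, ...]
    features: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.objects, "object")
        _check_unique(self.features, "feature")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(self.objects), len(self.features)):
            raise ContextError(
                f"values shape {vals.shape} does not match "
                f"{len(self.objects)} objects x {len(self.features)} features"
            )
        if vals.size and not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ContextError(
                f"non-finite value at object {self.objects[bad[0]]!r}, "
                f"feature {self.features[bad[1]]!r}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def n_features(self) -> int:
        return len(self.features)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a ``object,<feat1>,...,<featN>`` CSV of real-valued features."""
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "object":
        raise ParseError("feature CSV header must start with 'object'")
    return FeatureMatrix(
        objects=tuple(df.iloc[:, 0].astype(str)),
        features=tuple(str(c) for c in df.columns[1:]),
        values=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a ``object,label`` CSV into an object → label mapping."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["object", "label"]:
        raise ParseError("labels CSV header must be 'object,label'")
    _check_unique(tuple(df["object"]), "object")
    return dict(zip(df["object"], df["label"]))


_NORMALIZATIONS = ("minmax", "zscore", "none")


@dataclass
class Binarizer:
    """Normalize features and apply one global presence threshold.

    A value is mapped to 1 when it **strictly exceeds** the threshold
    after normalization, and 0 otherwise, so each attribute of the
    resulting context marks the presence of one feature.  The same scalar
    threshold applies to every feature.

    Parameters
    ----------
    normalization : {"minmax", "zscore", "none"}
        ``minmax`` rescales each feature to [0, 1] using the training
        minimum and maximum (held-out values are clipped back into [0, 1]
        before thresholding); ``zscore`` standardizes each feature with
        the training mean and standard deviation, in which case the
        threshold is read on the z-scale; ``none`` thresholds raw values.
    threshold : float
        The single global threshold, in [0, 1] for ``minmax``.

    The normalization statistics are learned once from a training matrix
    by :meth:`fit` and are immutable afterwards, so the identical
    transform applies to held-out data.  Constant training features carry
    no information and are mapped to 0 for every object (and logged).
    """

    normalization: str = "minmax"
    threshold: float = 0.5
    feature_names_: tuple[str, ...] | None = field(default=None, repr=False)
    shift_: np.ndarray | None = field(default=None, repr=False)
    scale_: np.ndarray | None = field(default=None, repr=False)
    constant_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {_NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )
        if self.normalization == "minmax" and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("minmax threshold must lie in [0, 1]")

    @property
    def fitted(self) -> bool:
        return self.feature_names_ is not None

    def fit(self, train: FeatureMatrix) -> "Binarizer":
        if self.fitted:
            raise ValueError("Binarizer is already fitted; statistics are immutable")
        if train.n_objects == 0:
            raise ContextError("cannot fit a binarizer on an empty feature matrix")
        vals = train.values
        if self.normalization == "minmax":
            lo = vals.min(axis=0)
            hi = vals.max(axis=0)
            self.shift_ = lo
            self.scale_ = hi - lo
            self.constant_ = self.scale_ == 0
        elif self.normalization == "zscore":
            self.shift_ = vals.mean(axis=0)
            self.scale_ = vals.std(axis=0, ddof=1) if train.n_objects > 1 else np.zeros(train.n_features)
            self.constant_ = self.scale_ == 0
        else:  # none
            self.shift_ = np.zeros(train.n_features)
            self.scale_ = np.ones(train.n_features)
            self.constant_ = (vals == vals[0]).all(axis=0) if train.n_objects else np.zeros(train.n_features, bool)
        self.feature_names_ = train.features
        n_const = int(self.constant_.sum())
        if n_const:
            names = [f for f, c in zip(train.features, self.constant_) if c]
            logger.warning(
                "constant training feature(s) %s carry no information; "
                "their bits are forced to 0", names,
            )
        logger.info(
            "fitted %s binarizer on %d objects x %d features (threshold=%g)",
            self.normalization, train.n_objects, train.n_features, self.threshold,
        )
        return self

    def transform(self, m: FeatureMatrix) -> FormalContext:
        if not self.fitted:
            raise ValueError("Binarizer must be fitted before transform")
        if m.features != self.feature_names_:
            raise ContextError(
                "feature names/order mismatch: binarizer was fitted on "
                f"{list(self.feature_names_)}, got {list(m.features)}"
            )
        scale = np.where(self.scale_ == 0, 1.0, self.scale_)
        norm = (m.values - self.shift_) / scale
        if self.normalization == "minmax":
            norm = np.clip(norm, 0.0, 1.0)
        bits = norm > self.threshold
        bits[:, self.constant_] = False
        return FormalContext(m.objects, m.features, bits)

    def fit_transform(self, train: FeatureMatrix) -> FormalContext:
        return self.fit(train).transform(train)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {"normalization": self.normalization, "threshold": self.threshold}
        if self.fitted:
            d.update(
                feature_names=list(self.feature_names_),
                shift=[float(x) for x in self.shift_],
                scale=[float(x) for x in self.scale_],
                constant=[bool(x) for x in self.constant_],
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Binarizer":
        b = cls(normalization=d["normalization"], threshold=d["threshold"])
        if "feature_names" in d:
            b.feature_names_ = tuple(d["feature_names"])
            b.shift_ = np.asarray(d["shift"], dtype=float)
            b.scale_ = np.asarray(d["scale"], dtype=float)
            b.constant_ = np.asarray(d["constant"], dtype=bool)
        return b


def fit_binarizer(train: FeatureMatrix, spec: Binarizer | None = None) -> Binarizer:
    """Fit ``spec`` (or a default min-max/0.5 binarizer) on ``train``."""
    return (spec if spec is not None else Binarizer()).fit(train)


def binarize(m: FeatureMatrix, fitted: Binarizer) -> FormalContext:
    """Apply a fitted binarizer, yielding a formal context over ``m``."""
    return fitted.transform(m)
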