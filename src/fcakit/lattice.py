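"""Concept enumeration and the concept lattice (Hasse order, exports).

A formal concept of a context (G, M, I) is a pair (A, B) with A ⊆ G,
B ⊆ M, A' = B and B' = A: the extent A is exactly the set of objects
sharing all attributes of the intent B, and vice versa.  Ordered by
extent inclusion, the concepts form a complete lattice; its transitive
reduction (the covering relation) is the Hasse diagram users read to
interpret a trained model.

Enumeration uses Close-by-One (CbO) over attributes in canonical (file)
order: starting from the top concept (G, G''), each recursion step adds
one attribute, closes, and descends only when the closure introduces no
attribute earlier than the one added — the canonicity test that ensures
each concept is generated exactly once.  A brute-force enumerator that
closes every subset of the smaller side of the context is kept as an
independent oracle for testing.

Concept indices are canonical: concepts are sorted by their intents
compared as ascending attribute-index sequences (lexicographically), so
the top concept is always index 0 and any two runs over the same context
number concepts identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .context import ContextError, FormalContext, iter_bits

__all__ = [
    "FormalConcept",
    "ConceptLattice",
    "enumerate_concepts",
    "brute_force_concepts",
    "build_order",
    "export_dot",
    "lattice_to_json",
]

_BRUTE_FORCE_LIMIT = 16


@dataclass(frozen=True)
class FormalConcept:
    """An (extent, intent) pair with its canonical enumeration index."""

    extent: tuple[str, ...]
    intent: tuple[str, ...]
    index: int
    extent_bits: int = field(repr=False, compare=False, default=0)
    intent_bits: int = field(repr=False, compare=False, default=0)


def _concepts_from_pairs(
    ctx: FormalContext, pairs: Iterable[tuple[int, int]]
) -> list[FormalConcept]:
    """Sort (extent_bits, intent_bits) pairs canonically and wrap them."""
    ordered = sorted(set(pairs), key=lambda p: tuple(iter_bits(p[1])))
    return [
        FormalConcept(
            extent=ctx.bits_to_objs(e),
            intent=ctx.bits_to_attrs(i),
            index=k,
            extent_bits=e,
            intent_bits=i,
        )
        for k, (e, i) in enumerate(ordered)
    ]


def enumerate_concepts(ctx: FormalContext) -> list[FormalConcept]:
    """Enumerate every formal concept of ``ctx`` exactly once (Close-by-One).

    Returns the concepts in canonical order (lexicographic on the intent's
    attribute-index sequence); ``concept.index`` records the position.
    """
    n = ctx.n_attributes
    pairs: list[tuple[int, int]] = []

    def rec(extent: int, intent: int, start: int) -> None:
        pairs.append((extent, intent))
        for j in range(start, n):
            if intent >> j & 1:
                continue
            new_extent = extent & ctx._col_bits[j]
            new_intent = ctx.intent_bits(new_extent)
            mask = (1 << j) - 1
            if new_intent & mask == intent & mask:  # canonicity test
                rec(new_extent, new_intent, j + 1)

    top_extent = ctx._all_objects_bits
    rec(top_extent, ctx.intent_bits(top_extent), 0)
    return _concepts_from_pairs(ctx, pairs)


def brute_force_concepts(ctx: FormalContext) -> list[FormalConcept]:
    """Exhaustive oracle: close every subset of the smaller of G and M.

    Deduplicated and returned in the same canonical order as
    :func:`enumerate_concepts`.  Refuses contexts whose smaller side
    exceeds 16 elements.
    """
    small = min(ctx.n_objects, ctx.n_attributes)
    if small > _BRUTE_FORCE_LIMIT:
        raise ContextError(
            f"brute-force enumeration refused: min(|G|,|M|) = {small} "
            f"exceeds {_BRUTE_FORCE_LIMIT}"
        )
    pairs: set[tuple[int, int]] = set()
    if ctx.n_attributes <= ctx.n_objects:
        for s in range(1 << ctx.n_attributes):
            e = ctx.extent_bits(s)
            pairs.add((e, ctx.intent_bits(e)))
    else:
        for s in range(1 << ctx.n_objects):
            i = ctx.intent_bits(s)
            pairs.add((ctx.extent_bits(i), i))
    return _concepts_from_pairs(ctx, pairs)


class ConceptLattice:
    """All concepts of one context plus the covering (Hasse) order.

    The covering relation — the transitive reduction of extent inclusion —
    is computed lazily on first access, since classification only needs
    the concept list.
    """

    def __init__(self, context: FormalContext, concepts: Sequence[FormalConcept]):
        if len({(c.extent_bits, c.intent_bits) for c in concepts}) != len(concepts):
            raise ContextError("duplicate concepts passed to ConceptLattice")
        self.context = context
        self.concepts = list(concepts)
        all_obj = context._all_objects_bits
        all_attr = context._all_attributes_bits
        tops = [c.index for c in self.concepts if c.extent_bits == all_obj]
        bottoms = [c.index for c in self.concepts if c.intent_bits == all_attr]
        if len(tops) != 1 or len(bottoms) != 1:
            raise ContextError(
                "concept set is not a complete lattice: expected exactly one "
                f"top and one bottom, found {len(tops)} / {len(bottoms)}"
            )
        self.top_index = tops[0]
        self.bottom_index = bottoms[0]
        self._covering_edges: list[tuple[int, int]] | None = None

    def __len__(self) -> int:
        return len(self.concepts)

    def __repr__(self) -> str:
        return f"ConceptLattice({len(self.concepts)} concepts over {self.context!r})"

    @property
    def covering_edges(self) -> list[tuple[int, int]]:
        """Pairs ``(sub_index, super_index)``: transitive reduction of ≤."""
        if self._covering_edges is None:
            self._covering_edges = self._compute_covers()
        return self._covering_edges

    def _compute_covers(self) -> list[tuple[int, int]]:
        by_size = sorted(
            self.concepts, key=lambda c: (c.extent_bits.bit_count(), c.index)
        )
        edges: list[tuple[int, int]] = []
        for sub in self.concepts:
            e = sub.extent_bits
            size = e.bit_count()
            covers: list[int] = []  # extent bitsets of accepted covers
            for sup in by_size:
                u = sup.extent_bits
                if u.bit_count() <= size or e & u != e:
                    continue  # not a strict superset
                if any(v & u == v for v in covers):
                    continue  # an accepted cover lies below it
                covers.append(u)
                edges.append((sub.index, sup.index))
        return sorted(edges)

    def superconcepts(self, index: int) -> list[FormalConcept]:
        """All concepts strictly above ``index`` in the extent order."""
        e = self.concepts[index].extent_bits
        return [
            c for c in self.concepts
            if c.extent_bits != e and e & c.extent_bits == e
        ]

    def subconcepts(self, index: int) -> list[FormalConcept]:
        e = self.concepts[index].extent_bits
        return [
            c for c in self.concepts
            if c.extent_bits != e and c.extent_bits & e == c.extent_bits
        ]


def build_order(
    ctx: FormalContext, concepts: Sequence[FormalConcept] | None = None
) -> ConceptLattice:
    """Build the concept lattice of ``ctx``.

    ``concepts`` must be exactly the concepts of ``ctx`` (canonically
    indexed); when omitted they are enumerated first.
    """
    if concepts is None:
        concepts = enumerate_concepts(ctx)
    return ConceptLattice(ctx, concepts)


def _node_label(concept: FormalConcept, annotation) -> str:
    intent = "{" + ",".join(concept.intent) + "}"
    if annotation is None:
        return intent
    return f"{intent}\\nclass {annotation}"


def export_dot(
    lat: ConceptLattice,
    labels: Mapping[int, object] | None = None,
) -> str:
    """Render the Hasse diagram as deterministic Graphviz DOT text.

    One node per concept (id ``c<index>``, label showing the intent and,
    when ``labels`` provides one, the class), one edge per covering pair
    drawn sub → super; ``rankdir=BT`` puts the top concept on top.
    """
    labels = labels or {}
    lines = ["digraph concept_lattice {", "  rankdir=BT;", "  node [shape=box];"]
    for c in lat.concepts:
        lines.append(f'  c{c.index} [label="{_node_label(c, labels.get(c.index))}"];')
    for sub, sup in lat.covering_edges:
        lines.append(f"  c{sub} -> c{sup};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def lattice_to_json(
    lat: ConceptLattice,
    labels: Mapping[int, object] | None = None,
) -> dict:
    """JSON-serializable lattice dump: concepts (with optional class labels)
    and covering edges."""
    labels = labels or {}
    concepts = []
    for c in lat.concepts:
        d = {"index": c.index, "extent": list(c.extent), "intent": list(c.intent)}
        if c.index in labels:
            d["label"] = labels[c.index]
        concepts.append(d)
    return {
        "concepts": concepts,
        "edges": [list(e) for e in lat.covering_edges],
    }
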