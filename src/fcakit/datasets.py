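"""Small built-in example data used in the documentation and tests."""

from __future__ import annotations

import numpy as np

from .context import FormalContext

__all__ = ["demo_context", "demo_labels"]

_DEMO_INCIDENCE = np.array(
    [
        [1, 0, 0, 0],
        [1, 1, 0, 0],
        [1, 1, 0, 0],
        [1, 1, 0, 1],
        [1, 1, 1, 0],
        [1, 0, 1, 0],
    ]
)


def demo_context() -> FormalContext:
    """The six-image worked example used throughout the docs.

    Six images (objects ``1``–``6``) described by four binarized
    high-level features ``a``–``d``.  Its concept lattice has exactly six
    concepts, which makes every derivation and classification step easy
    to trace by hand.
    """
    return FormalContext(
        objects=("1", "2", "3", "4", "5", "6"),
        attributes=("a", "b", "c", "d"),
        incidence=_DEMO_INCIDENCE,
    )


def demo_labels() -> dict[str, int]:
    """Benign/malignant labels (0/1) for the demo images."""
    return {"1": 0, "2": 1, "3": 1, "4": 1, "5": 1, "6": 0}
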