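"""Synthetic class-structured data with known signature attributes.

The generator emulates the regime the lattice classifier is built for:
a modest number of binarized high-level features (16 by default, the
width of a small CNN embedding head) over a two-class image set.  Each
class owns a disjoint *signature* subset of attributes; within a class a
signature attribute fires with probability ``p_signal`` and every other
attribute with probability ``p_noise``.  Continuous mode draws Gaussian
feature values (high mean on signature features, low elsewhere) so the
normalize-and-threshold binarization step can be exercised end to end.

All randomness flows through ``seed``: the same spec yields the same
data, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .context import FeatureMatrix

__all__ = ["SyntheticSpec", "generate", "default_signatures"]


def default_signatures(n_attributes: int, n_classes: int) -> tuple[tuple[int, ...], ...]:
    """Split the attribute indices evenly into one signature set per class."""
    per = n_attributes // n_classes
    if per == 0:
        raise ValueError("need at least one attribute per class")
    return tuple(
        tuple(range(k * per, (k + 1) * per)) for k in range(n_classes)
    )


@dataclass
class SyntheticSpec:
    """Parameters of the class-conditional generator.

    ``signatures`` lists, per class, the attribute indices characteristic
    of that class; sets must be pairwise disjoint.  In continuous mode the
    class-conditional Gaussians have mean ``mu_signal`` on signature
    features and ``mu_noise`` elsewhere, common standard deviation ``sd``.
    """

    n_per_class: int = 100
    n_attributes: int = 16
    n_classes: int = 2
    signatures: tuple[tuple[int, ...], ...] | None = None
    p_signal: float = 0.9
    p_noise: float = 0.05
    seed: int = 0
    mode: str = "binary"
    mu_signal: float = 0.8
    mu_noise: float = 0.2
    sd: float = 0.15
    feature_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "continuous"):
            raise ValueError(f"mode must be 'binary' or 'continuous', got {self.mode!r}")
        if not 0.0 <= self.p_noise < self.p_signal <= 1.0:
            raise ValueError(
                f"need 0 <= p_noise < p_signal <= 1, got "
                f"p_noise={self.p_noise}, p_signal={self.p_signal}"
            )
        if self.signatures is None:
            self.signatures = default_signatures(self.n_attributes, self.n_classes)
        else:
            self.signatures = tuple(tuple(s) for s in self.signatures)
        if len(self.signatures) != self.n_classes:
            raise ValueError("one signature set per class is required")
        flat = [j for s in self.signatures for j in s]
        if len(flat) != len(set(flat)):
            raise ValueError("signature sets must be pairwise disjoint")
        if flat and not 0 <= min(flat) <= max(flat) < self.n_attributes:
            raise ValueError("signature indices out of range")
        self.feature_names = tuple(f"f{j}" for j in range(self.n_attributes))


def generate(spec: SyntheticSpec):
    """Draw one dataset from ``spec``.

    Returns ``(matrix, labels)``: a 0/1 ``numpy`` array in binary mode, a
    :class:`~fcakit.context.FeatureMatrix` in continuous mode; labels are
    class indices ``0..n_classes-1``, one per row, in class order.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)

    if spec.mode == "binary":
        p = np.full((n, spec.n_attributes), spec.p_noise)
        for k, sig in enumerate(spec.signatures):
            rows = slice(k * spec.n_per_class, (k + 1) * spec.n_per_class)
            for j in sig:
                p[rows, j] = spec.p_signal
        data = (rng.random((n, spec.n_attributes)) < p).astype(np.uint8)
        return data, [int(l) for l in labels]

    mu = np.full((n, spec.n_attributes), spec.mu_noise)
    for k, sig in enumerate(spec.signatures):
        rows = slice(k * spec.n_per_class, (k + 1) * spec.n_per_class)
        for j in sig:
            mu[rows, j] = spec.mu_signal
    values = rng.normal(mu, spec.sd)
    fm = FeatureMatrix(
        objects=tuple(f"s{i}" for i in range(n)),
        features=spec.feature_names,
        values=values,
    )
    return fm, [int(l) for l in labels]
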