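"""Bicluster similarity: the pairwise F1 measure and its symmetrized average.

A bicluster is a rectangle (sample set x feature set).  For two rectangles A
and B with n_A = |samples_A| * |features_A|,

    F1(A, B) = 2 * r_{A&B} * c_{A&B} / (n_A + n_B),

the harmonic mean of precision and recall of the shared cells, where r and c
count common samples and common features.  For two collections, S(M1, M2)
averages each rectangle of M1's best match in M2, and the symmetrized score is
(S(M1, M2) + S(M2, M1)) / 2 — at most 1, and exactly 1 for identical sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["Bicluster", "f1_pair", "similarity", "f1_symmetric"]


@dataclass(frozen=True)
class Bicluster:
    """A rectangle of the data matrix: a set of samples times a set of features."""

    samples: frozenset[int]
    features: frozenset[int]

    def __init__(self, samples: Iterable[int], features: Iterable[int]):
        object.__setattr__(self, "samples", frozenset(samples))
        object.__setattr__(self, "features", frozenset(features))

    @property
    def size(self) -> int:
        return len(self.samples) * len(self.features)


def f1_pair(A: Bicluster, B: Bicluster) -> float:
    """Pairwise F1 in [0, 1]; 0 when both rectangles are empty."""
    denom = A.size + B.size
    if denom == 0:
        return 0.0
    r = len(A.samples & B.samples)
    c = len(A.features & B.features)
    return 2.0 * r * c / denom


def similarity(M1: Sequence[Bicluster], M2: Sequence[Bicluster]) -> float:
    """One-sided score: mean over A in M1 of the best F1 against any B in M2."""
    if not M1:
        raise ValueError("M1 must be nonempty")
    if not M2:
        warnings.warn("empty reference bicluster set; similarity is 0", stacklevel=2)
        return 0.0
    return sum(max(f1_pair(A, B) for B in M2) for A in M1) / len(M1)


def f1_symmetric(M1: Sequence[Bicluster], M2: Sequence[Bicluster]) -> float:
    """Symmetrized F1-type average of two bicluster collections."""
    if not M1 or not M2:
        warnings.warn("empty bicluster set; symmetrized F1 is 0", stacklevel=2)
        return 0.0
    return 0.5 * (similarity(M1, M2) + similarity(M2, M1))
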