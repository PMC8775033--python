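"""Count-data containers shared by all property models.

Two sampling designs are supported:

* bivariate counts ``(n0x, n1x)`` of a binary outcome ``y`` over ``kx``
  equiprobable hidden states ``x`` (marginal-probability and
  mutual-information estimation);
* a univariate count vector over ``k`` accessible states (entropy
  estimation), together with its multiplicity-histogram representation
  ``{count value -> number of states}``, which is the sufficient statistic
  for every permutation-invariant property.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BinaryConditionalCounts",
    "CountVector",
    "MultiplicityHistogram",
]


@dataclass(frozen=True)
class BinaryConditionalCounts:
    """Per-state counts ``(n0x, n1x)`` of a binary outcome over ``kx`` states.

    Only sampled states need to be listed; the remaining ``kx - len(pairs)``
    states are implicitly ``(0, 0)``.

    Parameters
    ----------
    pairs
        Sequence of ``(n0, n1)`` tuples, one per listed x state.
    kx
        Total number of x states, including unsampled ones.
    """

    pairs: tuple[tuple[int, int], ...]
    kx: int

    def __init__(self, pairs: Iterable[tuple[int, int]], kx: int):
        pairs = tuple((int(a), int(b)) for a, b in pairs)
        if any(a < 0 or b < 0 for a, b in pairs):
            raise ValueError("counts must be non-negative integers")
        kx = int(kx)
        if kx < 1:
            raise ValueError("kx must be >= 1")
        if len(pairs) > kx:
            raise ValueError(
                f"{len(pairs)} listed states exceed kx={kx} total states"
            )
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "kx", kx)

    @property
    def nx(self) -> np.ndarray:
        """Per-listed-state totals ``n0x + n1x``."""
        if not self.pairs:
            return np.zeros(0, dtype=int)
        return np.asarray([a + b for a, b in self.pairs], dtype=int)

    @property
    def n(self) -> int:
        return int(self.nx.sum())

    @property
    def n1(self) -> int:
        return int(sum(b for _, b in self.pairs))

    @property
    def f1(self) -> float:
        """Plug-in marginal frequency ``n1 / n``."""
        if self.n == 0:
            raise ValueError("f1 undefined for empty data")
        return self.n1 / self.n

    @property
    def k2(self) -> int:
        """Number of states with coincidences (``nx >= 2``)."""
        return int((self.nx >= 2).sum())

    def grouped(self) -> dict[tuple[int, int], int]:
        """Multiplicity of each distinct ``(n1, n0)`` pair, zero group included."""
        groups: Counter[tuple[int, int]] = Counter()
        for n0, n1 in self.pairs:
            groups[(n1, n0)] += 1
        unsampled = self.kx - len(self.pairs) + groups.pop((0, 0), 0)
        if unsampled:
            groups[(0, 0)] = unsampled
        return dict(groups)

    def swap_labels(self) -> "BinaryConditionalCounts":
        """Exchange the two outcome labels (``n0x <-> n1x``)."""
        return BinaryConditionalCounts([(b, a) for a, b in self.pairs], self.kx)

    def empty_like(self) -> "BinaryConditionalCounts":
        return BinaryConditionalCounts((), self.kx)


@dataclass(frozen=True)
class CountVector:
    """Counts per observed state plus the total number of accessible states."""

    counts: tuple[int, ...]
    k: int

    def __init__(self, counts: Iterable[int], k: int | None = None):
        counts = tuple(int(c) for c in counts)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative integers")
        occupied = sum(1 for c in counts if c > 0)
        if k is None:
            k = len(counts)
        k = int(k)
        if k < occupied:
            raise ValueError(f"k={k} smaller than the {occupied} occupied states")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "k", k)

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def occupied(self) -> int:
        return sum(1 for c in self.counts if c > 0)

    def to_multiplicities(self) -> "MultiplicityHistogram":
        entries: Counter[int] = Counter(c for c in self.counts if c > 0)
        entries[0] = self.k - self.occupied
        return MultiplicityHistogram(dict(entries))


@dataclass(frozen=True)
class MultiplicityHistogram:
    """Histogram ``{count value c -> number of states m_c}``.

    ``m_0`` counts the unobserved states, so ``sum(m_c) = k`` and
    ``sum(c * m_c) = n``.
    """

    entries: Mapping[int, int] = field(default_factory=dict)

    def __init__(self, entries: Mapping[int, int]):
        clean = {int(c): int(m) for c, m in entries.items() if int(m) != 0 or c == 0}
        if any(c < 0 or m < 0 for c, m in clean.items()):
            raise ValueError("count values and multiplicities must be >= 0")
        clean.setdefault(0, 0)
        object.__setattr__(self, "entries", clean)

    @classmethod
    def from_partition(cls, partition: Iterable[int], k: int) -> "MultiplicityHistogram":
        """Histogram for a multiset of positive counts among ``k`` states."""
        parts = [int(p) for p in partition]
        if any(p <= 0 for p in parts):
            raise ValueError("partition entries must be positive")
        if len(parts) > k:
            raise ValueError("more occupied states than k")
        entries = Counter(parts)
        entries[0] = k - len(parts)
        return cls(dict(entries))

    @property
    def n(self) -> int:
        return int(sum(c * m for c, m in self.entries.items()))

    @property
    def k(self) -> int:
        return int(sum(self.entries.values()))

    @property
    def k2(self) -> int:
        return int(sum(m for c, m in self.entries.items() if c >= 2))

    def empty_like(self) -> "MultiplicityHistogram":
        return MultiplicityHistogram({0: self.k})

    def to_counts(self) -> CountVector:
        counts = []
        for c in sorted(self.entries, reverse=True):
            if c > 0:
                counts.extend([c] * self.entries[c])
        return CountVector(counts, self.k)
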