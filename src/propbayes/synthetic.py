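"""Synthetic systems with known ground truth for recovery experiments.

Two toy systems are generated:

* a bivariate system with ``kx`` equiprobable x states and binary y whose
  conditionals ``q1|x`` are i.i.d. symmetric Beta(a, a) draws (default
  a = 0.5, the arcsine law, which spreads conditionals toward the
  deterministic endpoints and yields substantial mutual information);
* a ranked power-law distribution ``q_r ~ r^{-exponent}`` over ``k``
  states for entropy estimation.

For the entropy benchmark the module also enumerates all multiplicity sets
(integer partitions) of a small sample size n and computes each set's
probability under the generating distribution, either exactly (dynamic
programming over states) or by Monte-Carlo frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .counts import BinaryConditionalCounts, CountVector, MultiplicityHistogram
from .mi import ix

__all__ = [
    "BivariateSystem",
    "PowerLawSystem",
    "MultiplicityEnsemble",
    "make_bivariate_system",
    "sample_bivariate_counts",
    "make_powerlaw_system",
    "sample_counts",
    "enumerate_multiplicities",
    "multiplicity_weights",
]


@dataclass(frozen=True)
class BivariateSystem:
    """True conditionals q1|x of a kx-state bivariate system, plus exact MI."""

    kx: int
    beta_param: float
    conditionals: np.ndarray
    true_mi: float
    seed: int


@dataclass(frozen=True)
class PowerLawSystem:
    """Ranked power-law probabilities q_r ~ r^-exponent, plus exact entropy."""

    k: int
    exponent: float
    probabilities: np.ndarray
    true_entropy: float
    seed: int = 0


@dataclass(frozen=True)
class MultiplicityEnsemble:
    """All multiplicity sets of n samples with their class probabilities."""

    partitions: tuple[tuple[int, ...], ...]
    members: tuple[MultiplicityHistogram, ...]
    weights: np.ndarray
    method: str
    mc_draws: int
    seed: int


def make_bivariate_system(kx: int, a: float, seed: int) -> BivariateSystem:
    """Draw conditionals i.i.d. Beta(a, a); true MI = mean_x Ix(q1|x)."""
    if kx < 1 or a <= 0:
        raise ValueError("require kx >= 1 and a > 0")
    rng = np.random.default_rng(seed)
    cond = rng.beta(a, a, size=kx)
    cond.setflags(write=False)
    return BivariateSystem(
        kx=kx,
        beta_param=float(a),
        conditionals=cond,
        true_mi=float(np.mean(ix(cond))),
        seed=int(seed),
    )


def sample_bivariate_counts(
    system: BivariateSystem, n: int, seed: int
) -> BinaryConditionalCounts:
    """n samples: x uniform on kx states, then y ~ Bernoulli(q1|x)."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return BinaryConditionalCounts((), system.kx)
    x = rng.integers(0, system.kx, size=n)
    y = rng.random(n) < system.conditionals[x]
    n1 = np.bincount(x[y], minlength=system.kx)
    nx = np.bincount(x, minlength=system.kx)
    pairs = [
        (int(nx[i] - n1[i]), int(n1[i])) for i in range(system.kx) if nx[i] > 0
    ]
    return BinaryConditionalCounts(pairs, system.kx)


def make_powerlaw_system(k: int, exponent: float, seed: int = 0) -> PowerLawSystem:
    """Ranked law q_r = r^-exponent / Z; exponent 0 gives the uniform."""
    if k < 2:
        raise ValueError("require k >= 2")
    r = np.arange(1, k + 1, dtype=float)
    q = r**-exponent
    q /= q.sum()
    q.setflags(write=False)
    return PowerLawSystem(
        k=k,
        exponent=float(exponent),
        probabilities=q,
        true_entropy=float(-(q * np.log(q)).sum()),
        seed=int(seed),
    )


def sample_counts(system: PowerLawSystem, n: int, seed: int) -> CountVector:
    """Multinomial draw of n samples from the power-law probabilities."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, system.probabilities)
    return CountVector([int(c) for c in counts], system.k)


def _partitions(n: int, largest: int) -> Iterator[tuple[int, ...]]:
    if n == 0:
        yield ()
        return
    for first in range(min(n, largest), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def enumerate_multiplicities(n: int) -> list[tuple[int, ...]]:
    """All integer partitions of n, non-increasing, no duplicates.

    A partition is the multiset of positive per-state counts of a sample —
    the multiplicity set — e.g. (2, 1, 1, 1, 1) for n = 6.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return list(_partitions(n, n))


def _exact_partition_probability(
    partition: Sequence[int], q: np.ndarray
) -> float:
    """P(sorted multinomial counts == partition) by DP over states.

    Sums, over all ways to assign the distinct count values to disjoint
    subsets of states, the multinomial probability of the resulting count
    vector.
    """
    n = int(sum(partition))
    values = sorted(set(partition), reverse=True)
    caps = [partition.count(v) for v in values]
    coeff = math.factorial(n)
    for v, r in zip(values, caps):
        coeff /= math.factorial(v) ** r
    # dp over states: key = assigned counts per class
    start = tuple(0 for _ in values)
    target = tuple(caps)
    dp = {start: 1.0}
    for qs in q:
        new = dict(dp)
        powers = [qs**v for v in values]
        for t, val in dp.items():
            for j in range(len(values)):
                if t[j] < caps[j]:
                    t2 = t[:j] + (t[j] + 1,) + t[j + 1 :]
                    new[t2] = new.get(t2, 0.0) + val * powers[j]
        dp = new
    return float(coeff * dp.get(target, 0.0))


def multiplicity_weights(
    system: PowerLawSystem,
    n: int,
    method: str = "monte_carlo",
    mc_draws: int = 10**6,
    seed: int = 0,
) -> MultiplicityEnsemble:
    """Probability of each multiplicity class of n samples from the system.

    ``exact`` mode sums over injective count-to-state assignments by dynamic
    programming (refused for n > 12); ``monte_carlo`` mode uses the
    frequency over ``mc_draws`` multinomial samples.
    """
    parts = enumerate_multiplicities(n)
    parts = [p for p in parts if len(p) <= system.k]
    q = system.probabilities
    if method == "exact":
        if n > 12:
            raise ValueError("exact mode refused for n > 12")
        weights = np.array([_exact_partition_probability(p, q) for p in parts])
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        index = {p: i for i, p in enumerate(parts)}
        weights = np.zeros(len(parts))
        remaining = mc_draws
        batch = 200_000
        while remaining > 0:
            size = min(batch, remaining)
            draws = rng.multinomial(n, q, size=size)
            sorted_rows = -np.sort(-draws, axis=1)
            patterns, freqs = np.unique(sorted_rows, axis=0, return_counts=True)
            for row, freq in zip(patterns, freqs):
                key = tuple(int(c) for c in row if c > 0)
                weights[index[key]] += int(freq)
            remaining -= size
        weights /= mc_draws
    else:
        raise ValueError(f"unknown method {method!r}")
    members = tuple(
        MultiplicityHistogram.from_partition(p, system.k) for p in parts
    )
    weights.setflags(write=False)
    return MultiplicityEnsemble(
        partitions=tuple(parts),
        members=members,
        weights=weights,
        method=method,
        mc_draws=int(mc_draws if method == "monte_carlo" else 0),
        seed=int(seed),
    )
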