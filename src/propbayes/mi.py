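"""Mutual-information model via per-state one-dimensional quadratures.

Setting: ``kx`` equiprobable states ``x``, binary ``y`` with symmetric
marginal ``q_y = 1/2`` (hard-coded; generalizing the marginal is out of
scope).  The mutual information decomposes over states,

    I = (1/kx) sum_x Ix(q1|x),
    Ix(q) = ln 2 + q ln q + (1 - q) ln(1 - q)  in [0, ln 2],

so the exponential-family prior, the likelihood and hence the partition
function all factorize over x:

    Z(n, beta) = prod_x Z(n1x, n0x, beta),
    Z(n1, n0, beta) = int_0^1 q^n1 (1-q)^n0 e^{gamma Ix(q)} dq,  gamma = beta/kx.

Each factor is a smooth, bounded one-dimensional integral evaluated with a
fixed 200-node Gauss-Legendre rule in the log domain.  Only states with
coincidences (nx >= 2) carry beta-dependent evidence: by the q -> 1-q
symmetry of Ix, a singleton factor satisfies
``Z(1, 0, beta) = Z(0, 0, beta) / 2`` exactly, so its evidence contribution
is the constant ``-ln 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp, xlogy

from .counts import BinaryConditionalCounts

__all__ = [
    "StateGroup",
    "QuadratureRule",
    "gauss_legendre_01",
    "ix",
    "group_log_partition",
    "group_ix_mean",
    "mi_log_partition",
    "mi_posterior_mean",
    "mi_prior_mean",
    "mi_log_evidence",
    "mi_property_model",
]

LN2 = float(np.log(2.0))
DEFAULT_ORDER = 200


@dataclass(frozen=True)
class StateGroup:
    """A group of x states sharing the same ``(n1, n0)`` counts."""

    n1: int
    n0: int
    multiplicity: int


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes/weights on (0, 1); weights integrate constants exactly to 1."""

    nodes: np.ndarray
    weights: np.ndarray
    order: int


@lru_cache(maxsize=8)
def gauss_legendre_01(order: int = DEFAULT_ORDER) -> QuadratureRule:
    """Gauss-Legendre rule mapped from [-1, 1] to (0, 1).

    The rule is symmetric about 1/2, which makes the singleton identity
    ``Z(1,0,gamma) = Z(0,0,gamma)/2`` hold at machine precision.
    """
    x, w = np.polynomial.legendre.leggauss(order)
    nodes = (x + 1.0) / 2.0
    weights = w / 2.0
    nodes.setflags(write=False)
    weights.setflags(write=False)
    return QuadratureRule(nodes=nodes, weights=weights, order=order)


def ix(q):
    """Per-state mutual information Ix(q) = ln 2 + q ln q + (1-q) ln(1-q).

    Vectorized; endpoint limits Ix(0) = Ix(1) = ln 2 are exact, Ix(1/2) = 0.
    """
    q = np.asarray(q, dtype=float)
    out = LN2 + xlogy(q, q) + xlogy(1.0 - q, 1.0 - q)
    return float(out) if out.ndim == 0 else out


def _log_integrand(n1: int, n0: int, gamma: float, rule: QuadratureRule) -> np.ndarray:
    q = rule.nodes
    return xlogy(n1, q) + xlogy(n0, 1.0 - q) + gamma * ix(q)


def group_log_partition(
    n1: int, n0: int, gamma: float, rule: QuadratureRule | None = None
) -> float:
    """log int_0^1 q^n1 (1-q)^n0 e^{gamma Ix(q)} dq, in the log domain."""
    if n1 < 0 or n0 < 0:
        raise ValueError("counts must be non-negative")
    rule = rule or gauss_legendre_01()
    return float(logsumexp(_log_integrand(n1, n0, gamma, rule), b=rule.weights))


def group_ix_mean(
    n1: int, n0: int, gamma: float, rule: QuadratureRule | None = None
) -> float:
    """E[Ix(q)] under one state's posterior: a ratio of two quadratures."""
    rule = rule or gauss_legendre_01()
    logf = _log_integrand(n1, n0, gamma, rule)
    log_num = logsumexp(logf, b=rule.weights * ix(rule.nodes))
    log_den = logsumexp(logf, b=rule.weights)
    return float(np.exp(log_num - log_den))


def group_ix_var(
    n1: int, n0: int, gamma: float, rule: QuadratureRule | None = None
) -> float:
    """Var[Ix(q)] under one state's posterior (per-state evidence curvature).

    ``d^2/dgamma^2 log Z(n1, n0, gamma) = Var[Ix]``, so the curvature of the
    log evidence at its peak is the sum over coincidence states of
    ``Var_prior[Ix] - Var_posterior[Ix]``.
    """
    rule = rule or gauss_legendre_01()
    logf = _log_integrand(n1, n0, gamma, rule)
    log_den = logsumexp(logf, b=rule.weights)
    ixq = ix(rule.nodes)
    m1 = float(np.exp(logsumexp(logf, b=rule.weights * ixq) - log_den))
    m2 = float(np.exp(logsumexp(logf, b=rule.weights * ixq**2) - log_den))
    return max(m2 - m1 * m1, 0.0)


def _groups(counts: BinaryConditionalCounts) -> list[StateGroup]:
    return [
        StateGroup(n1=n1, n0=n0, multiplicity=m)
        for (n1, n0), m in counts.grouped().items()
    ]


def mi_log_partition(counts: BinaryConditionalCounts, beta: float) -> float:
    """log Z(n, beta): sum of per-group factors, zero-count group included."""
    gamma = beta / counts.kx
    rule = gauss_legendre_01()
    return float(
        sum(
            g.multiplicity * group_log_partition(g.n1, g.n0, gamma, rule)
            for g in _groups(counts)
        )
    )


def mi_posterior_mean(counts: BinaryConditionalCounts, beta: float) -> float:
    """<I|n,beta> = (1/kx) sum_x E[Ix] under each state's posterior."""
    gamma = beta / counts.kx
    rule = gauss_legendre_01()
    total = sum(
        g.multiplicity * group_ix_mean(g.n1, g.n0, gamma, rule)
        for g in _groups(counts)
    )
    return float(total / counts.kx)


def mi_prior_mean(beta: float, kx: int) -> float:
    """Prior mean MI: E[Ix] under p(q|gamma) ~ e^{gamma Ix(q)}, any state.

    Monotone in gamma from 0 (concentration at q = 1/2) to ln 2
    (concentration at the deterministic endpoints); ln 2 - 1/2 at gamma=0.
    """
    return group_ix_mean(0, 0, beta / kx)


def mi_log_evidence(counts: BinaryConditionalCounts, beta: float) -> float:
    """log p(n|beta) up to beta-independent constants.

    Only coincidence groups (nx >= 2) are evaluated numerically; each
    singleton contributes the exact constant ``-ln 2`` via the
    ``Z(1,0,beta) = Z(0,0,beta)/2`` symmetry, so the curve is flat in beta
    iff k2 = 0.
    """
    gamma = beta / counts.kx
    rule = gauss_legendre_01()
    z0 = group_log_partition(0, 0, gamma, rule)
    total = 0.0
    n_singletons = 0
    for g in _groups(counts):
        nx = g.n1 + g.n0
        if nx >= 2:
            total += g.multiplicity * (
                group_log_partition(g.n1, g.n0, gamma, rule) - z0
            )
        elif nx == 1:
            n_singletons += g.multiplicity
    return float(total - n_singletons * LN2)


def mi_property_model():
    """PropertyModel wiring of the MI model for the core solver."""
    from .core import PropertyModel

    return PropertyModel(
        name="mutual_information",
        log_partition=mi_log_partition,
        zero_counts=lambda counts: counts.empty_like(),
        bounds=lambda counts: (0.0, LN2),
        beta_scale=lambda counts: float(counts.kx),
        analytic_posterior_mean=mi_posterior_mean,
    )
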