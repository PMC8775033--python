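"""Marginal-probability model: closed-form partition functions.

The system has ``kx`` equiprobable hidden states ``x`` and a binary outcome
``y``; the target property is the marginal probability ``q1 = mean_x(q1|x)``
of ``y = 1``.  Under the exponential-family prior tilted by the property,
each state's posterior normalizer is a confluent hypergeometric function
``M(n1x+1, nx+2, beta/kx)``, so the model is fully closed-form:

    Z(n, beta)   = prod_x M(n1x+1, nx+2, gamma),      gamma = beta / kx
    <q1|n,beta>  = (1/kx) sum_x (n1x+1)/(nx+2) * M(n1x+2, nx+3, gamma)
                                               / M(n1x+1, nx+2, gamma)

The headline behaviour of this model is that on coincidence-free data
(all ``nx <= 1``) the MAP fixed point reproduces the plug-in estimate
``n1 / n`` exactly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .counts import BinaryConditionalCounts

__all__ = [
    "ConfluentEval",
    "log_confluent",
    "marginal_log_partition",
    "marginal_posterior_mean",
    "marginal_prior_mean",
    "marginal_property_model",
    "GAMMA_MAX",
]

logger = logging.getLogger(__name__)

#: Supported range of the scaled hyperparameter gamma = beta / kx.  Beyond
#: this the per-state prior mean is within ~1e-12 of its bound {0, 1} and
#: the solver clamps rather than evaluating M at overflowing arguments.
GAMMA_MAX = 500.0


@dataclass(frozen=True)
class ConfluentEval:
    """One evaluation of log M(a, b, z) (Kummer's function, first kind)."""

    a: float
    b: float
    z: float
    log_value: float


def log_confluent(a: float, b: float, z: float) -> float:
    """Natural log of the confluent hypergeometric function M(a, b, z).

    Only ``0 < a``, ``0 < b`` arise in this model (``a = n1x + 1``,
    ``b = nx + 2``).  For ``z < 0`` the Kummer transformation
    ``M(a, b, z) = e^z M(b - a, b, -z)`` is applied so that the underlying
    series has positive terms and no cancellation; this requires ``a < b``,
    which always holds here.

    Raises
    ------
    ValueError
        If the arguments fall outside the supported domain ``|z| <= 500``,
        ``0 < a < b`` (for negative ``z``).
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"log_confluent requires a, b > 0, got a={a}, b={b}")
    if abs(z) > GAMMA_MAX:
        raise ValueError(
            f"log_confluent: |z|={abs(z):g} outside the supported range "
            f"|z| <= {GAMMA_MAX:g}"
        )
    if z == 0.0:
        return 0.0
    if z > 0:
        val = special.hyp1f1(a, b, z)
        if not np.isfinite(val) or val <= 0:
            raise ValueError(f"log_confluent: hyp1f1({a},{b},{z}) = {val}")
        return float(np.log(val))
    # z < 0: Kummer transform keeps the series positive-term.
    if a >= b:
        raise ValueError("log_confluent with z < 0 requires a < b")
    val = special.hyp1f1(b - a, b, -z)
    if not np.isfinite(val) or val <= 0:
        raise ValueError(f"log_confluent: hyp1f1({b - a},{b},{-z}) = {val}")
    return float(z + np.log(val))


def _state_terms(counts: BinaryConditionalCounts) -> list[tuple[int, int, int]]:
    """(n1, n0, multiplicity) over all kx states, zero-count group included."""
    return [(n1, n0, m) for (n1, n0), m in counts.grouped().items()]


def marginal_log_partition(counts: BinaryConditionalCounts, beta: float) -> float:
    """log Z(n, beta) = sum over all kx states of log M(n1x+1, nx+2, beta/kx)."""
    gamma = beta / counts.kx
    return float(
        sum(
            m * log_confluent(n1 + 1, n1 + n0 + 2, gamma)
            for n1, n0, m in _state_terms(counts)
        )
    )


def _state_mean(n1: int, nx: int, gamma: float) -> float:
    """Posterior mean of q1|x for one state: ratio of contiguous M values."""
    log_ratio = log_confluent(n1 + 2, nx + 3, gamma) - log_confluent(n1 + 1, nx + 2, gamma)
    return (n1 + 1) / (nx + 2) * math.exp(log_ratio)


def marginal_posterior_mean(counts: BinaryConditionalCounts, beta: float) -> float:
    """Posterior mean marginal probability <q1|n,beta>, in (0, 1)."""
    gamma = beta / counts.kx
    if abs(gamma) > GAMMA_MAX:
        clamped = GAMMA_MAX if gamma > 0 else -GAMMA_MAX
        warnings.warn(
            f"gamma={gamma:g} beyond supported range; clamped to {clamped:g} "
            "(posterior mean saturates within 1e-12 of its bound)",
            RuntimeWarning,
            stacklevel=2,
        )
        gamma = clamped
    total = sum(
        m * _state_mean(n1, n1 + n0, gamma) for n1, n0, m in _state_terms(counts)
    )
    return float(total / counts.kx)


def marginal_prior_mean(beta: float, kx: int) -> float:
    """Prior mean marginal probability, identical for every state.

    Equals ``(1/2) M(2,3,gamma) / M(1,2,gamma)``; 1/2 at ``beta = 0``,
    saturating to 1 (0) as ``gamma -> +inf`` (``-inf``).
    """
    gamma = beta / kx
    if gamma > GAMMA_MAX:
        warnings.warn("gamma clamped to +GAMMA_MAX", RuntimeWarning, stacklevel=2)
        gamma = GAMMA_MAX
    elif gamma < -GAMMA_MAX:
        warnings.warn("gamma clamped to -GAMMA_MAX", RuntimeWarning, stacklevel=2)
        gamma = -GAMMA_MAX
    return _state_mean(0, 0, gamma)


def marginal_property_model():
    """PropertyModel wiring of this closed-form model for the core solver."""
    from .core import PropertyModel

    return PropertyModel(
        name="marginal_probability",
        log_partition=marginal_log_partition,
        zero_counts=lambda counts: counts.empty_like(),
        bounds=lambda counts: (0.0, 1.0),
        beta_scale=lambda counts: float(counts.kx),
        analytic_posterior_mean=marginal_posterior_mean,
    )
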