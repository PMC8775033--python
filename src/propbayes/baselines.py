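"""Reference estimators: plug-in, Miller-Madow, and the flat (beta=0) Bayes.

These are the comparison points for the MAP estimator.  The plug-in
estimators evaluate the property at the empirical frequencies and are
strongly biased for nonlinear properties in the undersampled regime —
notably, plug-in mutual information on singleton-only data returns the
empirical entropy of y (about ln 2 for balanced data) regardless of the
true value.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

from .counts import BinaryConditionalCounts, CountVector

__all__ = [
    "plugin_entropy",
    "miller_madow_entropy",
    "plugin_mi",
    "bayes_beta0",
]


def _probs(counts) -> np.ndarray:
    if isinstance(counts, CountVector):
        arr = np.asarray(counts.counts, dtype=float)
    else:
        arr = np.asarray(list(counts), dtype=float)
    n = arr.sum()
    if n < 1:
        raise ValueError("plug-in estimators require n >= 1")
    return arr[arr > 0] / n


def plugin_entropy(counts) -> float:
    """H(n/n) = -sum (n_i/n) ln(n_i/n) over occupied states, in nats."""
    p = _probs(counts)
    return float(-xlogy(p, p).sum())


def miller_madow_entropy(counts) -> float:
    """Plug-in entropy plus the first-order bias correction (occ - 1)/(2n)."""
    p = _probs(counts)
    if isinstance(counts, CountVector):
        n = counts.n
    else:
        n = int(sum(counts))
    return plugin_entropy(counts) + (len(p) - 1) / (2.0 * n)


def plugin_mi(counts: BinaryConditionalCounts) -> float:
    """Plug-in mutual information at the empirical joint frequencies.

    Uses the *empirical* marginal of y (not the model's assumed 1/2), so the
    baseline is self-contained:
    I = sum_x (nx/n) sum_y p(y|x) ln[p(y|x) / p(y)], over sampled states.
    """
    n = counts.n
    if n < 1:
        raise ValueError("plugin_mi requires n >= 1")
    p1 = counts.n1 / n
    p0 = 1.0 - p1
    total = 0.0
    for n0x, n1x in counts.pairs:
        nx = n0x + n1x
        if nx == 0:
            continue
        px = nx / n
        q1, q0 = n1x / nx, n0x / nx
        term = 0.0
        if q1 > 0:
            term += q1 * (np.log(q1) - np.log(p1))
        if q0 > 0:
            term += q0 * (np.log(q0) - np.log(p0))
        total += px * term
    return float(max(total, 0.0))


def bayes_beta0(model, counts) -> float:
    """Posterior property mean of the flat (beta = 0) member of the family."""
    from .core import member_posterior_mean

    return member_posterior_mean(model, counts, 0.0)
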