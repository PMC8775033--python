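"""Property-model-agnostic inference machinery.

A *property model* supplies one thing: the log-partition function
``log Z(n, beta)`` of the tilted posterior

    p(q | n, beta) = e^{beta F(q)} prod_j q_j^{n_j} / Z(n, beta),

where the one-parameter prior family ``p(q|beta) \\propto e^{beta F(q)}`` is
the maximum-entropy family with constrained mean property.  Everything else
follows from statistical-mechanics identities:

* posterior mean:      <F|n,beta>      = d/dbeta  log Z(n, beta)
* posterior variance:  <dF^2|n,beta>   = d^2/dbeta^2 log Z(n, beta)
* log evidence:        log p(n|beta)   = log Z(n, beta) - log Z(0, beta)
  (up to beta-independent constants, which are deliberately dropped)
* MAP hyperparameter:  beta0 solves <F|n,beta> = <F|beta>, i.e. the beta at
  which prior and posterior property estimates coincide — the stationary
  point of the evidence under a flat hyperprior.

The prior partition function ``Z0(beta)`` is always obtained by evaluating
``log_partition`` on an empty counts object, never through a separate
formula, so the two routes cannot drift apart.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Any, Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

__all__ = [
    "PropertyModel",
    "MemberSummary",
    "MapSolution",
    "SolverConfig",
    "member_prior_mean",
    "member_posterior_mean",
    "member_posterior_variance",
    "log_marginal_likelihood",
    "solve_map_beta",
    "averaged_estimate",
    "evidence_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropertyModel:
    """Contract a concrete property (entropy, MI, marginal) must fulfil.

    Attributes
    ----------
    name
        Identifier of the property F.
    log_partition
        ``(counts, beta) -> log Z(n, beta)``, finite for all finite beta on
        valid counts and convex in beta.
    zero_counts
        ``counts -> counts`` constructor of the empty-data object of
        matching shape, so that ``Z0(beta) = Z(0, beta)``.
    bounds
        ``counts -> (F_min, F_max)`` attainable property range.
    beta_scale
        ``counts -> s`` scale of the natural search coordinate
        ``gamma = beta / s`` (``kx`` for the bivariate models, 1 for
        entropy); root finding operates on gamma.
    analytic_posterior_mean
        Optional ``(counts, beta) -> <F|n,beta>`` closed form overriding
        numerical differentiation of ``log_partition``.
    """

    name: str
    log_partition: Callable[[Any, float], float]
    zero_counts: Callable[[Any], Any]
    bounds: Callable[[Any], tuple[float, float]]
    beta_scale: Callable[[Any], float] = lambda counts: 1.0
    analytic_posterior_mean: Optional[Callable[[Any, float], float]] = None


@dataclass(frozen=True)
class MemberSummary:
    """Per-beta record of the prior/posterior property estimates."""

    beta: float
    gamma: float
    prior_mean: float
    posterior_mean: float
    posterior_var: float
    log_evidence: float


@dataclass(frozen=True)
class MapSolution:
    """Root ``beta0`` of the prior = posterior fixed point, with diagnostics."""

    beta0: float
    estimate: float
    std: float
    bracket: tuple[float, float]
    n_iter: int
    converged: bool
    degenerate: bool


@dataclass(frozen=True)
class SolverConfig:
    """Numerical knobs of the derivative machinery and the MAP solver.

    ``bracket_init`` is expressed in the scaled coordinate gamma =
    beta / beta_scale(counts) and is doubled up to ``max_expansions`` times
    when the discrepancy D(gamma) does not change sign inside it.
    ``beta_grid`` (raw beta units) drives ``evidence_profile`` and
    ``averaged_estimate``; ``prior_weight`` is a weight over beta for the
    averaging (uniform by default: the empirical-Bayes variant).
    """

    fd_step: float = 1e-3
    tol: float = 1e-8
    bracket_init: tuple[float, float] = (-50.0, 50.0)
    max_expansions: int = 8
    beta_grid: Optional[Sequence[float]] = None
    prior_weight: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.fd_step <= 0 or self.tol <= 0:
            raise ValueError("fd_step and tol must be positive")
        if self.bracket_init[0] >= self.bracket_init[1]:
            raise ValueError("bracket_init must be an increasing pair")


def _step(cfg: SolverConfig, beta: float) -> float:
    return cfg.fd_step * max(1.0, abs(beta))


def _logz(model: PropertyModel, counts: Any, beta: float) -> float:
    val = model.log_partition(counts, float(beta))
    if not np.isfinite(val):
        raise ValueError(
            f"{model.name}: non-finite log-partition at beta={beta:g}"
        )
    return val


def _fd_first(model: PropertyModel, counts: Any, beta: float, cfg: SolverConfig) -> float:
    """Central difference of log Z in beta, Richardson-extrapolated once."""
    h = _step(cfg, beta)

    def central(hh: float) -> float:
        return (_logz(model, counts, beta + hh) - _logz(model, counts, beta - hh)) / (2 * hh)

    d_h = central(h)
    d_h2 = central(h / 2)
    return (4.0 * d_h2 - d_h) / 3.0


def _fd_second(model: PropertyModel, counts: Any, beta: float, cfg: SolverConfig) -> float:
    """Second central difference of log Z on a 5-point stencil."""
    h = _step(cfg, beta)
    f0 = _logz(model, counts, beta)

    def second(hh: float) -> float:
        return (
            _logz(model, counts, beta + hh) - 2 * f0 + _logz(model, counts, beta - hh)
        ) / (hh * hh)

    v_h = second(h)
    v_h2 = second(h / 2)
    return (4.0 * v_h2 - v_h) / 3.0


def member_posterior_mean(
    model: PropertyModel, counts: Any, beta: float, cfg: SolverConfig | None = None
) -> float:
    """Posterior property mean <F|n,beta> = d/dbeta log Z(n, beta)."""
    cfg = cfg or SolverConfig()
    if model.analytic_posterior_mean is not None:
        return float(model.analytic_posterior_mean(counts, float(beta)))
    return float(_fd_first(model, counts, beta, cfg))


def member_prior_mean(
    model: PropertyModel, counts: Any, beta: float, cfg: SolverConfig | None = None
) -> float:
    """Prior property mean <F|beta>: the posterior mean on empty data."""
    return member_posterior_mean(model, model.zero_counts(counts), beta, cfg)


def member_posterior_variance(
    model: PropertyModel, counts: Any, beta: float, cfg: SolverConfig | None = None
) -> float:
    """Posterior property variance <dF^2|n,beta> = d^2/dbeta^2 log Z."""
    cfg = cfg or SolverConfig()
    raw = _fd_second(model, counts, beta, cfg)
    if raw < -1e-8:
        warnings.warn(
            f"{model.name}: negative variance {raw:.3e} at beta={beta:g} "
            "clipped to 0 (log Z should be convex)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(max(raw, 0.0))


def log_marginal_likelihood(model: PropertyModel, counts: Any, beta: float) -> float:
    """Beta-dependent part of log p(n|beta) = log Z(n,beta) - log Z0(beta).

    Beta-independent constants (multinomial coefficients, discretization
    constants) are dropped: they cancel wherever the evidence is compared
    across beta.
    """
    return _logz(model, counts, beta) - _logz(model, model.zero_counts(counts), beta)


def _discrepancy(
    model: PropertyModel, counts: Any, zero: Any, beta: float, cfg: SolverConfig
) -> float:
    return member_posterior_mean(model, counts, beta, cfg) - member_posterior_mean(
        model, zero, beta, cfg
    )


_SCAN_POINTS = 9


def solve_map_beta(
    model: PropertyModel, counts: Any, cfg: SolverConfig | None = None
) -> MapSolution:
    """Find beta0 where prior and posterior property estimates coincide.

    Scans the initial gamma bracket for a sign change of the discrepancy
    ``D(beta) = <F|n,beta> - <F|beta>``, doubling the bracket up to
    ``cfg.max_expansions`` times, then refines with Brent's method.  Data
    carrying no beta information (``D`` flat at ~0 over the whole searched
    range) yield a *degenerate* solution at beta0 = 0 rather than an
    arbitrary root.
    """
    cfg = cfg or SolverConfig()
    zero = model.zero_counts(counts)
    scale = float(model.beta_scale(counts))

    def d_of_gamma(gamma: float) -> float:
        return _discrepancy(model, counts, zero, gamma * scale, cfg)

    def d_or_nan(gamma: float) -> float:
        # Extreme beta can underflow a model's partition function during
        # bracket expansion; such points carry no sign information.
        try:
            return d_of_gamma(gamma)
        except ValueError as exc:
            logger.debug("%s: D(gamma=%g) failed: %s", model.name, gamma, exc)
            return float("nan")

    lo, hi = cfg.bracket_init
    n_eval = 0
    for expansion in range(cfg.max_expansions + 1):
        grid = np.linspace(lo, hi, _SCAN_POINTS)
        vals = np.array([d_or_nan(g) for g in grid])
        n_eval += len(grid)
        logger.debug(
            "%s: bracket scan %d on gamma [%g, %g], max|D|=%g",
            model.name, expansion, lo, hi, np.nanmax(np.abs(vals)),
        )
        if np.isfinite(vals).all() and np.all(np.abs(vals) <= cfg.tol):
            # No data constrain beta (e.g. zero counts, coincidence-free MI).
            est = member_posterior_mean(model, counts, 0.0, cfg)
            var = member_posterior_variance(model, counts, 0.0, cfg)
            return MapSolution(
                beta0=0.0, estimate=float(est), std=float(np.sqrt(var)),
                bracket=(lo * scale, hi * scale), n_iter=n_eval,
                converged=True, degenerate=True,
            )
        # A genuine crossing needs opposite signs with at least one side
        # clearly non-zero: at extreme beta both means saturate and D
        # underflows to 0, which must not be mistaken for a root.
        big = np.abs(vals) > cfg.tol
        sign_change = np.nonzero(
            (np.sign(vals[:-1]) * np.sign(vals[1:]) < 0) & (big[:-1] | big[1:])
        )[0]
        interior_zero = np.nonzero(
            (vals == 0.0)
            & np.r_[big[1:], False]
            & np.r_[False, big[:-1]]
        )[0]
        if len(interior_zero):
            g0 = float(grid[interior_zero[0]])
            return _finish(model, counts, cfg, g0 * scale, (lo * scale, hi * scale), n_eval)
        if len(sign_change):
            i = int(sign_change[0])
            a, b = float(grid[i]), float(grid[i + 1])
            g0, res = optimize.brentq(
                d_of_gamma, a, b, xtol=1e-13, rtol=8.9e-16, full_output=True
            )
            n_eval += res.function_calls
            logger.debug(
                "%s: root gamma0=%g after %d evals, residual=%g",
                model.name, g0, n_eval, d_of_gamma(g0),
            )
            return _finish(
                model, counts, cfg, float(g0) * scale, (a * scale, b * scale), n_eval
            )
        lo, hi = 2 * lo, 2 * hi
    raise RuntimeError(
        f"{model.name}: no sign change of the prior/posterior discrepancy on "
        f"gamma in [{lo / 2:g}, {hi / 2:g}] after {cfg.max_expansions} "
        f"expansions; D at ends: {d_or_nan(lo / 2):.3e}, {d_or_nan(hi / 2):.3e}. "
        "The data appear incompatible with the searched beta range."
    )


def _finish(
    model: PropertyModel,
    counts: Any,
    cfg: SolverConfig,
    beta0: float,
    bracket: tuple[float, float],
    n_iter: int,
) -> MapSolution:
    est = member_posterior_mean(model, counts, beta0, cfg)
    var = member_posterior_variance(model, counts, beta0, cfg)
    resid = abs(est - member_prior_mean(model, counts, beta0, cfg))
    return MapSolution(
        beta0=float(beta0),
        estimate=float(est),
        std=float(np.sqrt(var)),
        bracket=bracket,
        n_iter=n_iter,
        converged=bool(resid <= max(cfg.tol, 1e3 * np.finfo(float).eps * max(1, abs(est)))),
        degenerate=False,
    )


def evidence_profile(
    model: PropertyModel, counts: Any, cfg: SolverConfig
) -> list[MemberSummary]:
    """One MemberSummary per point of ``cfg.beta_grid``."""
    if cfg.beta_grid is None or len(cfg.beta_grid) == 0:
        raise ValueError("evidence_profile requires a non-empty cfg.beta_grid")
    zero = model.zero_counts(counts)
    scale = float(model.beta_scale(counts))
    out = []
    for beta in cfg.beta_grid:
        beta = float(beta)
        out.append(
            MemberSummary(
                beta=beta,
                gamma=beta / scale,
                prior_mean=member_posterior_mean(model, zero, beta, cfg),
                posterior_mean=member_posterior_mean(model, counts, beta, cfg),
                posterior_var=member_posterior_variance(model, counts, beta, cfg),
                log_evidence=log_marginal_likelihood(model, counts, beta),
            )
        )
    return out


def averaged_estimate(
    model: PropertyModel, counts: Any, cfg: SolverConfig
) -> tuple[float, float]:
    """Evidence-weighted average of the member estimates over ``beta_grid``.

    The posterior means are averaged with trapezoidal weights proportional
    to ``prior_weight(beta) * p(n|beta)`` (uniform prior weight by default).
    The returned std combines the within-member variance with the
    between-member spread of the means.
    """
    profile = evidence_profile(model, counts, cfg)
    betas = np.array([s.beta for s in profile])
    log_ev = np.array([s.log_evidence for s in profile])
    means = np.array([s.posterior_mean for s in profile])
    variances = np.array([s.posterior_var for s in profile])
    if cfg.prior_weight is not None:
        with np.errstate(divide="ignore"):
            log_ev = log_ev + np.log([max(cfg.prior_weight(b), 0.0) for b in betas])
    # trapezoid quadrature weights on the (possibly non-uniform) grid
    dx = np.zeros_like(betas)
    dx[1:] += np.diff(betas) / 2
    dx[:-1] += np.diff(betas) / 2
    log_w = log_ev - logsumexp(log_ev, b=dx)
    w = np.exp(log_w) * dx
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(
            "evidence underflow across the whole beta_grid; widen the grid"
        )
    w = w / total
    est = float(np.dot(w, means))
    var = float(np.dot(w, variances + (means - est) ** 2))
    return est, float(np.sqrt(max(var, 0.0)))
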