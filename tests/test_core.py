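"""Model-agnostic machinery: derivative identities, convexity, the MAP
fixed point, evidence profiles and evidence-weighted averaging."""

import dataclasses
import math

import numpy as np
import pytest

from propbayes.core import (
    SolverConfig,
    averaged_estimate,
    evidence_profile,
    log_marginal_likelihood,
    member_posterior_mean,
    member_posterior_variance,
    member_prior_mean,
    solve_map_beta,
)
from propbayes.counts import BinaryConditionalCounts, MultiplicityHistogram
from propbayes.entropy import ConvGrid, entropy_property_model
from propbayes.marginal import marginal_property_model
from propbayes.mi import LN2, mi_property_model


ENTROPY_GRID = ConvGrid(2048)


def _models():
    return {
        "marginal": marginal_property_model(),
        "mi": mi_property_model(),
        "entropy": entropy_property_model(ENTROPY_GRID),
    }


def _sample_counts(name):
    if name == "entropy":
        return MultiplicityHistogram.from_partition((2, 1, 1), 10)
    return BinaryConditionalCounts([(2, 1), (0, 3), (1, 0)], 10)


class TestPriorMeansBetaZero:
    def test_closed_forms(self, cfg):
        models = _models()
        c = _sample_counts("marginal")
        assert member_prior_mean(models["marginal"], c, 0.0, cfg) == pytest.approx(0.5)
        assert member_prior_mean(models["mi"], c, 0.0, cfg) == pytest.approx(
            LN2 - 0.5, abs=1e-8
        )
        m = MultiplicityHistogram.from_partition((1,), 2)
        assert member_prior_mean(models["entropy"], m, 0.0, cfg) == pytest.approx(
            0.5, abs=1e-3
        )


class TestCrossRouteConsistency:
    @pytest.mark.parametrize("name", ["marginal", "mi"])
    def test_analytic_matches_finite_difference_bivariate(self, name, cfg):
        model = _models()[name]
        numeric = dataclasses.replace(model, analytic_posterior_mean=None)
        c = _sample_counts(name)
        for beta in (-30.0, 0.0, 30.0):
            assert member_posterior_mean(model, c, beta, cfg) == pytest.approx(
                member_posterior_mean(numeric, c, beta, cfg), abs=1e-6
            )

    def test_leave_one_out_matches_finite_difference_entropy(self, cfg):
        model = entropy_property_model(ConvGrid(4096))
        numeric = dataclasses.replace(model, analytic_posterior_mean=None)
        m = MultiplicityHistogram.from_partition((2, 1, 1, 1, 1), 30)
        for beta in (-5.0, 0.0, 3.0):
            assert member_posterior_mean(model, m, beta, cfg) == pytest.approx(
                member_posterior_mean(numeric, m, beta, cfg), abs=1e-4
            )


class TestConvexityAndMonotonicity:
    @pytest.mark.parametrize("name", ["marginal", "mi", "entropy"])
    def test_log_partition_convex_and_means_monotone(self, name, cfg):
        model = _models()[name]
        counts = _sample_counts(name)
        scale = model.beta_scale(counts)
        betas = np.linspace(-20, 20, 41) * scale
        logz = np.array([model.log_partition(counts, b) for b in betas])
        second = np.diff(logz, 2)
        assert np.all(second >= -1e-6)
        post = np.array([member_posterior_mean(model, counts, b, cfg) for b in betas])
        prior = np.array([member_prior_mean(model, counts, b, cfg) for b in betas])
        assert np.all(np.diff(post) >= -1e-8)
        assert np.all(np.diff(prior) >= -1e-8)
        lo, hi = model.bounds(counts)
        tol = 1e-3 if name == "entropy" else 1e-12
        assert np.all(post >= lo - tol) and np.all(post <= hi + tol)

    def test_variance_non_negative(self, cfg):
        for name, model in _models().items():
            counts = _sample_counts(name)
            assert member_posterior_variance(model, counts, 1.5, cfg) >= 0.0


class TestEvidence:
    def test_entropy_zero_counts_evidence_identically_zero(self):
        model = entropy_property_model(ENTROPY_GRID)
        m = MultiplicityHistogram({0: 8})
        for beta in (-4.0, 0.0, 4.0):
            assert log_marginal_likelihood(model, m, beta) == 0.0

    def test_stationary_at_map(self, cfg):
        model = marginal_property_model()
        c = BinaryConditionalCounts([(1, 0)] * 18 + [(0, 1)] * 12, kx=50)
        sol = solve_map_beta(model, c, cfg)
        h = 1e-3 * max(1.0, abs(sol.beta0))
        fd = (
            log_marginal_likelihood(model, c, sol.beta0 + h)
            - log_marginal_likelihood(model, c, sol.beta0 - h)
        ) / (2 * h)
        assert abs(fd) <= 1e-7


class TestMapSolver:
    @pytest.mark.parametrize("name", ["marginal", "mi", "entropy"])
    def test_zero_counts_degenerate_at_beta_zero(self, name, cfg):
        model = _models()[name]
        counts = _sample_counts(name)
        empty = model.zero_counts(counts)
        sol = solve_map_beta(model, empty, cfg)
        assert sol.degenerate and sol.beta0 == 0.0 and sol.converged

    def test_fixed_point_residual(self, cfg):
        model = mi_property_model()
        c = BinaryConditionalCounts([(0, 2)] * 3 + [(1, 1)], kx=30)
        sol = solve_map_beta(model, c, cfg)
        assert sol.converged
        resid = abs(
            member_posterior_mean(model, c, sol.beta0, cfg)
            - member_prior_mean(model, c, sol.beta0, cfg)
        )
        assert resid <= cfg.tol

    def test_coincidence_free_mi_data_is_degenerate(self, cfg):
        model = mi_property_model()
        c = BinaryConditionalCounts([(1, 0)] * 6 + [(0, 1)] * 6, kx=40)
        sol = solve_map_beta(model, c, cfg)
        assert sol.degenerate and sol.beta0 == 0.0


class TestEvidenceProfile:
    def test_grid_point_at_zero_reproduces_closed_forms(self):
        model = mi_property_model()
        c = BinaryConditionalCounts([(1, 1)] * 3, kx=3)
        cfg = SolverConfig(beta_grid=np.array([-3.0, 0.0, 3.0]) * 3)
        profile = evidence_profile(model, c, cfg)
        at_zero = profile[1]
        assert at_zero.beta == 0.0
        assert at_zero.prior_mean == pytest.approx(LN2 - 0.5, abs=1e-8)
        assert at_zero.posterior_mean == pytest.approx(LN2 - 7 / 12, abs=1e-8)

    def test_variance_matches_grid_curvature_of_log_partition(self):
        model = mi_property_model()
        c = BinaryConditionalCounts([(2, 1), (1, 1)], kx=5)
        betas = np.linspace(-1.0, 1.0, 9) * 5
        cfg = SolverConfig(beta_grid=betas)
        profile = evidence_profile(model, c, cfg)
        logz = np.array([model.log_partition(c, b) for b in betas])
        step = betas[1] - betas[0]
        curv = np.diff(logz, 2) / step**2
        for i, summary in enumerate(profile[1:-1], start=1):
            assert summary.posterior_var == pytest.approx(curv[i - 1], abs=step**2)

    def test_evidence_argmax_consistent_with_map(self, cfg):
        model = marginal_property_model()
        c = BinaryConditionalCounts([(1, 0)] * 18 + [(0, 1)] * 12, kx=50)
        sol = solve_map_beta(model, c, cfg)
        grid = np.linspace(sol.beta0 - 25 * 50, sol.beta0 + 25 * 50, 41)
        pcfg = SolverConfig(beta_grid=grid)
        profile = evidence_profile(model, c, pcfg)
        log_ev = np.array([s.log_evidence for s in profile])
        argmax = grid[np.argmax(log_ev)]
        assert abs(argmax - sol.beta0) <= grid[1] - grid[0]


class TestAveragedEstimate:
    def test_peaked_evidence_close_to_map(self, cfg):
        # many replicated coincidence states -> sharply peaked evidence
        model = mi_property_model()
        c = BinaryConditionalCounts([(0, 2)] * 120 + [(1, 1)] * 40, kx=1200)
        sol = solve_map_beta(model, c, cfg)
        grid = np.linspace(-60.0, 60.0, 241) * c.kx
        est, std = averaged_estimate(model, c, SolverConfig(beta_grid=grid))
        assert abs(est - sol.estimate) <= max(sol.std, 1e-3)

    def test_uniform_evidence_reduces_to_uniform_average(self):
        model = mi_property_model()
        c = BinaryConditionalCounts([(1, 0)] * 5 + [(0, 1)] * 5, kx=30)  # no coincidences
        grid = np.linspace(-2.0, 2.0, 21) * c.kx
        cfg = SolverConfig(beta_grid=grid)
        est, _ = averaged_estimate(model, c, cfg)
        means = np.array([member_posterior_mean(model, c, b, cfg) for b in grid])
        # trapezoid weights on a uniform grid: half weight at the ends
        w = np.ones_like(grid)
        w[0] = w[-1] = 0.5
        assert est == pytest.approx(np.dot(w, means) / w.sum(), rel=1e-9)

    def test_requires_grid(self):
        with pytest.raises(ValueError):
            averaged_estimate(
                mi_property_model(),
                BinaryConditionalCounts([(1, 1)], 2),
                SolverConfig(),
            )


class TestSolverConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SolverConfig(fd_step=0.0)
        with pytest.raises(ValueError):
            SolverConfig(bracket_init=(3.0, -3.0))
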