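"""Entropy model: convolution engine gates (closed forms at beta = 0,
Monte-Carlo oracle at beta != 0, resolution stability)."""

import math

import numpy as np
import pytest
from scipy.special import digamma, gammaln

from propbayes.core import SolverConfig, solve_map_beta
from propbayes.counts import CountVector, MultiplicityHistogram
from propbayes.entropy import (
    ConvGrid,
    entropy_log_partition,
    entropy_posterior_mean,
    entropy_prior_mean,
    entropy_property_model,
    estimate_entropy,
    mc_oracle,
    state_factor,
    wolpert_wolf_uniform,
)

GRID = ConvGrid(2048)


class TestStateFactor:
    def test_endpoint_conventions(self):
        w0 = state_factor(0, 0.0, GRID)
        assert np.all(w0 == 1.0)
        w1 = state_factor(1, 0.0, GRID)
        assert np.allclose(w1, GRID.x, atol=0)
        grid_with_half = ConvGrid(2049)  # 0.5 is a node
        wb = state_factor(0, 1.0, grid_with_half)
        assert wb[0] == 1.0 and wb[-1] == 1.0
        mid = np.argmin(abs(grid_with_half.x - 0.5))
        assert wb[mid] == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_positive_interior(self):
        w = state_factor(3, -4.0, GRID)
        assert np.all(w[1:] > 0)


class TestWolpertWolf:
    def test_half_nat_case(self):
        assert wolpert_wolf_uniform(CountVector((1, 0), 2)) == pytest.approx(0.5)

    def test_no_data_reduces_to_prior_mean(self):
        for k in (2, 7, 30):
            expected = digamma(k + 1) - digamma(2)
            assert wolpert_wolf_uniform(CountVector((), k)) == pytest.approx(expected)

    def test_k30_prior_value(self):
        # psi(31) - psi(2) = sum_{j=2}^{30} 1/j
        harmonic = sum(1 / j for j in range(2, 31))
        assert wolpert_wolf_uniform(CountVector((), 30)) == pytest.approx(
            harmonic, abs=1e-12
        )


class TestConvolutionEngineBetaZero:
    @pytest.mark.parametrize(
        "counts,k",
        [((0, 0), 2), ((1, 0), 2), ((2, 1, 0), 3), ((3, 1, 1), 5),
         ((4, 4, 2, 1, 1), 10), ((2, 1, 1, 1, 1), 30)],
    )
    def test_log_partition_matches_dirichlet_identity(self, counts, k):
        cv = CountVector(counts, k)
        mult = cv.to_multiplicities()
        lhs = entropy_log_partition(mult, 0.0, GRID) - entropy_log_partition(
            mult.empty_like(), 0.0, GRID
        )
        rhs = gammaln(k) - gammaln(cv.n + k) + sum(gammaln(c + 1) for c in counts)
        assert lhs == pytest.approx(rhs, abs=1e-3)

    def test_uniform_convolution_density_at_one(self):
        # two flat factors: density of U + U' at 1 is exactly 1
        m = MultiplicityHistogram({0: 2})
        assert entropy_log_partition(m, 0.0, GRID) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("counts,k", [((1, 0), 2), ((2, 1, 0), 3), ((2, 1, 1, 1, 1), 30)])
    def test_posterior_mean_matches_wolpert_wolf(self, counts, k):
        cv = CountVector(counts, k)
        conv = entropy_posterior_mean(cv.to_multiplicities(), 0.0, GRID)
        assert conv == pytest.approx(wolpert_wolf_uniform(cv), abs=1e-3)


class TestMcOracle:
    def test_self_consistency_at_beta_zero(self):
        m = CountVector((2, 1, 0), 3).to_multiplicities()
        res = mc_oracle(m, 0.0, 50_000, seed=3)
        assert res.log_z_ratio == 0.0
        assert abs(res.mean_h - wolpert_wolf_uniform(m.to_counts())) <= 3 * res.se_mean_h

    @pytest.mark.parametrize("beta", [-2.0, 2.0])
    def test_brackets_convolution_results(self, beta):
        m = CountVector((2, 1, 0), 3).to_multiplicities()
        res = mc_oracle(m, beta, 200_000, seed=11)
        pm = entropy_posterior_mean(m, beta)
        lzr = entropy_log_partition(m, beta) - entropy_log_partition(m, 0.0)
        assert abs(pm - res.mean_h) <= 3 * res.se_mean_h + 1e-3
        assert abs(lzr - res.log_z_ratio) <= 3 * res.se_log_z_ratio + 1e-3


class TestPriorMean:
    def test_beta_zero_closed_forms(self):
        assert entropy_prior_mean(2, 0.0, GRID) == pytest.approx(0.5, abs=1e-3)
        assert entropy_prior_mean(30, 0.0, GRID) == pytest.approx(
            digamma(31) - digamma(2), abs=1e-3
        )

    def test_monotone_in_k_and_beta(self):
        values = [entropy_prior_mean(k, 0.0, GRID) for k in (2, 5, 10, 30)]
        assert np.all(np.diff(values) > 0)
        k = 10
        by_beta = [entropy_prior_mean(k, b, GRID) for b in (-10.0, -2.0, 0.0, 2.0, 10.0)]
        assert np.all(np.diff(by_beta) > 0)
        assert all(0 <= v <= math.log(k) for v in by_beta)

    def test_strong_negative_tilt_kills_entropy(self):
        m = CountVector((2, 1), 3).to_multiplicities()
        assert entropy_posterior_mean(m, -60.0) < 0.1


class TestResolutionStability:
    @pytest.mark.parametrize("partition", [(2, 1, 1, 1, 1), (4, 2)])
    def test_default_grid_vs_doubled(self, partition):
        m = MultiplicityHistogram.from_partition(partition, 30)
        g1, g2 = ConvGrid(4096), ConvGrid(8192)
        for beta in (-5.0, 0.0, 5.0):
            a = entropy_posterior_mean(m, beta, g1)
            b = entropy_posterior_mean(m, beta, g2)
            assert abs(a - b) <= 1e-4


class TestEstimateEntropy:
    def test_permutation_invariance(self):
        cfg = SolverConfig()
        a = estimate_entropy(CountVector((2, 1, 1, 1, 1, 0), 30), cfg)
        b = estimate_entropy(CountVector((1, 1, 2, 0, 1, 1), 30), cfg)
        assert a.estimate == b.estimate and a.beta0 == b.beta0

    def test_single_occupied_state_bounds(self):
        sol = estimate_entropy(CountVector((6,), 30), SolverConfig())
        assert 0.0 < sol.estimate < math.log(30)
        assert sol.beta0 < 0  # concentrated data pull toward low entropy

    def test_tiny_k_one_signed_discrepancy_raises(self):
        # at k = 2 the prior/posterior entropy curves need not intersect:
        # the discrepancy stays one-signed and the solver reports it.
        with pytest.raises(RuntimeError, match="no sign change"):
            estimate_entropy(CountVector((3, 0), 2), SolverConfig())

    def test_k_warning_when_support_used(self):
        # the warning fires regardless of whether the tiny-k solve then
        # finds an interior fixed point
        with pytest.warns(RuntimeWarning, match="observed support"):
            try:
                estimate_entropy(CountVector((2, 1, 1)), SolverConfig())
            except RuntimeError:
                pass

    def test_k1_degenerate(self):
        model = entropy_property_model()
        m = MultiplicityHistogram({3: 1})
        sol = solve_map_beta(model, m)
        assert sol.degenerate and sol.estimate == 0.0
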