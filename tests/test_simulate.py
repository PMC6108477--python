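"""Synthetic-data generators, RSSE, and the benchmark harness."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from catopt import (
    ProbabilityTable,
    SimulationSpec,
    gen_auxiliary,
    gen_discretized_mvnormal,
    gen_two_level_uniform,
    mle_estimate,
    rsse,
    run_benchmark,
    setting_spec,
    shuffle_category_labels,
    summarize_benchmark,
)


class TestTwoLevelUniform:
    def test_dependent_block_cell_probability(self):
        # aligned low block: 0.7 / prod(m_i/2); outside both blocks: 0
        _, truth = gen_two_level_uniform(
            m=(100, 100, 100), p_super=0.7, dependent=True, n=10, seed=0,
            shuffle=False,
        )
        low = ["c000"] * 3
        high = ["c099"] * 3
        mixed = ["c000", "c000", "c099"]
        assert truth.probability(low) == pytest.approx(0.7 / 125_000)
        assert truth.probability(high) == pytest.approx(0.3 / 125_000)
        assert truth.probability(mixed) == 0.0

    def test_independent_top_block_cell_probability(self):
        # p = (0.7, 0.8, 0.9): top block cell mass 0.504 / prod(m_i/2)
        _, truth = gen_two_level_uniform(
            m=(100, 100, 100), p_super=(0.7, 0.8, 0.9), dependent=False, n=10,
            seed=0, shuffle=False,
        )
        assert truth.probability(["c000"] * 3) == pytest.approx(0.504 / 125_000)

    def test_truth_sums_to_one(self):
        for dependent in (True, False):
            _, truth = gen_two_level_uniform(
                m=(20, 20, 20),
                p_super=0.7 if dependent else (0.7, 0.8, 0.9),
                dependent=dependent,
                n=5,
                seed=1,
            )
            assert truth.total() == pytest.approx(1.0, abs=1e-12)

    def test_odd_category_count_rejected(self):
        with pytest.raises(ValueError):
            gen_two_level_uniform(m=(21, 20, 20), n=5)

    def test_samples_respect_zero_probability_cells(self):
        obs, truth = gen_two_level_uniform(
            m=(10, 10, 10), p_super=0.7, dependent=True, n=400, seed=3
        )
        dense = truth.to_dense()
        for row in obs.codes:
            assert dense[tuple(row)] > 0


class TestDiscretizedNormal:
    def test_zero_correlation_factorizes(self):
        _, truth = gen_discretized_mvnormal(
            m=(8, 8, 8), corr=0.0, n=5, seed=0, shuffle=False
        )
        dense = truth.to_dense()
        m1 = dense.sum(axis=(1, 2))
        m2 = dense.sum(axis=(0, 2))
        m3 = dense.sum(axis=(0, 1))
        product = m1[:, None, None] * m2[None, :, None] * m3[None, None, :]
        np.testing.assert_allclose(dense, product, atol=1e-9)

    def test_symmetric_grid_reflection_invariance(self):
        _, truth = gen_discretized_mvnormal(
            m=(8, 8, 8), corr=0.5, n=5, seed=0, shuffle=False
        )
        dense = truth.to_dense()
        np.testing.assert_allclose(dense, dense[::-1, ::-1, ::-1], atol=1e-12)

    def test_cell_masses_match_cdf_differencing_oracle(self):
        # independent check through the normal CDF over a few cells
        corr = 0.3
        m = 6
        _, truth = gen_discretized_mvnormal(
            m=(m, m, m), corr=corr, n=5, seed=0, shuffle=False
        )
        dense = truth.to_dense()
        cov = np.full((3, 3), corr)
        np.fill_diagonal(cov, 1.0)
        dist = multivariate_normal(mean=np.zeros(3), cov=cov)
        edges = np.linspace(-3, 3, m + 1)
        total = 0.0
        cells = [(0, 0, 0), (2, 3, 1), (3, 3, 3), (5, 1, 4)]
        for cell in cells:
            corners = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        sign = (-1) ** (3 - dx - dy - dz)
                        point = [
                            edges[cell[0] + dx],
                            edges[cell[1] + dy],
                            edges[cell[2] + dz],
                        ]
                        corners += sign * dist.cdf(point)
            total += corners
            # quadrature truth is renormalized over the truncated grid, the
            # CDF oracle is not; the truncation holds ~0.8% of the mass
            assert dense[cell] == pytest.approx(corners, rel=2e-2)
        assert total > 0

    def test_non_positive_definite_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            gen_discretized_mvnormal(m=(4, 4), cov=bad, n=5, seed=0)


class TestAuxiliaryFamilies:
    def test_equal_mass_supers_give_uniform_cells(self):
        _, truth = gen_auxiliary(
            "multi_super_uniform", m=(10, 10, 10), n=5, seed=0,
            k_super=5, masses="equal", shuffle=False,
        )
        dense = truth.to_dense()
        np.testing.assert_allclose(dense, 1.0 / dense.size, atol=1e-12)

    def test_additive_exponential_is_a_distribution(self):
        _, truth = gen_auxiliary(
            "additive_exponential", m=(8, 8, 8), n=5, seed=0, rate=1.0
        )
        dense = truth.to_dense()
        assert np.all(dense >= 0)
        assert dense.sum() == pytest.approx(1.0, abs=1e-9)

    def test_clayton_matches_monte_carlo_copula_draws(self):
        theta = 2.0
        m = 5
        _, truth = gen_auxiliary(
            "clayton_uniform", m=(m, m, m), n=5, seed=0, theta=theta,
            shuffle=False,
        )
        dense = truth.to_dense()
        # Marshall-Olkin sampler for the Clayton copula
        rng = np.random.default_rng(7)
        n_mc = 200_000
        g = rng.gamma(1.0 / theta, size=n_mc)
        e = rng.exponential(size=(n_mc, 3))
        u = (1.0 + e / g[:, None]) ** (-1.0 / theta)
        cells = np.minimum((u * m).astype(int), m - 1)
        emp = np.zeros((m, m, m))
        np.add.at(emp, tuple(cells.T), 1.0)
        emp /= n_mc
        assert np.abs(dense - emp).max() < 0.01

    def test_lognormal_truth_normalized(self):
        _, truth = gen_auxiliary("lognormal", m=(8, 8, 8), n=5, seed=0, corr=0.2)
        assert truth.to_dense().sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            gen_auxiliary("no_such_family", n=5, seed=0)


class TestShuffle:
    @pytest.fixture
    def data(self):
        return gen_two_level_uniform(
            m=(10, 10, 10), p_super=(0.7, 0.8, 0.9), n=300, seed=5, shuffle=False
        )

    def test_mle_rsse_invariant_under_shuffling(self, data):
        obs, truth = data
        before = rsse(mle_estimate(obs), truth)
        obs2, truth2 = shuffle_category_labels(obs, truth, seed=11)
        after = rsse(mle_estimate(obs2), truth2)
        assert after == pytest.approx(before, abs=1e-12)

    def test_double_shuffle_with_same_stream_changes_then_preserves_mass(self, data):
        obs, truth = data
        obs2, truth2 = shuffle_category_labels(obs, truth, seed=11)
        assert truth2.total() == pytest.approx(truth.total())
        assert obs2.total_weight == obs.total_weight

    def test_shuffle_applies_a_consistent_permutation(self, data):
        obs, truth = data
        obs2, truth2 = shuffle_category_labels(obs, truth, seed=11)
        dense, dense2 = truth.to_dense(), truth2.to_dense()
        # recover the per-variable permutation from the observations
        rng = np.random.default_rng(11)
        perms = [rng.permutation(m) for m in obs.space.sizes]
        np.testing.assert_array_equal(perms[0][obs.codes[:, 0]], obs2.codes[:, 0])
        np.testing.assert_allclose(
            dense2[np.ix_(*perms)], dense, atol=1e-15
        )


class TestRSSE:
    def test_identical_tables_give_zero(self):
        _, truth = gen_two_level_uniform(m=(6, 6, 6), p_super=0.7, dependent=True,
                                         n=5, seed=0)
        assert rsse(truth, truth) == 0.0

    def test_point_mass_on_zero_cell_closed_form(self):
        _, truth = gen_two_level_uniform(
            m=(6, 6, 6), p_super=0.7, dependent=True, n=5, seed=0, shuffle=False
        )
        # all estimated mass on a cell where the truth is 0
        est = ProbabilityTable(
            truth.space,
            cell_codes=np.array([[0, 0, 5]]),  # low x low x high: zero truth
            cell_probs=np.array([1.0]),
        )
        expected = np.sqrt(1.0 + np.sum(truth.to_dense() ** 2))
        assert rsse(est, truth) == pytest.approx(expected, abs=1e-12)

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(2)
        obs, truth = gen_two_level_uniform(m=(6, 6, 6), p_super=(0.7, 0.8, 0.9),
                                           n=100, seed=3)
        est = mle_estimate(obs)
        oracle = float(
            np.sqrt(np.sum((est.to_dense() - truth.to_dense()) ** 2))
        )
        assert rsse(est, truth) == pytest.approx(oracle, abs=1e-12)

    def test_bounded_by_sqrt_two(self):
        obs, truth = gen_two_level_uniform(m=(6, 6, 6), p_super=0.7,
                                           dependent=True, n=20, seed=4)
        assert rsse(mle_estimate(obs), truth) <= np.sqrt(2.0)


class TestBenchmark:
    def test_fixed_seed_reproduces_results(self):
        spec = setting_spec(2, m=10, n=100)
        r1 = run_benchmark(spec, ["mle"], replicates=2, seed=9)
        r2 = run_benchmark(spec, ["mle"], replicates=2, seed=9)
        assert r1.equals(r2)

    def test_mle_mean_rsse_matches_analytic_expectation(self):
        # E[sum (p_hat - p)^2] = (1 - sum p^2)/n for the multinomial MLE
        spec = setting_spec(2, m=10, n=500)
        results = run_benchmark(spec, ["mle"], replicates=60, seed=21)
        _, truth = spec.generate(0)
        p2 = float(np.sum(truth.to_dense() ** 2))
        analytic_sq = (1.0 - p2) / spec.n
        sq = results["rsse"].to_numpy() ** 2
        se = sq.std(ddof=1) / np.sqrt(sq.size)
        assert abs(sq.mean() - analytic_sq) < 3 * se

    def test_summary_reports_cv_as_sd_over_mean(self):
        spec = setting_spec(1, m=10, n=100)
        results = run_benchmark(spec, ["mle", "kde"], replicates=3, seed=2)
        summary = summarize_benchmark(results)
        for _, row in summary.iterrows():
            assert row["cv"] == pytest.approx(row["sd_rsse"] / row["mean_rsse"])

    def test_opt_error_decreases_with_sample_size(self):
        # n-consistency of the posterior-mean estimate on setting (2)
        means = []
        for n in (800, 3200, 12800):
            spec = setting_spec(2, m=20, n=n)
            res = run_benchmark(spec, ["opt"], replicates=3, seed=31)
            means.append(res["rsse"].mean())
        assert means[0] > means[1] > means[2]
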