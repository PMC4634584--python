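import numpy as np
import pytest
from scipy.stats import kstest

from deges import CountMatrix, GroupDesign, SimulationConfig, simulate_counts
from deges.glm import (
    DispersionEstimates,
    bh_adjust,
    estimate_blind_dispersion,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    fit_gene_nb,
    lrt_test,
)
from deges.norm import simple_factors
from deges.simulate import NBParamPool
from oracles import bh_double_loop, grid_max_group_loglik, nb_loglik_scalar


def _pool(mu_log_mean=np.log(100), sigma=1.0, phi=0.2, n=2000, seed=0):
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(mu_log_mean, sigma, n))
    return NBParamPool(mu, np.full(n, phi))


class TestFitGeneNB:
    def test_equal_counts_full_equals_null(self):
        y = np.full(9, 30)
        offsets = np.zeros(9)
        gidx = np.repeat([0, 1, 2], 3)
        mu_f, ll_f = fit_gene_nb(y, offsets, gidx, 0.05, model="full")
        mu_n, ll_n = fit_gene_nb(y, offsets, gidx, 0.05, model="null")
        np.testing.assert_allclose(mu_f, mu_n, rtol=1e-8)
        assert abs(ll_f - ll_n) < 1e-8

    def test_poisson_closed_form(self):
        y = np.array([12, 8, 15, 10])
        offsets = np.log(np.array([1.0, 2.0, 1.5, 0.5]))
        mu, ll = fit_gene_nb(y, offsets, np.zeros(4, dtype=int), 0.0, model="null")
        # Poisson MLE: exp(beta) = sum(y) / sum(exp(offsets))
        beta_hat = np.log(y.sum() / np.exp(offsets).sum())
        np.testing.assert_allclose(mu, np.exp(beta_hat + offsets), rtol=1e-8)
        np.testing.assert_allclose(ll, nb_loglik_scalar(y, mu, 0.0), rtol=1e-10)

    def test_three_group_toy_matches_grid_oracle(self):
        y = np.array([10, 12, 11, 40, 38, 42, 9, 11, 10])
        gidx = np.repeat([0, 1, 2], 3)
        offsets = np.zeros(9)
        phi = 0.05
        _, ll_full = fit_gene_nb(y, offsets, gidx, phi, model="full")
        expected = sum(
            grid_max_group_loglik(y[gidx == k], phi) for k in range(3)
        )
        assert abs(ll_full - expected) < 1e-6
        _, ll_null = fit_gene_nb(y, offsets, gidx, phi, model="null")
        assert abs(ll_null - grid_max_group_loglik(y, phi)) < 1e-6


class TestCommonDispersion:
    def test_poisson_data_small_estimate(self):
        cfg = SimulationConfig(
            n_gene=2000, p_deg=0.0, group_sizes=(3, 3, 3),
            pool=_pool(phi=0.0, seed=1), seed=6,
        )
        m, _, design = simulate_counts(cfg)
        assert estimate_common_dispersion(m, design) < 0.02

    def test_recovers_phi_point_two(self):
        cfg = SimulationConfig(
            n_gene=2000, p_deg=0.0, group_sizes=(3, 3, 3),
            pool=_pool(phi=0.2, seed=0), seed=5,
        )
        m, _, design = simulate_counts(cfg)
        assert 0.15 < estimate_common_dispersion(m, design) < 0.25

    def test_single_sample_per_group_errors(self):
        cfg = SimulationConfig(n_gene=100, p_deg=0.0, group_sizes=(1, 1, 1), seed=0)
        m, _, design = simulate_counts(cfg)
        with pytest.raises(ValueError, match="blind"):
            estimate_common_dispersion(m, design)


@pytest.fixture(scope="module")
def mixed_phi_data():
    """Half the genes at phi=0.05, half at phi=0.4 (known per-gene truth)."""
    from deges.simulate import nb_draw

    rng = np.random.default_rng(3)
    mu = np.exp(rng.normal(np.log(200), 0.5, 2000))
    phi = np.where(np.arange(2000) < 1000, 0.05, 0.4)
    means = np.repeat(mu[:, None], 9, axis=1)
    counts = nb_draw(means, phi[:, None], np.random.default_rng(4))
    m = CountMatrix([f"g{i}" for i in range(2000)], [f"s{j}" for j in range(9)], counts)
    design = GroupDesign({f"s{j}": f"G{j // 3 + 1}" for j in range(9)})
    return m, design, phi


class TestTagwiseDispersion:
    def test_huge_prior_recovers_common(self, mixed_phi_data):
        m, design, _ = mixed_phi_data
        common = estimate_common_dispersion(m, design)
        tw = estimate_tagwise_dispersion(m, design, prior_df=1e12)
        np.testing.assert_allclose(tw, common, rtol=0.15)

    def test_shrinkage_beats_both_extremes(self, mixed_phi_data):
        m, design, true_phi = mixed_phi_data
        common = estimate_common_dispersion(m, design)
        unshrunk = estimate_tagwise_dispersion(m, design, prior_df=0.0)
        shrunk = estimate_tagwise_dispersion(m, design, prior_df=10.0)

        def rmse(est):
            return np.sqrt(np.mean((est - true_phi) ** 2))

        assert rmse(shrunk) < rmse(unshrunk)
        assert rmse(shrunk) < rmse(np.full(2000, common))
        # shrunken estimates separate the two sub-populations
        assert np.median(shrunk[:1000]) < np.median(shrunk[1000:])

    def test_negative_prior_rejected(self, mixed_phi_data):
        m, design, _ = mixed_phi_data
        with pytest.raises(ValueError):
            estimate_tagwise_dispersion(m, design, prior_df=-1.0)


class TestBlindDispersion:
    def test_identical_columns_phi_near_zero(self):
        col = np.random.default_rng(0).poisson(80, 500) + 1
        m = CountMatrix(
            [f"g{i}" for i in range(500)], ["a", "b", "c"], np.column_stack([col] * 3)
        )
        assert estimate_blind_dispersion(m) < 0.01

    def test_de_inflates_blind_phi(self):
        cfg = SimulationConfig(
            n_gene=4000, p_deg=0.25, group_sizes=(1, 1, 1),
            deg_proportions=(1 / 3, 1 / 3, 1 / 3), seed=9,
        )
        m, truth, _ = simulate_counts(cfg)
        blind = estimate_blind_dispersion(m)
        non_deg_only = estimate_blind_dispersion(m.subset_genes(~truth.is_deg))
        assert blind > non_deg_only

    def test_phi_monotone_in_injected_fold_change(self):
        rng = np.random.default_rng(10)
        base = rng.poisson(100, size=(400, 3)) + 1
        phis = []
        for fold in (1.0, 2.0, 4.0, 8.0):
            counts = base.copy()
            counts[:100, 0] = np.round(counts[:100, 0] * fold)
            m = CountMatrix(
                [f"g{i}" for i in range(400)], ["a", "b", "c"], counts
            )
            phis.append(estimate_blind_dispersion(m))
        assert all(a <= b + 1e-9 for a, b in zip(phis, phis[1:]))

    def test_single_sample_errors(self):
        m = CountMatrix(["g1"], ["s1"], np.array([[5]]))
        with pytest.raises(ValueError):
            estimate_blind_dispersion(m)


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = np.round(rng.uniform(size=rng.integers(1, 30)), 2)
            np.testing.assert_allclose(bh_adjust(p), bh_double_loop(p), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


@pytest.fixture(scope="module")
def null_result():
    """LRT on DEG-free data at fixed (mu, phi) = (200, 0.1), known phi."""
    pool = NBParamPool(np.array([200.0]), np.array([0.1]))
    cfg = SimulationConfig(n_gene=10000, p_deg=0.0, group_sizes=(3, 3, 3), pool=pool, seed=21)
    m, _, design = simulate_counts(cfg)
    nrm = simple_factors(m, "none")
    disp = DispersionEstimates(0.1, np.full(10000, 0.1))
    return lrt_test(m, design, nrm, disp)


class TestLRT:
    def test_chi_square_calibration_known_phi(self, null_result):
        # under the null with the true dispersion supplied, p-values are
        # uniform (Kolmogorov-Smirnov at alpha = 0.01)
        assert kstest(null_result.p_value, "uniform").pvalue > 0.01

    def test_type_one_error_near_nominal(self, null_result):
        frac = (null_result.p_value < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_lr_nonnegative(self, null_result):
        assert np.all(null_result.lr_stat >= 0)

    def test_identical_group_means_lr_zero(self):
        m = CountMatrix(
            ["g1"], [f"s{j}" for j in range(9)], np.full((1, 9), 25, dtype=int)
        )
        design = GroupDesign({f"s{j}": f"G{j // 3 + 1}" for j in range(9)})
        res = lrt_test(m, design, simple_factors(m, "none"), DispersionEstimates(0.1, np.array([0.1])))
        assert res.lr_stat[0] < 1e-6
        assert res.p_value[0] > 0.999

    def test_strong_deg_power(self):
        # 4-fold DEG at mu=200, phi=0.01, Nrep=3 -> tiny p-value
        rng = np.random.default_rng(2)
        from deges.simulate import nb_draw

        means = np.full((1, 9), 200.0)
        means[0, :3] *= 4
        counts = nb_draw(means, np.array([[0.01]]), rng)
        m = CountMatrix(["g1"], [f"s{j}" for j in range(9)], counts)
        design = GroupDesign({f"s{j}": f"G{j // 3 + 1}" for j in range(9)})
        # unit offsets: a one-gene matrix's library sizes are the gene's own
        # counts and would absorb the group difference
        res = lrt_test(m, design, np.zeros(9), DispersionEstimates(0.01, np.array([0.01])))
        assert res.p_value[0] < 1e-4

    def test_offset_scale_invariance(self):
        cfg = SimulationConfig(n_gene=300, p_deg=0.1, group_sizes=(3, 3, 3), seed=13)
        m, _, design = simulate_counts(cfg)
        nrm = simple_factors(m, "none")
        disp = DispersionEstimates(0.1, np.full(300, 0.1))
        res1 = lrt_test(m, design, nrm.offsets(), disp)
        res2 = lrt_test(m, design, nrm.offsets() + np.log(7.0), disp)
        np.testing.assert_allclose(res1.p_value, res2.p_value, atol=1e-9)
        np.testing.assert_array_equal(res1.rank, res2.rank)

    def test_all_zero_gene_filtered_and_ranked_last(self):
        counts = np.vstack([np.full(9, 40), np.zeros(9), np.full(9, 10)]).astype(int)
        counts[2, :3] = 60
        m = CountMatrix(["a", "b", "c"], [f"s{j}" for j in range(9)], counts)
        design = GroupDesign({f"s{j}": f"G{j // 3 + 1}" for j in range(9)})
        res = lrt_test(m, design, simple_factors(m, "none"), DispersionEstimates(0.1, np.full(3, 0.1)))
        assert not res.tested[1]
        assert res.n_filtered == 1
        assert res.q_value[1] == 1.0
        assert res.rank[1] == 3  # after both tested genes

    def test_rank_follows_p_with_lr_tiebreak(self, null_result):
        order = np.argsort(null_result.rank)
        p_sorted = null_result.p_value[order]
        assert np.all(np.diff(p_sorted) >= -1e-15)
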