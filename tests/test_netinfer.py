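import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coocnet.io_model import AbundanceTable
from coocnet.netinfer import (
    DeconvolutionParams,
    EdgeCandidate,
    InferenceConfig,
    bh_adjust,
    bootstrap_distribution,
    both_measure_support,
    braycurtis_similarity,
    browns_merge,
    deconvolve,
    empirical_brown_covariance,
    infer_environment_network,
    permutation_null,
    reboot_pvalue,
    rmt_threshold,
    spearman_score,
)
from coocnet.synthetic import PlantedDesign, PlantedEdge, generate_dataset


def random_table(n_esvs=10, n_samples=40, seed=0):
    rng = np.random.default_rng(seed)
    return AbundanceTable(
        [f"E{i}" for i in range(n_esvs)],
        [f"S{j}" for j in range(n_samples)],
        rng.integers(0, 200, size=(n_esvs, n_samples)),
    )


class TestMeasures:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ])
    def test_spearman_hand_values(self, x, y, expected):
        assert spearman_score(x, y) == pytest.approx(expected, abs=1e-12)

    def test_spearman_constant_vector_undefined(self):
        assert np.isnan(spearman_score([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("x,y,expected", [
        ([0.2, 0.5, 0.3], [0.2, 0.5, 0.3], 1.0),
        ([1, 0, 0], [0, 1, 1], 0.0),
        ([1, 1], [1, 3], 2 / 3),
    ])
    def test_braycurtis_hand_values(self, x, y, expected):
        assert braycurtis_similarity(x, y) == pytest.approx(expected, abs=1e-12)

    def test_braycurtis_all_zero_undefined(self):
        assert np.isnan(braycurtis_similarity([0, 0], [0, 0]))


class TestPermutationNull:
    def test_preserves_count_multiset(self):
        table = random_table(seed=1)
        rng = np.random.default_rng(0)
        row = table.counts[2].astype(float)
        perms = rng.permuted(np.tile(row, (50, 1)), axis=1)
        for p in perms:
            assert sorted(p) == sorted(row)

    def test_seed_determinism(self):
        table = random_table(seed=2)
        a = permutation_null(table, ("E1", "E2"), "spearman", 100, seed=9)
        b = permutation_null(table, ("E1", "E2"), "spearman", 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_null_mean_near_zero_for_independent_data(self):
        table = random_table(n_esvs=5, n_samples=100, seed=3)
        null = permutation_null(table, ("E0", "E1"), "spearman", 1000,
                                renormalize=False, seed=0)
        se = np.nanstd(null) / np.sqrt(len(null))
        assert abs(np.nanmean(null)) < 3 * se + 1e-3

    def test_renormalized_null_captures_compositional_bias(self):
        # a pair holding a large share of a 5-ESV composition: the
        # renormalized null is shifted negative (shared-denominator coupling)
        table = random_table(n_esvs=5, n_samples=100, seed=3)
        null = permutation_null(table, ("E0", "E1"), "spearman", 1000,
                                renormalize=True, seed=0)
        assert np.nanmean(null) < -0.05

    def test_rejects_nonpositive_iterations(self):
        with pytest.raises(ValueError):
            permutation_null(random_table(), ("E0", "E1"), n_iter=0)


class TestBootstrap:
    def test_single_sample_errors(self):
        t = AbundanceTable(["a", "b"], ["s"], np.array([[1], [2]]))
        with pytest.raises(ValueError):
            bootstrap_distribution(t, ("a", "b"))

    def test_seed_determinism(self):
        table = random_table(seed=4)
        a = bootstrap_distribution(table, ("E0", "E3"), "bc", 100, seed=5)
        b = bootstrap_distribution(table, ("E0", "E3"), "bc", 100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_bootstrap_mean_tracks_sample_score(self):
        table = random_table(n_esvs=4, n_samples=200, seed=6)
        rel = table.relative_abundance()
        observed = spearman_score(rel[0], rel[1])
        boots = bootstrap_distribution(table, ("E0", "E1"), "spearman", 1000, seed=1)
        assert abs(np.nanmean(boots) - observed) < 0.05


class TestRebootPvalue:
    def test_equal_means_give_one(self):
        boot = np.array([0.4, 0.5, 0.6])
        null = np.full(10, boot.mean())
        assert reboot_pvalue(null, boot) == pytest.approx(1.0)

    def test_gaussian_tail_hand_value(self):
        rng = np.random.default_rng(0)
        boot = rng.normal(0.5, 0.1, 200_000)
        null = np.full(10, 0.696)
        assert reboot_pvalue(null, boot) == pytest.approx(0.05, abs=0.002)

    def test_degenerate_bootstrap(self):
        assert reboot_pvalue(np.array([0.5]), np.array([0.5, 0.5])) == 1.0
        assert reboot_pvalue(np.array([0.9]), np.array([0.5, 0.5])) == 0.0


class TestBrownsMerge:
    def test_unit_pvalues_merge_to_one(self):
        assert browns_merge(1.0, 1.0, 0.0) == pytest.approx(1.0)

    def test_fisher_at_zero_covariance(self):
        assert browns_merge(0.05, 0.05, 0.0) == pytest.approx(0.0175, abs=2e-4)

    def test_perfect_dependence_returns_p(self):
        for p in (0.01, 0.2, 0.77):
            assert browns_merge(p, p, 4.0) == pytest.approx(p, rel=1e-9)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_fisher_equivalence_property(self, ps):
        """Zero covariance reduces Brown's method to Fisher's method exactly."""
        from scipy import stats

        for p in ps:
            t = -2 * (np.log(p) + np.log(p))
            fisher = stats.chi2.sf(t, 4)
            assert browns_merge(p, p, 0.0) == pytest.approx(fisher, rel=1e-12)

    def test_empirical_covariance_clamped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 1, 100)
        cov = empirical_brown_covariance(p, p)
        assert 0.0 <= cov <= 4.0


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_vector(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_never_decreases(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestRmtThreshold:
    def test_identity_matrix_returns_scan_start(self):
        result = rmt_threshold(np.eye(100))
        assert result.threshold == pytest.approx(0.30)
        assert not result.fallback_used

    def test_null_correlation_matrix_threshold_exceeds_null_quantile(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((500, 100))
        corr = np.corrcoef(x.T)
        null_q99 = np.quantile(np.abs(corr[np.triu_indices(100, 1)]), 0.99)
        result = rmt_threshold(np.abs(corr))
        assert result.threshold > null_q99

    def test_small_matrix_falls_back_with_warning(self):
        m = np.full((5, 5), 0.8)
        np.fill_diagonal(m, 1.0)
        result = rmt_threshold(m)
        assert result.fallback_used
        assert result.threshold == pytest.approx(0.30)

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError):
            rmt_threshold(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestBothMeasureSupport:
    def test_positive_edge_supported(self):
        cand = EdgeCandidate(("a", "b"), rho=0.9, bc_sim=0.9,
                             p_spearman_adj=0.01, p_bc_adj=0.01)
        assert both_measure_support(cand, 0.5, 0.5)

    def test_single_measure_not_enough(self):
        cand = EdgeCandidate(("a", "b"), rho=0.9, bc_sim=0.9,
                             p_spearman_adj=0.01, p_bc_adj=0.5)
        assert not both_measure_support(cand, 0.5, 0.5)

    def test_negative_edge_uses_low_bc_tail(self):
        cand = EdgeCandidate(("a", "b"), rho=-0.9, bc_sim=0.05,
                             p_spearman_adj=0.01, p_bc_adj=0.01)
        assert both_measure_support(cand, 0.5, 0.5)
        # high similarity contradicts mutual exclusion
        cand2 = EdgeCandidate(("a", "b"), rho=-0.9, bc_sim=0.9,
                              p_spearman_adj=0.01, p_bc_adj=0.01)
        assert not both_measure_support(cand2, 0.5, 0.5)


class TestDeconvolve:
    def test_zero_matrix_unchanged(self):
        np.testing.assert_array_equal(deconvolve(np.zeros((4, 4))), np.zeros((4, 4)))

    def test_chain_transitive_edge_ranked_below_direct(self):
        obs = np.array([
            [0.0, 0.8, 0.5],
            [0.8, 0.0, 0.8],
            [0.5, 0.8, 0.0],
        ])
        direct = deconvolve(obs)
        assert direct[0, 2] < direct[0, 1]
        assert direct[0, 2] < direct[1, 2]

    def test_preserves_symmetry(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-1, 1, (10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        out = deconvolve(m)
        np.testing.assert_allclose(out, out.T, atol=1e-12)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            deconvolve(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestPipeline:
    def test_retained_edge_pvalues_within_bounds(self, planted_dataset):
        _, table, _ = planted_dataset
        net = infer_environment_network(table, InferenceConfig(n_iter=100, seed=0))
        assert net.n_edges > 0
        for _, _, d in net.graph.edges(data=True):
            for f in ("p_spearman", "p_bc", "p_merged", "p_adjusted"):
                assert 0.0 <= d[f] <= 1.0
            assert d["p_adjusted"] >= d["p_merged"] - 1e-12
            assert d["p_adjusted"] <= 0.05
            assert d["sign"] == np.sign(d["rho"]) and d["rho"] != 0

    def test_planted_edges_recovered_with_signs(self, planted_dataset):
        _, table, truth = planted_dataset
        net = infer_environment_network(table, InferenceConfig(n_iter=100, seed=0))
        got = {(a, b): d["sign"] for a, b, d in net.graph.edges(data=True)}
        expected = {(a, b): s for a, b, s in truth["soil"]}
        recovered = [k for k in expected if k in got]
        assert len(recovered) >= 0.8 * len(expected)
        for k in recovered:
            assert got[k] == expected[k]

    def test_no_isolated_vertices(self, planted_dataset):
        _, table, _ = planted_dataset
        net = infer_environment_network(table, InferenceConfig(n_iter=100, seed=0))
        assert all(d > 0 for _, d in net.graph.degree)

    def test_determinism_same_seed(self, planted_dataset):
        _, table, _ = planted_dataset
        cfg = InferenceConfig(n_iter=50, seed=13)
        n1 = infer_environment_network(table, cfg)
        n2 = infer_environment_network(table, cfg)
        assert n1.edge_keys() == n2.edge_keys()
        for k in n1.edge_keys():
            assert n1.graph.edges[k]["p_merged"] == n2.graph.edges[k]["p_merged"]

    def test_exhaustive_mode_keeps_same_retained_set(self):
        envs = frozenset(["soil"])
        planted = [PlantedEdge("ESV01", "ESV02", 0.9, envs),
                   PlantedEdge("ESV03", "ESV04", -0.9, envs)]
        design = PlantedDesign(n_environments=1, samples_per_environment=120,
                               n_esvs=16, planted_edges=planted, seed=21)
        table, _ = generate_dataset(design)
        fast = infer_environment_network(table, InferenceConfig(n_iter=100, seed=2))
        full = infer_environment_network(
            table, InferenceConfig(n_iter=100, seed=2, exhaustive=True))
        assert fast.edge_keys() == full.edge_keys()

    def test_deconvolution_alpha_below_one_prunes_edges(self, planted_dataset):
        _, table, _ = planted_dataset
        cfg_full = InferenceConfig(n_iter=50, seed=1)
        cfg_half = InferenceConfig(
            n_iter=50, seed=1, deconvolution=DeconvolutionParams(alpha=0.5))
        full = infer_environment_network(table, cfg_full)
        half = infer_environment_network(table, cfg_half)
        assert half.n_edges <= full.n_edges
        assert half.n_edges >= 1
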