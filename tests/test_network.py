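import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tuberscope import network, synthetic
from tuberscope.io import ExpressionMatrix, GeneSet

from conftest import as_matrix


class TestSelectTopVariable:
    def test_constant_gene_ranks_last(self):
        m = as_matrix(
            np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 9.0], [0.0, 4.0, 8.0]]), "log2"
        )
        out = network.select_top_variable(m, k=2)
        assert "g000" not in out.gene_ids

    def test_k_equals_n_is_reordering_only(self):
        rng = np.random.default_rng(2)
        m = as_matrix(rng.normal(size=(10, 5)), "log2")
        out = network.select_top_variable(m, k=10)
        assert sorted(out.gene_ids) == sorted(m.gene_ids)

    def test_mad_hand_value_and_tie_break(self):
        # MAD of [1,2,3,4,100] is 1 (median of |x - 3|)
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert np.median(np.abs(x - np.median(x))) == 1.0
        m = as_matrix(np.vstack([x, x, x * 0 + 1]), "log2")
        out = network.select_top_variable(m, k=2)
        assert out.gene_ids == ["g000", "g001"]  # tied MADs broken by gene ID


class TestSpearman:
    def test_monotone_pairs(self):
        m = as_matrix(
            np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 5.0, 7.0, 11.0],
                      [9.0, 6.0, 4.0, 1.0]]), "log2"
        )
        rho = network.spearman_matrix(m)
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert rho.iloc[0, 2] == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        m = as_matrix(np.array([[1.0, 2.0, 3.0], [3.0, 5.0, 4.0]]), "log2")
        rho = network.spearman_matrix(m)
        assert rho.iloc[0, 1] == pytest.approx(0.5)

    def test_matches_scipy_on_random_matrix(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(15, 12))
        rho = network.spearman_matrix(as_matrix(x, "log2")).to_numpy()
        oracle = stats.spearmanr(x.T).statistic
        assert np.allclose(rho, oracle, atol=1e-12)

    def test_constant_gene_zeroed_with_warning(self):
        x = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            rho = network.spearman_matrix(as_matrix(x, "log2"))
        assert rho.iloc[0, 1] == 0.0
        assert rho.iloc[0, 0] == 1.0


class TestSoftPower:
    def test_planted_modules_reach_scale_free_fit(self, module_sim):
        expr, _, _ = module_sim
        rho = network.spearman_matrix(expr)
        scan = network.pick_soft_power(rho)
        assert 3 <= scan.chosen <= 12
        assert scan.table.loc[scan.chosen, "r_squared"] >= 0.8

    def test_degenerate_all_equal_correlations_skipped(self):
        n = 30
        rho = pd.DataFrame(
            np.full((n, n), 0.5) + np.eye(n) * 0.5,
            index=[f"g{i}" for i in range(n)],
            columns=[f"g{i}" for i in range(n)],
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="undefined"):
                network.pick_soft_power(rho, powers=range(1, 4))

    def test_fit_invariant_to_gene_permutation(self, module_sim):
        expr, _, _ = module_sim
        rho = network.spearman_matrix(expr)
        perm = np.random.default_rng(0).permutation(len(rho))
        rho_p = rho.iloc[perm, perm]
        a = network.pick_soft_power(rho)
        b = network.pick_soft_power(rho_p)
        assert a.chosen == b.chosen
        assert np.allclose(a.table["r_squared"], b.table["r_squared"], equal_nan=True)

    def test_chosen_power_reproducible(self, module_sim):
        expr, _, _ = module_sim
        rho = network.spearman_matrix(expr)
        assert network.pick_soft_power(rho).chosen == network.pick_soft_power(rho).chosen


class TestAdjacency:
    def test_arithmetic_and_monotonicity(self):
        rho = pd.DataFrame(
            [[1.0, 0.5, 0.9], [0.5, 1.0, -0.7], [0.9, -0.7, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        a6 = network.adjacency(rho, 6)
        assert a6.loc["a", "b"] == pytest.approx(0.015625)
        a1 = network.adjacency(rho, 1)
        assert np.allclose(a1.to_numpy(), np.abs(rho.to_numpy()))
        # larger |rho| gives larger adjacency at fixed power
        assert a6.loc["a", "c"] > a6.loc["a", "b"]

    def test_beta_below_one_rejected(self):
        rho = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            network.adjacency(rho, 0)


def tom_triple_loop(a):
    """Independent O(n^3) oracle for the topological overlap matrix."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestTopologicalOverlap:
    def test_complete_graph_is_all_ones(self):
        n = 5
        adj = pd.DataFrame(
            np.ones((n, n)), index=[f"g{i}" for i in range(n)],
            columns=[f"g{i}" for i in range(n)],
        )
        tom = network.topological_overlap(adj)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_isolated_pair_overlap_equals_adjacency(self):
        x = 0.6
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = x
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=list("abcd"), columns=list("abcd"))
        tom = network.topological_overlap(adj)
        # k_i = k_j = x, l_ij = 0: omega = x / (x + 1 - x) = x
        assert tom.loc["a", "b"] == pytest.approx(x)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        for n in (6, 12, 20):
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            adj = pd.DataFrame(
                a, index=[f"g{i}" for i in range(n)],
                columns=[f"g{i}" for i in range(n)],
            )
            tom = network.topological_overlap(adj).to_numpy()
            assert np.abs(tom - tom_triple_loop(a)).max() < 1e-12

    def test_range_and_symmetry(self, module_sim):
        expr, _, _ = module_sim
        rho = network.spearman_matrix(expr)
        tom = network.topological_overlap(network.adjacency(rho, 6)).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
        assert np.allclose(tom, tom.T)


class TestModuleDetection:
    def two_block_tom(self):
        a = np.zeros((10, 10))
        a[:5, :5] = 1.0
        a[5:, 5:] = 1.0
        adj = pd.DataFrame(
            a, index=[f"g{i}" for i in range(10)],
            columns=[f"g{i}" for i in range(10)],
        )
        return network.topological_overlap(adj)

    def test_two_perfect_blocks(self):
        labels = network.detect_modules(self.two_block_tom(), min_size=3)
        assert set(labels) == {1, 2}
        assert len(set(labels.iloc[:5])) == 1
        assert len(set(labels.iloc[5:])) == 1

    def test_planted_three_modules_recovered(self, module_sim):
        from sklearn.metrics import adjusted_rand_score

        expr, _, truth = module_sim
        mset, scan = network.build_network(expr, min_size=50)
        truth_labels = [truth.module_of[g] for g in mset.labels.index]
        assert adjusted_rand_score(truth_labels, mset.labels.to_numpy()) >= 0.8

    def test_pure_noise_yields_no_modules(self):
        rng = np.random.default_rng(11)
        m = as_matrix(rng.normal(size=(300, 22)), "log2")
        rho = network.spearman_matrix(m)
        scan = network.pick_soft_power(rho)
        tom = network.topological_overlap(network.adjacency(rho, scan.chosen))
        labels = network.detect_modules(tom, min_size=100)
        assert (labels == 0).all()

    def test_permutation_equivariance(self):
        tom = self.two_block_tom()
        perm = np.random.default_rng(1).permutation(len(tom))
        tom_p = tom.iloc[perm, perm]
        a = network.detect_modules(tom, min_size=3)
        b = network.detect_modules(tom_p, min_size=3)
        assert a.sort_index().equals(b.sort_index())

    def test_min_size_larger_than_n_warns_all_unassigned(self):
        tom = self.two_block_tom()
        with pytest.warns(UserWarning, match="unassigned"):
            labels = network.detect_modules(tom, min_size=100)
        assert (labels == 0).all()


class TestEigengene:
    def test_duplicated_rows_explain_all_variance(self):
        rng = np.random.default_rng(3)
        profile = rng.normal(size=8)
        m = as_matrix(np.tile(profile, (4, 1)), "log2")
        labels = pd.Series(1, index=m.gene_ids)
        mset = network.module_eigengene(m, labels)
        assert mset.variance_explained[1] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        e = mset.eigengenes.loc[1].to_numpy()
        assert abs(np.corrcoef(e, z)[0, 1]) == pytest.approx(1.0)

    def test_eigengene_tracks_latent_factor(self):
        params = synthetic.ModuleSimParams(
            n_genes=60, module_sizes=(60,), within_module_cor=0.9,
            n_samples=20, n_mirna=0, seed=2,
        )
        expr, _, truth = params, None, None
        expr, _, truth = synthetic.simulate_modules(params)
        labels = pd.Series([truth.module_of[g] for g in expr.gene_ids],
                           index=expr.gene_ids)
        mset = network.module_eigengene(expr, labels)
        # the factor is recoverable as the mean member profile
        factor_proxy = expr.values.mean(axis=0)
        r = np.corrcoef(mset.eigengenes.loc[1], factor_proxy)[0, 1]
        assert abs(r) >= 0.95

    def test_orientation_mean_kme_positive(self, module_sim):
        expr, _, truth = module_sim
        labels = pd.Series([truth.module_of[g] for g in expr.gene_ids],
                           index=expr.gene_ids)
        mset = network.module_eigengene(expr, labels)
        for m in mset.module_ids:
            members = mset.members(m)
            assert mset.kme.loc[members, m].mean() > 0

    def test_variance_maximizing_direction(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(30, 12))
        m = as_matrix(x, "log2")
        labels = pd.Series(1, index=m.gene_ids)
        mset = network.module_eigengene(m, labels)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        best = np.linalg.norm(z @ mset.eigengenes.loc[1].to_numpy()) ** 2
        for _ in range(1000):
            u = rng.normal(size=12)
            u /= np.linalg.norm(u)
            assert np.linalg.norm(z @ u) ** 2 <= best + 1e-9

    def test_constant_module_rejected(self):
        m = as_matrix(np.ones((3, 5)), "log2")
        labels = pd.Series(1, index=m.gene_ids)
        with pytest.raises(ValueError, match="constant"):
            network.module_eigengene(m, labels)


class TestModuleMembership:
    def test_identical_and_negated_profiles(self):
        rng = np.random.default_rng(6)
        e = rng.normal(size=10)
        x = np.vstack([e, -e, rng.normal(size=10)])
        m = as_matrix(x, "log2")
        eig = pd.DataFrame([e], index=[1], columns=m.sample_ids)
        kme = network.module_membership(m, eig)
        assert kme.loc["g000", 1] == pytest.approx(1.0)
        assert kme.loc["g001", 1] == pytest.approx(-1.0)

    def test_null_genes_have_moderate_kme(self):
        rng = np.random.default_rng(13)
        e = rng.normal(size=22)
        x = rng.normal(size=(20, 22))
        m = as_matrix(x, "log2")
        eig = pd.DataFrame([e], index=[1], columns=m.sample_ids)
        kme = network.module_membership(m, eig)
        assert np.abs(kme[1]).max() < 0.6

    def test_constant_gene_zero_with_warning(self):
        x = np.vstack([np.ones(6), np.arange(6.0)])
        m = as_matrix(x, "log2")
        eig = pd.DataFrame([np.arange(6.0)], index=[1], columns=m.sample_ids)
        with pytest.warns(UserWarning, match="constant"):
            kme = network.module_membership(m, eig)
        assert kme.loc["g000", 1] == 0.0


class TestModuleEnrichment:
    def test_module_equals_set_closed_form(self):
        from scipy.special import comb

        universe = {f"g{i}" for i in range(100)}
        labels = pd.Series(
            [1] * 10 + [0] * 90, index=[f"g{i}" for i in range(100)]
        )
        gs = GeneSet("s", "d", tuple(f"g{i}" for i in range(10)))
        out = network.module_enrichment(labels, [gs], universe)
        assert out["p"].iloc[0] == pytest.approx(1.0 / comb(100, 10), rel=1e-9)

    def test_disjoint_module_and_set_not_enriched(self):
        universe = {f"g{i}" for i in range(40)}
        labels = pd.Series(
            [1] * 10 + [0] * 30, index=[f"g{i}" for i in range(40)]
        )
        gs = GeneSet("s", "d", tuple(f"g{i}" for i in range(20, 30)))
        out = network.module_enrichment(labels, [gs], universe)
        assert out["p"].iloc[0] >= 0.5

    def test_bh_across_pairs_matches_oracle(self):
        from test_diffexpr import bh_brute_force

        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        universe = set(genes)
        labels = pd.Series(rng.integers(0, 4, 60), index=genes)
        sets = [
            GeneSet(f"s{k}", "d", tuple(rng.choice(genes, 12, replace=False)))
            for k in range(5)
        ]
        out = network.module_enrichment(labels, sets, universe)
        assert np.allclose(out["p_adj"], bh_brute_force(out["p"].to_numpy()))
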