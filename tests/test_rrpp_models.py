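"""Phylogenetic covariance, GLS, RRPP ANOVA, Holm, and robustness checks
against independent oracles."""

from itertools import combinations, permutations

import dendropy
import numpy as np
import pytest

from arborclim.rrpp_models import (
    ModelError,
    gls_transform,
    pairwise_comparisons,
    phylo_covariance,
    phylo_pair_distance,
    posterior_robustness,
    rrpp_anova,
    sequential_bonferroni,
)
from arborclim.synthetic_world import simulate_chronogram


def newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick")


def mrca_depth_oracle(tree: dendropy.Tree):
    """Brute-force root-to-MRCA path sums per tip pair."""
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
        depth[node] = d
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    pdm = {}
    for a, b in combinations(labels, 2):
        chain_a = ancestors(leaves[a])
        chain_b = set(ancestors(leaves[b]))
        mrca = next(n for n in chain_a if n in chain_b)
        pdm[(a, b)] = depth[mrca]
    return labels, depth, pdm, leaves


class TestPhyloCovariance:
    def test_star_tree(self):
        tree = newick("(a:3,b:3,c:3,d:3);")
        C, labels = phylo_covariance(tree)
        np.testing.assert_allclose(np.diag(C), 3.0)
        off = C[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_single_cherry_geometry(self):
        tree = newick("((a:1,b:1):2,c:3);")
        C, labels = phylo_covariance(tree)
        i, j = labels.index("a"), labels.index("b")
        assert C[i, j] == pytest.approx(2.0)  # depth T=3, terminal t=1
        assert C[i, labels.index("c")] == pytest.approx(0.0)

    def test_random_tree_matches_path_sum_oracle(self):
        tree = simulate_chronogram(12, 1.0, 21)
        C, labels = phylo_covariance(tree)
        _, depth, pdm, leaves = mrca_depth_oracle(tree)
        for a, b in combinations(labels, 2):
            i, j = labels.index(a), labels.index(b)
            assert C[i, j] == pytest.approx(pdm[(a, b)], rel=1e-10)
        for a in labels:
            i = labels.index(a)
            assert C[i, i] == pytest.approx(depth[leaves[a]], rel=1e-10)

    def test_non_ultrametric_warns(self):
        tree = newick("((a:1,b:2):1,c:3);")
        with pytest.warns(UserWarning, match="not ultrametric"):
            phylo_covariance(tree)


class TestPairDistance:
    def test_self_distance_zero(self):
        C, _ = phylo_covariance(simulate_chronogram(6, 1.0, 1))
        d = phylo_pair_distance(C)
        np.testing.assert_array_equal(np.diag(d), 0.0)
        np.testing.assert_allclose(d, d.T)

    def test_star_tree_distances(self):
        C, _ = phylo_covariance(newick("(a:2,b:2,c:2);"))
        d = phylo_pair_distance(C)
        off = d[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 4.0)

    def test_equals_patristic_path_length(self):
        tree = simulate_chronogram(10, 1.0, 5)
        C, labels = phylo_covariance(tree)
        d = phylo_pair_distance(C)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a, b in combinations(labels, 2):
            i, j = labels.index(a), labels.index(b)
            assert d[i, j] == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), rel=1e-9
            )


class TestGLSTransform:
    def test_identity_covariance_is_ols(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((6, 2))
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        Yt, Xt, P = gls_transform(Y, X, np.eye(6))
        np.testing.assert_allclose(Yt, Y, atol=1e-12)
        np.testing.assert_allclose(Xt, X, atol=1e-12)

    def test_whitening_property(self):
        C, _ = phylo_covariance(simulate_chronogram(8, 1.0, 2))
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((8, 2))
        X = np.ones((8, 1))
        _, _, P = gls_transform(Y, X, C)
        np.testing.assert_allclose(P @ C @ P.T, np.eye(8), atol=1e-10)

    def test_matches_normal_equations_gls(self):
        tree = simulate_chronogram(6, 1.0, 4)
        C, _ = phylo_covariance(tree)
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((6, 3))
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        Yt, Xt, _ = gls_transform(Y, X, C)
        beta_transformed = np.linalg.lstsq(Xt, Yt, rcond=None)[0]
        Ci = np.linalg.inv(C)
        beta_direct = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ Y)
        np.testing.assert_allclose(beta_transformed, beta_direct, atol=1e-9)

    def test_singular_covariance_rejected(self):
        C = np.ones((4, 4))  # rank 1: effectively duplicated tips
        with pytest.raises(ModelError, match="near-duplicate"):
            gls_transform(np.zeros((4, 1)), np.ones((4, 1)), C)


def classic_anova_f(y, idx_a, idx_b):
    m = y.mean()
    ssb = len(idx_a) * (y[idx_a].mean() - m) ** 2
    ssb += len(idx_b) * (y[idx_b].mean() - m) ** 2
    sst = ((y - m) ** 2).sum()
    ssw = sst - ssb
    return (ssb / 1) / (ssw / (len(y) - 2))


class TestRRPPAnova:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(6)
        groups = np.array(["A", "A", "A", "T", "T", "T"])
        res = rrpp_anova(y[:, None], groups, C=None, exhaustive=True)
        assert len(res.perm_stats) == 720
        f_obs = classic_anova_f(y, [0, 1, 2], [3, 4, 5])
        fs = np.array(
            [classic_anova_f(y[list(p)], [0, 1, 2], [3, 4, 5])
             for p in permutations(range(6))]
        )
        p_oracle = np.mean(fs >= f_obs - 1e-12)
        assert res.F_obs == pytest.approx(f_obs, rel=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_ols_limit_equals_classical_trace_f(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((10, 4))
        groups = np.array(["A"] * 5 + ["T"] * 5)
        res = rrpp_anova(Y, groups, C=None, n_perm=99, seed=0)
        # classical trace F from group-mean decomposition
        grand = Y.mean(axis=0)
        ss_m = sum(
            5 * np.sum((Y[groups == g].mean(axis=0) - grand) ** 2)
            for g in ("A", "T")
        )
        ss_e = sum(
            np.sum((Y[groups == g] - Y[groups == g].mean(axis=0)) ** 2)
            for g in ("A", "T")
        )
        f = (ss_m / 1) / (ss_e / 8)
        assert res.F_obs == pytest.approx(f, rel=1e-10)

    def test_identical_responses_rejected(self):
        Y = np.ones((8, 2))
        groups = np.array(["A"] * 4 + ["T"] * 4)
        with pytest.raises(ModelError, match="degenerate"):
            rrpp_anova(Y, groups, n_perm=99)

    def test_small_group_rejected(self):
        Y = np.random.default_rng(0).standard_normal((5, 2))
        groups = np.array(["A", "T", "T", "T", "T"])
        with pytest.raises(ModelError, match=">= 2 members"):
            rrpp_anova(Y, groups, n_perm=99)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((12, 3))
        groups = np.array(["A"] * 6 + ["T"] * 6)
        r1 = rrpp_anova(Y, groups, n_perm=199, seed=7)
        r2 = rrpp_anova(Y, groups, n_perm=199, seed=7)
        assert r1.p == r2.p and r1.Z == r2.Z
        np.testing.assert_array_equal(r1.perm_stats, r2.perm_stats)

    def test_input_order_invariance(self):
        # sorting species before analysis makes p independent of row order
        tree = simulate_chronogram(10, 1.0, 30)
        C, labels = phylo_covariance(tree)
        rng = np.random.default_rng(13)
        Y = rng.standard_normal((10, 2))
        groups = np.array(["A"] * 5 + ["T"] * 5)
        perm = rng.permutation(10)
        inv = np.argsort(perm)
        r1 = rrpp_anova(Y, groups, C, n_perm=199, seed=3)
        r2 = rrpp_anova(
            Y[perm][inv], groups[perm][inv], C, n_perm=199, seed=3
        )
        assert r1.p == r2.p

    def test_gls_group_means_returned(self):
        tree = simulate_chronogram(8, 1.0, 31)
        C, _ = phylo_covariance(tree)
        rng = np.random.default_rng(14)
        Y = rng.standard_normal((8, 2))
        groups = np.array(["A"] * 4 + ["T"] * 4)
        res = rrpp_anova(Y, groups, C, n_perm=99, seed=0)
        M = np.column_stack([(groups == g).astype(float) for g in ("A", "T")])
        Ci = np.linalg.inv(C)
        means = np.linalg.solve(M.T @ Ci @ M, M.T @ Ci @ Y)
        np.testing.assert_allclose(res.coefficients, means, atol=1e-8)


class TestPairwiseComparisons:
    def test_two_groups_match_overall_test(self):
        # with two groups and identity covariance the pairwise distance is
        # a monotone function of the overall F, so p agrees on a shared
        # permutation schedule
        rng = np.random.default_rng(20)
        Y = rng.standard_normal((12, 3))
        groups = np.array(["A"] * 6 + ["T"] * 6)
        overall = rrpp_anova(Y, groups, None, n_perm=299, seed=5)
        pair = pairwise_comparisons(Y, groups, None, n_perm=299, seed=5)[0]
        assert pair.p == pytest.approx(overall.p, abs=1e-12)

    def test_displaced_group_detected(self):
        rng = np.random.default_rng(21)
        hits = 0
        for rep in range(100):
            Y = rng.standard_normal((18, 2))
            groups = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
            Y[groups == "c"] += 4.0  # large displacement
            comps = pairwise_comparisons(Y, groups, None, n_perm=199,
                                         seed=rep)
            by_pair = {
                tuple(sorted((c.group_a, c.group_b))): c for c in comps
            }
            ok = (
                by_pair[("a", "c")].p <= 0.05
                and by_pair[("b", "c")].p <= 0.05
                and by_pair[("a", "b")].p > 0.05
            )
            hits += ok
        assert hits >= 95

    def test_significance_flag_is_z_cutoff(self):
        rng = np.random.default_rng(22)
        Y = rng.standard_normal((16, 2))
        Y[8:] += 2.0
        groups = np.array(["A"] * 8 + ["T"] * 8)
        comp = pairwise_comparisons(Y, groups, None, n_perm=199, seed=1)[0]
        assert comp.significant == (comp.Z > 1.645)

    def test_delta_coefficients_are_mean_differences(self):
        rng = np.random.default_rng(23)
        Y = rng.standard_normal((10, 2))
        groups = np.array(["A"] * 5 + ["T"] * 5)
        comp = pairwise_comparisons(Y, groups, None, n_perm=99, seed=0)[0]
        expected = Y[:5].mean(axis=0) - Y[5:].mean(axis=0)
        np.testing.assert_allclose(comp.delta_coefficients, expected,
                                   atol=1e-10)


class TestSequentialBonferroni:
    def test_family_of_twelve_alpha_ladder(self):
        res = sequential_bonferroni([0.001] * 12, 0.05)
        assert round(min(res.adjusted_alpha), 4) == 0.0042
        assert max(res.adjusted_alpha) == pytest.approx(0.05)

    def test_family_of_five_alpha_ladder(self):
        res = sequential_bonferroni([0.001, 0.002, 0.656, 0.022, 0.088], 0.05)
        assert res.adjusted_alpha[res.rank == 1][0] == pytest.approx(0.01)

    def test_single_test_uses_family_alpha(self):
        res = sequential_bonferroni([0.04], 0.05)
        assert res.adjusted_alpha[0] == pytest.approx(0.05)
        assert res.significant[0]

    def test_holm_stopping_blocks_later_ranks(self):
        # rank 1 significant, rank 2 fails, rank 3 would pass alone but is
        # blocked by the step-down rule
        res = sequential_bonferroni([0.001, 0.04, 0.049], 0.05)
        assert res.significant.tolist() == [True, False, False]

    def test_alphas_nondecreasing_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 9)
        res = sequential_bonferroni(p, 0.05)
        order = np.argsort(res.rank)
        assert (np.diff(res.adjusted_alpha[order]) >= -1e-15).all()

    def test_empty_input(self):
        res = sequential_bonferroni([])
        assert res.p_values.size == 0


class TestPosteriorRobustness:
    def _setup(self):
        tree = simulate_chronogram(12, 1.0, 40)
        C, species = phylo_covariance(tree)
        rng = np.random.default_rng(41)
        Y = rng.standard_normal((12, 2))
        Y[6:] += 3.0
        groups = np.array(["A"] * 6 + ["T"] * 6)
        return tree, species, Y, groups

    def test_identical_trees_zero_width_interval(self):
        tree, species, Y, groups = self._setup()
        rob = posterior_robustness(
            Y, groups, species, [tree] * 5, n_perm=99, seed=0
        )
        # same tree, but per-tree seeds differ: interval reflects only
        # permutation noise, so collapse it by checking all trees used
        assert rob.n_trees_used == 5
        rob_same_seed = posterior_robustness(
            Y, groups, species, [tree], n_perm=99, seed=0
        )
        assert rob_same_seed.interval[0] == pytest.approx(
            rob_same_seed.interval[1]
        )

    def test_interval_brackets_median(self):
        from arborclim.synthetic_world import sample_posterior_trees

        tree, species, Y, groups = self._setup()
        trees = sample_posterior_trees(tree, 10, 0.2, seed=1)
        rob = posterior_robustness(Y, groups, species, trees, n_perm=99,
                                   seed=2)
        med = np.median(rob.z_values)
        assert rob.interval[0] <= med <= rob.interval[1]

    def test_tree_missing_species_skipped(self):
        tree, species, Y, groups = self._setup()
        small = simulate_chronogram(5, 1.0, 50)  # lacks the species
        rob = posterior_robustness(
            Y, groups, species, [tree, small], n_perm=99, seed=0
        )
        assert rob.n_trees_used == 1
        assert rob.n_trees_skipped == 1
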