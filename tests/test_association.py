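"""Chi-squared association tests, Pearson-residual profiles and NMDS."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from floradisp import (FactorTable, SynthSpec, association_edges,
                       build_contingency, chi_squared, gen_factor_table,
                       nmds_embed, positive_clusters, pr_profile_distance)
from floradisp.association import (AssociationResult, ContingencyTable,
                                   all_pairwise_associations)


def _ft(rows, factors):
    """rows: list of (taxon, {factor: set})"""
    taxa = [r[0] for r in rows]
    cells = [[frozenset(r[1].get(f, ())) for f in factors] for r in rows]
    return FactorTable(taxa, factors, cells)


class TestBuildContingency:
    @pytest.fixture
    def ft(self):
        return _ft(
            [("t1", {"climate": {"temperate"}, "region": {"Eurasia", "Africa"}}),
             ("t2", {"climate": {"tropical"}, "region": {"Africa"}}),
             ("t3", {"climate": {"temperate"}, "region": {"Eurasia"}}),
             ("t4", {"climate": {"polar"}, "region": {"Eurasia"}}),
             ("t5", {"climate": {"tropical"}, "region": {"Africa"}})],
            {"climate": ("tropical", "temperate", "polar"),
             "region": ("Eurasia", "Africa")})

    def test_cartesian_multi_membership_counting(self, ft):
        ct = build_contingency(ft, "climate", "region")
        df = ct.to_frame()
        # t1 adds one count to (temperate, Eurasia) AND (temperate, Africa)
        assert df.loc["temperate", "Eurasia"] == 2
        assert df.loc["temperate", "Africa"] == 1
        assert df.loc["tropical", "Africa"] == 2

    def test_merge_semantics(self, ft):
        ct = build_contingency(ft, "climate", "region",
                               merges={"climate": {"polar": "temperate"}})
        df = ct.to_frame()
        assert "polar" not in df.index
        assert df.loc["temperate", "Eurasia"] == 3

    def test_zero_marginal_raises_with_hint(self, ft):
        with pytest.raises(ValueError, match="merg"):
            build_contingency(ft, "climate", "region",
                              exclusions={"region": {"Africa"}})
        # excluding Africa leaves 'tropical' with no taxa -> zero row

    def test_same_factor_rejected(self, ft):
        with pytest.raises(ValueError):
            build_contingency(ft, "climate", "climate")

    def test_df_after_merge_and_exclusion(self):
        # 5 climates merged to 4, 5 growth forms reduced to 4 -> df = 9
        ft = gen_factor_table(SynthSpec(seed=8, n_taxa=300))
        ct = build_contingency(ft, "growth_form", "climate",
                               merges={"climate": {"polar": "cold"}},
                               exclusions={"growth_form": {"root parasites"}})
        res = chi_squared(ct)
        assert res.df == 9


class TestChiSquared:
    def test_perfect_diagonal_2x2(self):
        ct = ContingencyTable("f1", "f2", ["a", "b"], ["x", "y"],
                              np.array([[10, 0], [0, 10]]))
        res = chi_squared(ct)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_independence_gives_zero(self):
        # outer product of marginals: O == E everywhere
        counts = np.outer([10, 20, 30], [4, 6])
        ct = ContingencyTable("f1", "f2", list("abc"), list("xy"), counts)
        res = chi_squared(ct)
        assert res.chi2 == pytest.approx(0.0)
        assert np.allclose(res.pr, 0.0)

    def test_pearson_residual_value(self):
        # O = 10 with E = 5 -> PR = 5/sqrt(5) = 2.2361
        counts = np.array([[10, 0], [0, 10]])
        ct = ContingencyTable("f1", "f2", list("ab"), list("xy"), counts)
        res = chi_squared(ct)
        assert res.pr[0, 0] == pytest.approx((10 - 5) / np.sqrt(5))
        assert res.pr[0, 0] == pytest.approx(2.2361, abs=1e-4)

    def test_residuals_balance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 30, (3, 4))
        ct = ContingencyTable("f1", "f2", list("abc"), list("wxyz"), counts)
        res = chi_squared(ct)
        O, E = counts, counts.sum(1)[:, None] * counts.sum(0) / counts.sum()
        assert (O - E).sum() == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(
            __import__("scipy.stats", fromlist=["chi2"]).chi2.sf(res.chi2, res.df))

    def test_matches_hand_computation_3x3(self):
        counts = np.array([[8, 2, 1], [3, 9, 2], [1, 2, 7]])
        ct = ContingencyTable("f1", "f2", list("abc"), list("xyz"), counts)
        res = chi_squared(ct)
        O = counts.astype(float)
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        assert res.chi2 == pytest.approx(((O - E) ** 2 / E).sum())
        assert res.df == 4


def _result(fa, fb, rows, cols, counts):
    return chi_squared(ContingencyTable(fa, fb, rows, cols, np.asarray(counts)))


class TestAssociationEdges:
    def test_nonsignificant_pair_contributes_nothing(self):
        res = _result("f1", "f2", ["a", "b"], ["x", "y"], [[5, 5], [5, 5]])
        assert res.p > 0.05
        assert association_edges({("f1", "f2"): res}) == []

    def test_edge_sign_weight_and_threshold(self):
        res = _result("f1", "f2", ["a", "b"], ["x", "y"], [[20, 1], [1, 20]])
        edges = association_edges({("f1", "f2"): res}, pr_threshold=2.0)
        assert len(edges) == 4
        signs = {(u[1], v[1]): s for u, v, s, _ in edges}
        assert signs[("a", "x")] == 1 and signs[("a", "y")] == -1
        big = association_edges({("f1", "f2"): res},
                                pr_threshold=1 + max(abs(res.pr.ravel())))
        assert big == []

    def test_invariant_under_factor_swap(self):
        res = _result("f1", "f2", ["a", "b"], ["x", "y"], [[20, 1], [1, 20]])
        swapped = _result("f2", "f1", ["x", "y"], ["a", "b"],
                          np.array([[20, 1], [1, 20]]).T)
        e1 = association_edges({("f1", "f2"): res})
        e2 = association_edges({("f2", "f1"): swapped})
        assert e1 == e2


class TestPrProfileDistance:
    def test_symmetric_zero_diagonal(self):
        res = _result("f1", "f2", ["a", "b"], ["x", "y"], [[20, 1], [1, 20]])
        _, dist = pr_profile_distance({("f1", "f2"): res})
        assert np.allclose(dist, dist.T)
        assert np.all(np.diag(dist) == 0)

    def test_bray_curtis_hand_example(self):
        # shifted profiles (0, 2) vs (2, 0) -> BC = (2+2)/(0+2+2+0) = 1
        from scipy.spatial.distance import braycurtis
        assert braycurtis([0.0, 2.0], [2.0, 0.0]) == pytest.approx(1.0)
        res = _result("f1", "f2", ["a", "b"], ["x", "y"], [[20, 1], [1, 20]])
        nodes, dist = pr_profile_distance({("f1", "f2"): res})
        i = nodes.index(("f1", "a"))
        j = nodes.index(("f1", "b"))
        # a and b have mirrored profiles -> large dissimilarity
        assert dist[i, j] >= 0.5


class TestNmdsEmbed:
    def test_equilateral_triangle_near_zero_stress(self):
        dist = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        emb = nmds_embed(dist, n_starts=8, seed=0)
        assert emb.stress < 0.01
        rms = np.sqrt((emb.coordinates ** 2).sum(axis=1).mean())
        assert rms == pytest.approx(1.0)

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        dist = squareform(pdist(pts))
        emb = nmds_embed(dist, n_starts=16, seed=1)
        assert emb.stress < 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        dist = squareform(rng.uniform(0.2, 1.0, 15))
        e1 = nmds_embed(dist, n_starts=4, seed=7)
        e2 = nmds_embed(dist, n_starts=4, seed=7)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)


class TestPlantedStructureRecovery:
    def test_two_means_split_separates_planted_blocks(self):
        """NMDS coordinates of block categories separate the planted
        clusters under a 2-means split in >=90% of replicates."""
        spec0 = SynthSpec(seed=0)
        blocks = spec0.blocks
        block_nodes = {}
        for b, blk in enumerate(blocks):
            for f, cats in blk.items():
                for c in cats:
                    block_nodes[(f, c)] = b
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            spec = SynthSpec(seed=5000 + rep, n_taxa=300,
                             association_strength=0.8,
                             factor_missing_frac=0.0, factor_polym_frac=0.0)
            ft = gen_factor_table(spec)
            results = all_pairwise_associations(ft)
            nodes, dist = pr_profile_distance(results)
            emb = nmds_embed(dist, nodes, n_starts=4, seed=rep)
            idx = [i for i, u in enumerate(nodes) if u in block_nodes]
            truth = np.array([block_nodes[nodes[i]] for i in idx])
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
                emb.coordinates[idx])
            lab = km.labels_
            agree = max((lab == truth).mean(), (lab != truth).mean())
            wins += agree == 1.0
        assert wins / n_rep >= 0.9

    def test_positive_clusters_from_edges(self):
        edges = [(("f1", "a"), ("f2", "x"), 1, 3.0),
                 (("f2", "x"), ("f3", "m"), 1, 2.5),
                 (("f1", "b"), ("f2", "y"), 1, 2.2),
                 (("f1", "a"), ("f2", "y"), -1, 2.8)]
        comps = positive_clusters(edges)
        assert {("f1", "a"), ("f2", "x"), ("f3", "m")} in comps
        assert {("f1", "b"), ("f2", "y")} in comps
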