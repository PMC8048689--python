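"""Permutation ANOVA and central-tendency tests against first-principles
oracles, exhaustive enumeration, and their invariances."""

import numpy as np
import pytest
from scipy.stats import f_oneway
from scipy.spatial.distance import pdist, squareform

from floradisp import (DistanceMatrix, FactorTable, SynthSpec,
                       aggregate_over_resolutions, distance_matrix, f_ratio,
                       permutation_anova, posthoc_pairwise,
                       resolve_factor_polymorphism, simulate_dataset)

from conftest import (oracle_exhaustive_anova_p, oracle_exhaustive_t_p,
                      oracle_f_ratio)


def _dm_from_points(x):
    """Euclidean distance matrix from univariate points."""
    x = np.asarray(x, float)[:, None]
    d = squareform(pdist(x))
    return d


class TestResolveFactorPolymorphism:
    @pytest.fixture
    def ft(self):
        return FactorTable(
            ["t1", "t2", "t3"], {"climate": ("temperate", "cold")},
            [[frozenset({"temperate", "cold"})], [frozenset({"cold"})],
             [frozenset()]])

    def test_uniform_choice_over_seeds(self, ft):
        picks = [resolve_factor_polymorphism(ft, "climate", s)["t1"]
                 for s in range(400)]
        frac = np.mean([p == "temperate" for p in picks])
        assert 0.4 < frac < 0.6

    def test_single_valued_unchanged_and_missing_absent(self, ft):
        a = resolve_factor_polymorphism(ft, "climate", 0)
        assert a["t2"] == "cold"
        assert "t3" not in a


class TestFRatio:
    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(0)
        d = squareform(rng.uniform(0.05, 1.0, 15))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert f_ratio(d, labels) == pytest.approx(oracle_f_ratio(d, labels))

    def test_reduces_to_classical_anova_for_euclidean_univariate(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 7), rng.normal(0.5, 1, 9), rng.normal(1, 1, 6)]
        x = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], [7, 9, 6])
        f_classic = f_oneway(*groups).statistic
        assert f_ratio(_dm_from_points(x), labels) == pytest.approx(f_classic)

    def test_group_of_one_rejected(self):
        d = _dm_from_points([0, 1, 2, 3])
        with pytest.raises(ValueError, match="fewer than 2"):
            f_ratio(d, np.array([0, 0, 0, 1]))

    def test_perfect_separation_infinite(self):
        # two internally identical groups, separated
        d = np.zeros((4, 4))
        d[:2, 2:] = 0.8
        d[2:, :2] = 0.8
        assert f_ratio(d, np.array([0, 0, 1, 1])) == np.inf


class TestPermutationAnova:
    def _toy(self, seed=0, n=20, shift=0.0):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, n // 2),
                            rng.normal(shift, 1, n - n // 2)])
        taxa = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(taxa, _dm_from_points(x), np.full((n, n), 1))
        groups = {t: ("A" if i < n // 2 else "B") for i, t in enumerate(taxa)}
        return dm, groups

    def test_perfectly_separated_p_minimal(self):
        # F_obs is infinite; only permutations regenerating the exact
        # partition tie with it, which is vanishingly rare at this size
        n = 24
        d = np.zeros((n, n))
        d[: n // 2, n // 2:] = 0.9
        d[n // 2:, : n // 2] = 0.9
        taxa = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(taxa, d, np.full((n, n), 1))
        groups = {t: ("A" if i < n // 2 else "B") for i, t in enumerate(taxa)}
        res = permutation_anova(dm, groups, n_perm=999, seed=0)
        assert res.f_obs == np.inf
        assert res.p == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        d = squareform(rng.uniform(0.05, 1.0, 28))  # 8 taxa
        taxa = [f"t{i}" for i in range(8)]
        dm = DistanceMatrix(taxa, d, np.full((8, 8), 1))
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        groups = {t: str(l) for t, l in zip(taxa, labels)}
        exact = oracle_exhaustive_anova_p(d, labels)
        res = permutation_anova(dm, groups, n_perm=9999, seed=1)
        assert abs(res.p - exact) <= 0.02

    def test_relabeling_invariance(self):
        dm, groups = self._toy(seed=5, shift=0.8)
        renamed = {t: {"A": "Z", "B": "Q"}[g] for t, g in groups.items()}
        r1 = permutation_anova(dm, groups, n_perm=499, seed=9)
        r2 = permutation_anova(dm, renamed, n_perm=499, seed=9)
        assert r1.p == r2.p and r1.f_obs == pytest.approx(r2.f_obs)

    def test_constant_distances_never_significant(self):
        # equal pairwise distances: F is permutation-invariant, so p = 1
        n = 8
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        taxa = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(taxa, d, np.full((n, n), 1))
        groups = {t: ("A" if i < 4 else "B") for i, t in enumerate(taxa)}
        res = permutation_anova(dm, groups, n_perm=999, seed=0)
        assert res.p == 1.0

    def test_p_convention_add_one(self):
        dm, groups = self._toy(seed=2, shift=3.0)
        res = permutation_anova(dm, groups, n_perm=199, seed=0,
                                p_convention="add-one")
        assert res.p >= 1 / 200

    def test_group_sizes_reported(self):
        dm, groups = self._toy(n=10)
        res = permutation_anova(dm, groups, n_perm=99, seed=0)
        assert res.group_sizes == {"A": 5, "B": 5}

    def test_invalid_n_perm(self):
        dm, groups = self._toy()
        with pytest.raises(ValueError):
            permutation_anova(dm, groups, n_perm=0)


class TestPosthocPairwise:
    def _three_group_dm(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, 6), rng.normal(shift, 1, 6),
                            rng.normal(2 * shift, 1, 6)])
        taxa = [f"t{i}" for i in range(18)]
        dm = DistanceMatrix(taxa, _dm_from_points(x), np.full((18, 18), 1))
        groups = {t: "ABC"[i // 6] for i, t in enumerate(taxa)}
        return dm, groups

    def test_bonferroni_arithmetic_three_groups(self):
        dm, groups = self._three_group_dm(seed=1, shift=0.5)
        results = posthoc_pairwise(dm, groups, n_perm=199, seed=0)
        assert len(results) == 3
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, 3 * r.p_raw))
            assert r.p_adj >= r.p_raw
            assert abs(r.t_obs) <= 1 + 1e-12

    def test_identical_groups_t_zero(self):
        # two groups with identical internal distance structure
        block = _dm_from_points([0.0, 0.3, 0.9])
        d = np.zeros((6, 6))
        d[:3, :3] = block
        d[3:, 3:] = block
        d[:3, 3:] = 0.5
        d[3:, :3] = 0.5
        taxa = list("abcdef")
        dm = DistanceMatrix(taxa, d, np.full((6, 6), 1))
        groups = {t: ("A" if i < 3 else "B") for i, t in enumerate(taxa)}
        r = posthoc_pairwise(dm, groups, n_perm=99, seed=0)[0]
        assert r.t_obs == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        d = squareform(rng.uniform(0.05, 1.0, 15))  # 6 taxa, 3 vs 3
        taxa = [f"t{i}" for i in range(6)]
        dm = DistanceMatrix(taxa, d, np.full((6, 6), 1))
        groups = {t: ("A" if i < 3 else "B") for i, t in enumerate(taxa)}
        t_exact, p_exact = oracle_exhaustive_t_p(d, 3)
        r = posthoc_pairwise(dm, groups, n_perm=9999, seed=3)[0]
        assert r.t_obs == pytest.approx(t_exact)
        assert abs(r.p_raw - p_exact) <= 0.02


class TestPower:
    def test_power_monotone_in_between_group_effect(self):
        """Rejection rate of the permutation ANOVA grows with the planted
        between-group modal-shift effect (and sits near alpha at zero)."""
        from floradisp import gen_morph_matrix
        from floradisp.simulate import _factor_assignments

        rates = []
        for shift in (0.0, 0.3, 0.8):
            rej = 0
            n_rep = 30
            for rep in range(n_rep):
                spec = SynthSpec(seed=4000 + rep, n_taxa=60, n_binary=8,
                                 n_unordered=4, n_ordered=2, n_continuous=0,
                                 missing_frac=0.0, morph_polym_frac=0.0,
                                 factor_missing_frac=0.0,
                                 factor_polym_frac=0.0, modal_shift=shift,
                                 dispersion={}, default_dispersion=0.25)
                m = gen_morph_matrix(spec)
                _, primary, _ = _factor_assignments(spec)
                groups = dict(zip(spec.taxa, primary["climate"]))
                sizes = {}
                for c in groups.values():
                    sizes[c] = sizes.get(c, 0) + 1
                groups = {t: c for t, c in groups.items() if sizes[c] >= 3}
                dm = distance_matrix(m)
                rej += permutation_anova(dm, groups, n_perm=199,
                                         seed=rep).p <= 0.05
            rates.append(rej / n_rep)
        assert rates[0] <= 0.2          # near-null at zero effect
        assert rates[2] >= rates[0] + 0.3
        assert rates[1] <= rates[2] + 1e-9


class TestAggregation:
    def test_no_polymorphism_zero_sd(self):
        ds = simulate_dataset(SynthSpec(seed=21, n_taxa=40,
                                        morph_polym_frac=0.0,
                                        factor_polym_frac=0.0))
        agg = aggregate_over_resolutions(ds.morph, ds.factors, "habitat",
                                         n_perm=99, n_resolutions=5,
                                         base_seed=1)
        assert agg.stat_sd == 0.0 and agg.p_sd == 0.0
        assert agg.n_resolutions == 5

    def test_polymorphism_produces_spread_and_determinism(self, small_dataset):
        a1 = aggregate_over_resolutions(small_dataset.morph,
                                        small_dataset.factors, "climate",
                                        n_perm=99, n_resolutions=4, base_seed=2)
        a2 = aggregate_over_resolutions(small_dataset.morph,
                                        small_dataset.factors, "climate",
                                        n_perm=99, n_resolutions=4, base_seed=2)
        assert a1.stats == a2.stats and a1.ps == a2.ps
        assert a1.stat_sd > 0

    def test_posthoc_aggregation_keys(self, small_dataset):
        agg = aggregate_over_resolutions(small_dataset.morph,
                                         small_dataset.factors, "habitat",
                                         test="posthoc", n_perm=49,
                                         n_resolutions=3, base_seed=0)
        for (a, b), r in agg.items():
            assert a < b
            assert 1 <= r.n_resolutions <= 3

    def test_monte_carlo_stability_in_resolutions(self, small_dataset):
        a = aggregate_over_resolutions(small_dataset.morph,
                                       small_dataset.factors, "climate",
                                       n_perm=99, n_resolutions=8, base_seed=3)
        b = aggregate_over_resolutions(small_dataset.morph,
                                       small_dataset.factors, "climate",
                                       n_perm=99, n_resolutions=16, base_seed=4)
        se = a.stat_sd / np.sqrt(a.n_resolutions) + b.stat_sd / np.sqrt(b.n_resolutions)
        assert abs(a.stat_mean - b.stat_mean) <= max(4 * se, 0.2 * a.stat_mean)
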