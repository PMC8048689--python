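"""Model / results objects tying the analysis stages together.

Each model is built from the input tables and exposes a ``fit()`` returning
a results object that carries estimates, uncertainties and a ``summary()``
table, in the spirit of statsmodels:

* :class:`DisparityAnova` — disparity by category of one factor, the
  distance-based permutation ANOVA and central-tendency post-hoc tests,
  aggregated over random polymorphism resolutions;
* :class:`FactorAssociation` — chi-squared association tests among all
  factor pairs, Pearson residuals, the NMDS association network and its
  positive clusters;
* :class:`LatitudinalDisparity` — per-10-degree-bin richness and disparity
  profiles, gradient statistics and the richness-controlled null envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from .clusters import cluster_contrast, cluster_members
from .datamodel import FactorTable, MorphMatrix, OccurrenceTable
from .distance import (DisparityEstimate, distance_matrix, disparity_by_category)
from .latitude import (GradientStats, bin_presence, gradient_stats,
                       profile_disparity, richness_controlled_null)
from .permutation import (AggregatedResult, PairwiseTestResult,
                          aggregate_over_resolutions)
from .rng import spawn_rngs

logger = logging.getLogger("floradisp")

__all__ = ["DisparityAnova", "DisparityAnovaResults",
           "FactorAssociation", "FactorAssociationResults",
           "LatitudinalDisparity", "LatitudinalDisparityResults"]


def _intersect_taxa(morph: MorphMatrix, factors: FactorTable) -> list[str]:
    common = [t for t in morph.taxa if t in set(factors.taxa)]
    lost = (len(morph.taxa) - len(common), len(factors.taxa) - len(common))
    if any(lost):
        logger.warning("taxa restricted to intersection: %d morphology-only, "
                       "%d factor-only excluded", *lost)
    return common


@dataclass
class DisparityAnovaResults:
    factor: str
    disparity: dict[str, DisparityEstimate]
    anova: AggregatedResult
    posthoc: dict[tuple[str, str], AggregatedResult]
    n_perm: int
    n_resolutions: int

    def disparity_frame(self) -> pd.DataFrame:
        rows = [{"category": c, "disparity": e.mean, "sd": e.sd,
                 "n_taxa": e.n_taxa, "n_pairs": e.n_pairs, "defined": e.defined}
                for c, e in self.disparity.items()]
        return pd.DataFrame(rows)

    def posthoc_frame(self) -> pd.DataFrame:
        rows = [{"category_a": a, "category_b": b,
                 "T_mean": r.stat_mean, "T_sd": r.stat_sd,
                 "p_adj_mean": r.p_mean, "p_adj_sd": r.p_sd,
                 "n_resolutions": r.n_resolutions}
                for (a, b), r in self.posthoc.items()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Disparity by category of factor {self.factor!r}",
            self.disparity_frame().to_string(index=False, float_format="%.4f"),
            "",
            (f"Permutation ANOVA ({self.n_perm} permutations, "
             f"{self.n_resolutions} polymorphism resolutions):"),
            (f"  F = {self.anova.stat_mean:.2f} +- {self.anova.stat_sd:.2f}, "
             f"P = {self.anova.p_mean:.3g} +- {self.anova.p_sd:.3g}"),
        ]
        if self.posthoc:
            lines += ["", "Post-hoc central-tendency tests (Bonferroni-adjusted):",
                      self.posthoc_frame().to_string(index=False, float_format="%.4f")]
        return "\n".join(lines)


class DisparityAnova:
    """Disparity variation among the categories of one grouping factor.

    Parameters
    ----------
    morph : MorphMatrix
    factors : FactorTable
    factor : str
        The factor whose categories are compared.
    min_group_size : int
        Categories left with fewer taxa after each single-category
        resolution are dropped from the tests (descriptive disparity keeps
        them).
    """

    def __init__(self, morph: MorphMatrix, factors: FactorTable, factor: str,
                 min_group_size: int = 3):
        if factor not in factors.factors:
            raise KeyError(f"unknown factor {factor!r}")
        self.morph = morph
        self.factors = factors
        self.factor = factor
        self.min_group_size = min_group_size
        self.taxa = _intersect_taxa(morph, factors)

    @classmethod
    def from_files(cls, matrix_path, chardef_path, factor_path, factor,
                   **read_kwargs):
        from .datamodel import read_factor_table, read_morph_matrix
        return cls(read_morph_matrix(matrix_path, chardef_path, **read_kwargs),
                   read_factor_table(factor_path, **read_kwargs), factor)

    def fit(self, n_perm: int = 999, n_resolutions: int = 20, seed: int = 0,
            p_convention: str = "count", posthoc: bool = True
            ) -> DisparityAnovaResults:
        """Run the aggregated permutation ANOVA (and post-hoc tests).

        Descriptive per-category disparity uses the first polymorphism
        resolution and the multi-membership convention (a species counts in
        every category it belongs to); the tests resolve each species to one
        category per resolution.
        """
        rng0 = spawn_rngs(seed, 1)[0]
        dm = distance_matrix(self.morph, seed=rng0)
        disparity = disparity_by_category(dm, self.factors, self.factor)
        anova = aggregate_over_resolutions(
            self.morph, self.factors, self.factor, test="anova", n_perm=n_perm,
            n_resolutions=n_resolutions, base_seed=seed,
            min_group_size=self.min_group_size, p_convention=p_convention)
        ph = {}
        if posthoc:
            ph = aggregate_over_resolutions(
                self.morph, self.factors, self.factor, test="posthoc",
                n_perm=n_perm, n_resolutions=n_resolutions, base_seed=seed,
                min_group_size=self.min_group_size, p_convention=p_convention)
        return DisparityAnovaResults(self.factor, disparity, anova, ph,
                                     n_perm, n_resolutions)


@dataclass
class FactorAssociationResults:
    tests: dict[tuple[str, str], assoc.AssociationResult]
    edges: list
    embedding: assoc.NetworkEmbedding
    clusters: list[set]
    alpha: float
    pr_threshold: float
    cluster_contrast_result: PairwiseTestResult | None = None
    cluster_sizes: tuple[int, int] | None = None
    cluster_disparity: tuple[DisparityEstimate, DisparityEstimate] | None = None

    def table(self) -> pd.DataFrame:
        rows = [{"factor_a": fa, "factor_b": fb, "chi2": r.chi2, "df": r.df,
                 "p": r.p} for (fa, fb), r in self.tests.items()]
        return pd.DataFrame(rows)

    def coordinates_frame(self) -> pd.DataFrame:
        emb = self.embedding
        return pd.DataFrame({
            "factor": [u[0] for u in emb.nodes],
            "category": [u[1] for u in emb.nodes],
            "x": emb.coordinates[:, 0], "y": emb.coordinates[:, 1],
        })

    def edges_frame(self) -> pd.DataFrame:
        rows = [{"factor_a": u[0], "category_a": u[1], "factor_b": v[0],
                 "category_b": v[1], "sign": s, "abs_pr": w}
                for u, v, s, w in self.edges]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Chi-squared associations among factor pairs:",
                 self.table().to_string(index=False, float_format="%.4g"),
                 "", f"NMDS stress = {self.embedding.stress:.4f}; "
                     f"{len(self.edges)} edges at alpha={self.alpha}, "
                     f"|PR|>={self.pr_threshold}"]
        for i, comp in enumerate(self.clusters, 1):
            cats = ", ".join(f"{f}:{c}" for f, c in sorted(comp))
            lines.append(f"cluster {i}: {cats}")
        if self.cluster_contrast_result is not None:
            r = self.cluster_contrast_result
            nA, nB = self.cluster_sizes
            lines += ["", (f"cluster 1 (n={nA}) vs cluster 2 (n={nB}): "
                           f"T = {r.t_obs:.4f}, P = {r.p_raw:.4g} "
                           f"({r.n_perm} permutations)")]
        return "\n".join(lines)


class FactorAssociation:
    """Associations among the categories of different grouping factors."""

    def __init__(self, factors: FactorTable, merges=None, exclusions=None,
                 counting: str = "cartesian"):
        self.factors = factors
        self.merges = merges
        self.exclusions = exclusions
        self.counting = counting

    def fit(self, alpha: float = 0.05, pr_threshold: float = 2.0, k: int = 2,
            n_starts: int = 16, seed: int = 0) -> FactorAssociationResults:
        tests = assoc.all_pairwise_associations(
            self.factors, self.merges, self.exclusions, self.counting,
            seed=seed)
        edges = assoc.association_edges(tests, alpha, pr_threshold)
        nodes, dist = assoc.pr_profile_distance(tests)
        embedding = assoc.nmds_embed(dist, nodes, k=k, n_starts=n_starts,
                                     seed=seed, edges=edges)
        clusters = assoc.positive_clusters(edges)
        return FactorAssociationResults(tests, edges, embedding, clusters,
                                        alpha, pr_threshold)

    def contrast_clusters(self, results: FactorAssociationResults,
                          morph: MorphMatrix, spec_a: dict | None = None,
                          spec_b: dict | None = None, n_perm: int = 99999,
                          seed: int = 0) -> FactorAssociationResults:
        """Disparity contrast between two clusters of associated categories.

        By default the two largest positive-edge components are converted
        to cluster specifications (factor -> its categories in the
        component); explicit specs may be supplied instead.
        """
        if spec_a is None or spec_b is None:
            if len(results.clusters) < 2:
                raise ValueError("fewer than 2 clusters in the association "
                                 "network; supply explicit cluster specs")
            def to_spec(comp):
                spec: dict[str, set] = {}
                for f, c in comp:
                    spec.setdefault(f, set()).add(c)
                return spec
            spec_a = spec_a or to_spec(results.clusters[0])
            spec_b = spec_b or to_spec(results.clusters[1])
        mem_a = cluster_members(self.factors, spec_a)
        mem_b = cluster_members(self.factors, spec_b)
        overlap = mem_a & mem_b
        mem_a, mem_b = mem_a - overlap, mem_b - overlap
        rngs = spawn_rngs(seed, 2)
        dm = distance_matrix(morph, seed=rngs[0])
        from .distance import group_disparity
        results.cluster_contrast_result = cluster_contrast(
            dm, mem_a, mem_b, n_perm=n_perm, seed=rngs[1])
        results.cluster_sizes = (len(mem_a), len(mem_b))
        results.cluster_disparity = (group_disparity(dm, sorted(mem_a)),
                                     group_disparity(dm, sorted(mem_b)))
        return results


@dataclass
class LatitudinalDisparityResults:
    profile: "object"   # LatProfile
    richness_gradient: GradientStats
    disparity_gradient: GradientStats
    disparity_gradient_filtered: GradientStats | None
    richness_disparity_corr: GradientStats | None

    def profile_frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def summary(self) -> str:
        def fmt(name, g):
            if g is None:
                return f"{name}: n/a"
            if not g.defined:
                return f"{name}: undefined (constant response)"
            return (f"{name}: r = {g.r:.3f}, P = {g.p:.3g}, "
                    f"slope = {g.slope:.4g}, intercept = {g.intercept:.4g} "
                    f"({g.n_bins} bins)")
        return "\n".join([
            "Latitudinal profile (10-degree bins):",
            self.profile_frame().to_string(index=False, float_format="%.4f"),
            "",
            fmt("richness ~ |latitude|", self.richness_gradient),
            fmt("disparity ~ |latitude|", self.disparity_gradient),
            fmt("disparity ~ |latitude| (bins above richness filter)",
                self.disparity_gradient_filtered),
            fmt("disparity ~ richness", self.richness_disparity_corr),
        ])


class LatitudinalDisparity:
    """Latitudinal gradient of species richness and floral disparity."""

    def __init__(self, occurrences: OccurrenceTable, morph: MorphMatrix,
                 width: float = 10.0, min_records: int = 1,
                 range_fill: bool = False):
        self.occ = occurrences.restrict_to(morph.taxa)
        self.morph = morph
        self.width = width
        self.min_records = min_records
        self.range_fill = range_fill

    def fit(self, seed: int = 0, n_draws: int = 1000,
            min_richness_filter: int | None = 5) -> LatitudinalDisparityResults:
        rngs = spawn_rngs(seed, 2)
        dm = distance_matrix(self.morph, seed=rngs[0])
        profile = bin_presence(self.occ, self.width, self.min_records,
                               self.range_fill)
        profile = profile_disparity(profile, dm)
        profile = richness_controlled_null(profile, dm, n_draws=n_draws,
                                           seed=rngs[1])
        rich = gradient_stats(profile, "richness")
        disp = gradient_stats(profile, "disparity")
        disp_f = None
        if min_richness_filter is not None:
            try:
                disp_f = gradient_stats(profile, "disparity",
                                        min_richness_filter=min_richness_filter)
            except ValueError:
                logger.warning("too few bins above the richness filter")
        # disparity vs richness across bins
        from scipy import stats as sps
        y = np.array([e.mean if (e and e.defined) else np.nan
                      for e in profile.disparity])
        x = profile.richness.astype(float)
        ok = ~np.isnan(y) & (x > 0)
        rd = None
        if ok.sum() >= 3 and np.ptp(y[ok]) > 0 and np.ptp(x[ok]) > 0:
            r, p = sps.pearsonr(x[ok], y[ok])
            fit = sps.linregress(x[ok], y[ok])
            rd = GradientStats(float(r), float(p), float(fit.slope),
                               float(fit.intercept), int(ok.sum()))
        return LatitudinalDisparityResults(profile, rich, disp, disp_f, rd)
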