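"""Factor-category association tests and the NMDS association network.

For every pair of grouping factors (e.g. growth form x climate) a
contingency table of species counts is tested for independence with a
Pearson chi-squared test (no continuity correction).  Association strength
and direction per category pair come from the Pearson residuals
PR = (O - E) / sqrt(E).

To visualise all pairwise associations at once, each category is given a
profile of its PR values against the categories of the other factors;
profiles are shifted to non-negativity (Bray-Curtis requires a non-negative
domain), turned into a Bray-Curtis dissimilarity matrix, and embedded in 2-D
with non-metric multidimensional scaling.  Significantly positively
associated categories land close together; edges record sign and |PR| for
category pairs from significant tests exceeding a residual threshold
(default |PR| >= 2, roughly a 5% standard-normal cutoff).  Clusters of
mutually associated categories are the connected components of the
positive-edge graph.

Species with multi-valued cells contribute one count to every category pair
in the Cartesian product of their category-sets (deterministic; a random
single-category resolution is available via ``counting="resolve"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2 as chi2_dist
from sklearn.manifold import MDS

from .datamodel import FactorTable
from .permutation import resolve_factor_polymorphism
from .rng import as_rng

logger = logging.getLogger("floradisp")

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "NetworkEmbedding",
    "build_contingency",
    "chi_squared",
    "association_edges",
    "pr_profile_distance",
    "nmds_embed",
    "positive_clusters",
]

Node = tuple[str, str]  # (factor, category)


@dataclass
class ContingencyTable:
    row_factor: str
    col_factor: str
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    merges: dict | None = None
    exclusions: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class AssociationResult:
    table: ContingencyTable
    chi2: float
    df: int
    p: float
    pr: np.ndarray  # Pearson residuals, same shape as counts

    @property
    def factors(self) -> tuple[str, str]:
        return (self.table.row_factor, self.table.col_factor)

    def pr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pr, index=self.table.row_labels,
                            columns=self.table.col_labels)


@dataclass
class NetworkEmbedding:
    nodes: list[Node]
    coordinates: np.ndarray  # (n_nodes, k), centred, unit RMS
    stress: float
    edges: list[tuple[Node, Node, int, float]]  # (u, v, sign, |PR|)


def _apply_merges_exclusions(cell: frozenset, factor: str, merges, exclusions) -> frozenset:
    cats = set(cell)
    if merges and factor in merges:
        cats = {merges[factor].get(c, c) for c in cats}
    if exclusions and factor in exclusions:
        cats -= set(exclusions[factor])
    return frozenset(cats)


def build_contingency(ft: FactorTable, factor_a: str, factor_b: str,
                      merges=None, exclusions=None, counting: str = "cartesian",
                      seed=None) -> ContingencyTable:
    """Species-count contingency table for two distinct factors.

    ``merges`` maps {factor: {old_category: new_category}} (e.g. fold
    'polar' into 'cold'), ``exclusions`` maps {factor: iterable of dropped
    categories}.  Taxa missing either factor (after exclusions) contribute
    nothing.  Under ``counting="cartesian"`` a taxon adds one count per
    (a, b) pair in the product of its category-sets; ``counting="resolve"``
    first resolves each taxon to a single category per factor (needs a
    seed).  Any zero marginal raises, with a hint to merge categories.
    """
    if factor_a == factor_b:
        raise ValueError("factors must be distinct")

    def final_labels(factor):
        labs = []
        for c in ft.factors[factor]:
            c2 = merges[factor].get(c, c) if merges and factor in merges else c
            if exclusions and factor in exclusions and c2 in set(exclusions[factor]):
                continue
            if c2 not in labs:
                labs.append(c2)
        return labs

    rows, cols = final_labels(factor_a), final_labels(factor_b)
    ri = {c: i for i, c in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=int)

    col_a, col_b = ft.column(factor_a), ft.column(factor_b)
    if counting == "resolve":
        res_a = resolve_factor_polymorphism(ft, factor_a, as_rng(seed))
        res_b = resolve_factor_polymorphism(ft, factor_b, as_rng(seed))
        col_a = {t: frozenset([c]) for t, c in res_a.items()}
        col_b = {t: frozenset([c]) for t, c in res_b.items()}
    elif counting != "cartesian":
        raise ValueError(f"unknown counting mode {counting!r}")

    for taxon in ft.taxa:
        ca = _apply_merges_exclusions(col_a.get(taxon, frozenset()), factor_a,
                                      merges, exclusions)
        cb = _apply_merges_exclusions(col_b.get(taxon, frozenset()), factor_b,
                                      merges, exclusions)
        if not ca or not cb:
            continue
        for a in ca:
            for b in cb:
                counts[ri[a], ci[b]] += 1

    zero_rows = [rows[i] for i in np.where(counts.sum(axis=1) == 0)[0]]
    zero_cols = [cols[j] for j in np.where(counts.sum(axis=0) == 0)[0]]
    if zero_rows or zero_cols:
        raise ValueError(
            f"zero marginals in {factor_a} x {factor_b} table "
            f"(rows {zero_rows}, cols {zero_cols}); consider merging sparse "
            f"categories")
    return ContingencyTable(factor_a, factor_b, rows, cols, counts,
                            merges=merges, exclusions=exclusions)


def chi_squared(ct: ContingencyTable) -> AssociationResult:
    """Pearson chi-squared test of independence, without continuity
    correction, plus the matrix of Pearson residuals (O - E)/sqrt(E)."""
    O = ct.counts.astype(float)
    total = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    if (E == 0).any():
        raise ValueError("expected count of zero; check marginals")
    chi2 = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(chi2_dist.sf(chi2, df))
    pr = (O - E) / np.sqrt(E)
    return AssociationResult(ct, chi2, df, p, pr)


def all_pairwise_associations(ft: FactorTable, merges=None, exclusions=None,
                              counting: str = "cartesian", seed=None
                              ) -> dict[tuple[str, str], AssociationResult]:
    """Chi-squared association test for every unordered pair of factors."""
    out = {}
    for fa, fb in combinations(ft.factor_names, 2):
        ct = build_contingency(ft, fa, fb, merges, exclusions, counting, seed)
        out[(fa, fb)] = chi_squared(ct)
    return out


def association_edges(results: dict[tuple[str, str], AssociationResult],
                      alpha: float = 0.05, pr_threshold: float = 2.0
                      ) -> list[tuple[Node, Node, int, float]]:
    """Edges of the association network.

    For each factor pair whose chi-squared test is significant at ``alpha``,
    every category pair with |PR| >= ``pr_threshold`` contributes an edge
    carrying the residual's sign and |PR| as weight.  Edges only ever join
    categories of different factors, and the list is invariant to the order
    in which factors were paired.
    """
    edges = []
    for res in results.values():
        if res.p >= alpha:
            continue
        fa, fb = res.factors
        for i, ra in enumerate(res.table.row_labels):
            for j, cb in enumerate(res.table.col_labels):
                prv = res.pr[i, j]
                if abs(prv) >= pr_threshold:
                    u, v = sorted([(fa, ra), (fb, cb)])
                    edges.append((u, v, 1 if prv > 0 else -1, float(abs(prv))))
    return sorted(edges)


def pr_profile_distance(results: dict[tuple[str, str], AssociationResult]
                        ) -> tuple[list[Node], np.ndarray]:
    """Bray-Curtis dissimilarities between category PR profiles.

    Each category's profile is its PR against every category of the other
    factors (0 for same-factor entries, which carry no test).  Profiles are
    shifted to non-negativity by subtracting the global minimum PR before
    applying Bray-Curtis.  A pair of all-zero shifted profiles gets
    distance 0.
    """
    nodes: list[Node] = []
    for res in results.values():
        fa, fb = res.factors
        for c in res.table.row_labels:
            if (fa, c) not in nodes:
                nodes.append((fa, c))
        for c in res.table.col_labels:
            if (fb, c) not in nodes:
                nodes.append((fb, c))
    nodes = sorted(nodes)
    ni = {u: i for i, u in enumerate(nodes)}
    M = np.zeros((len(nodes), len(nodes)))
    for res in results.values():
        fa, fb = res.factors
        for i, ra in enumerate(res.table.row_labels):
            for j, cb in enumerate(res.table.col_labels):
                M[ni[(fa, ra)], ni[(fb, cb)]] = res.pr[i, j]
                M[ni[(fb, cb)], ni[(fa, ra)]] = res.pr[i, j]
    shifted = M - M.min()
    with np.errstate(invalid="ignore"):
        dist = squareform(pdist(shifted, metric="braycurtis"))
    dist = np.nan_to_num(dist, nan=0.0)  # all-zero profile pairs
    return nodes, dist


def nmds_embed(dist: np.ndarray, nodes=None, k: int = 2, n_starts: int = 16,
               seed=None, max_iter: int = 300, edges=None) -> NetworkEmbedding:
    """Non-metric MDS (Kruskal stress-1) of a dissimilarity matrix.

    Best of ``n_starts`` random SMACOF initialisations, deterministic given
    ``seed``; coordinates are centred and scaled to unit root-mean-square.
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if nodes is None:
        nodes = [("", str(i)) for i in range(n)]
    rng = as_rng(seed)
    import inspect
    mds_params = inspect.signature(MDS).parameters
    common = dict(n_components=k, n_init=n_starts, max_iter=max_iter, eps=1e-9,
                  random_state=int(rng.integers(2 ** 31)))
    if "metric_mds" in mds_params:  # sklearn >= 1.9 naming
        mds = MDS(metric_mds=False, metric="precomputed", init="random",
                  **common)
    else:
        mds = MDS(metric=False, dissimilarity="precomputed",
                  normalized_stress=True, **common)
    coords = mds.fit_transform(dist)
    stress = float(mds.stress_)
    if stress > 0.2:
        logger.warning("NMDS stress %.3f is high; embedding may be unreliable", stress)
    coords = coords - coords.mean(axis=0)
    rms = np.sqrt((coords ** 2).sum(axis=1).mean())
    if rms > 0:
        coords = coords / rms
    return NetworkEmbedding(list(nodes), coords, stress, list(edges or []))


def positive_clusters(edges) -> list[set[Node]]:
    """Connected components of the positive-edge association graph,
    largest first (the 'clusters' of mutually associated categories)."""
    g = nx.Graph()
    for u, v, sign, _w in edges:
        if sign > 0:
            g.add_edge(u, v)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))
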