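"""Distance-based permutation ANOVA and central-tendency permutation tests.

Significance of disparity differences among factor categories is assessed
without distributional assumptions, because each taxon contributes to many
pairwise distances and classical degrees of freedom do not apply.

The one-way F-ratio is computed directly from the distance matrix using the
standard partition of squared interpoint distances:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within
    F = (SS_among / (a - 1)) / (SS_within / (N - a))

Its null distribution comes from shuffling taxon identities (equivalently,
group labels) without replacement.  The default p-value convention is the
plain exceedance count ``#{F_perm >= F_obs} / n_perm`` so that a
never-exceeded statistic reports p = 0; the ``"add-one"`` variant
``(#{>=} + 1) / (n_perm + 1)`` is available.  Ties count toward the
numerator.

Post-hoc comparisons use the central-tendency statistic T = difference of
the two categories' mean within-category pairwise distances, permuting taxa
between the two categories only, with a two-sided p and a Bonferroni
correction over the pairs tested.

Because factor cells may be multi-valued (a species growing in both
temperate and cold climates, say), every test is re-run over many random
single-category resolutions of the factor table — each with a fresh random
resolution of morphological polymorphism and a freshly computed distance
matrix — and reported as mean +- SD over resolutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FactorTable, MorphMatrix
from .distance import DistanceMatrix, distance_matrix
from .rng import as_rng

logger = logging.getLogger("floradisp")

__all__ = [
    "PermutationAnovaResult",
    "PairwiseTestResult",
    "AggregatedResult",
    "resolve_factor_polymorphism",
    "f_ratio",
    "permutation_anova",
    "posthoc_pairwise",
    "aggregate_over_resolutions",
]

# fancy-gather memory cap (elements per chunk)
_CHUNK_ELEMS = 20_000_000


@dataclass
class PermutationAnovaResult:
    f_obs: float
    p: float
    n_perm: int
    group_sizes: dict[str, int]


@dataclass
class PairwiseTestResult:
    pair: tuple[str, str]
    t_obs: float
    p_raw: float
    p_adj: float
    n_perm: int


@dataclass
class AggregatedResult:
    """Mean +- SD of a test statistic and its p-value over random
    polymorphism resolutions."""

    stat_mean: float
    stat_sd: float
    p_mean: float
    p_sd: float
    n_resolutions: int
    stats: list[float] = field(default_factory=list, repr=False)
    ps: list[float] = field(default_factory=list, repr=False)


def resolve_factor_polymorphism(ft: FactorTable, factor, seed) -> dict[str, str]:
    """One uniformly drawn category per taxon for one factor.

    Taxa with a missing cell are absent from the returned assignment (they
    take no part in tests).  Deterministic given seed.
    """
    rng = as_rng(seed)
    col = ft.column(factor)
    out = {}
    for taxon in ft.taxa:
        cell = col[taxon]
        if len(cell) == 0:
            continue
        cats = sorted(cell)
        out[taxon] = cats[rng.integers(len(cats))] if len(cats) > 1 else cats[0]
    return out


def _align(dm: DistanceMatrix, groups: dict[str, str]):
    """Restrict dm to taxa in ``groups``; return (D, labels, cats)."""
    taxa = [t for t in dm.taxa if t in groups]
    idx = dm.indices(taxa)
    D = dm.d[np.ix_(idx, idx)]
    if np.isnan(D).any():
        raise ValueError("distance matrix has undefined pairs among tested taxa")
    cats = sorted({groups[t] for t in taxa})
    code = {c: k for k, c in enumerate(cats)}
    labels = np.array([code[groups[t]] for t in taxa], dtype=int)
    return D, labels, cats


def _ss_terms(D2: np.ndarray, labels: np.ndarray):
    n = len(labels)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        members = np.where(labels == g)[0]
        ss_within += D2[np.ix_(members, members)].sum() / (2.0 * len(members))
    return ss_total, ss_within


def f_ratio(dm_or_d, groups_or_labels) -> float:
    """One-way distance-based F-ratio.

    Accepts either a :class:`DistanceMatrix` plus a taxon -> category
    mapping, or a square ndarray plus an integer label vector.  Every group
    must have at least 2 taxa.  Perfect separation (zero within-group
    distances with positive among-group variation) returns ``inf``.
    """
    if isinstance(dm_or_d, DistanceMatrix):
        D, labels, cats = _align(dm_or_d, groups_or_labels)
    else:
        D = np.asarray(dm_or_d, float)
        labels = np.asarray(groups_or_labels)
        cats = None
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2]
    if len(small):
        names = [cats[g] for g in small] if cats else list(small)
        raise ValueError(f"groups with fewer than 2 taxa: {names}")
    n, a = len(labels), len(uniq)
    ss_total, ss_within = _ss_terms(D ** 2, labels)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return float("inf") if ss_among > 0 else 0.0
    return float((ss_among / (a - 1)) / (ss_within / (n - a)))


def _pair_sums(M: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Per-row sums of M over all unordered pairs drawn from ``members``.

    ``members``: (B, k) index array.  Diagonal of M must be zero.  Chunked
    to bound the (B, k, k) gather.
    """
    B, k = members.shape
    out = np.empty(B)
    step = max(1, _CHUNK_ELEMS // max(1, k * k))
    for lo in range(0, B, step):
        sub = members[lo:lo + step]
        out[lo:lo + step] = M[sub[:, :, None], sub[:, None, :]].sum(axis=(1, 2)) / 2.0
    return out


def _perm_indices(rng, n_perm, n) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _p_from_count(count: int, n_perm: int, convention: str) -> float:
    if convention == "count":
        return count / n_perm
    if convention == "add-one":
        return (count + 1) / (n_perm + 1)
    raise ValueError(f"unknown p-value convention {convention!r}")


def permutation_anova(dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None,
                      p_convention: str = "count") -> PermutationAnovaResult:
    """Permutation test of the distance-based F-ratio.

    ``groups`` maps taxon -> category (missing taxa simply excluded).  The
    null shuffles taxon identities of the distance matrix without
    replacement, preserving group sizes and the multiset of distances.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_rng(seed)
    D, labels, cats = _align(dm, groups)
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 taxa: {[cats[g] for g in small]}")
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    D2 = D ** 2
    ss_total, ss_within_obs = _ss_terms(D2, labels)
    f_obs = f_ratio(D, labels)

    P = _perm_indices(rng, n_perm, n)
    ss_within = np.zeros(n_perm)
    for g in uniq:
        pos = np.where(labels == g)[0]
        ss_within += _pair_sums(D2, P[:, pos]) / len(pos)
    with np.errstate(divide="ignore"):
        f_perm = np.where(
            ss_within > 0,
            ((ss_total - ss_within) / (a - 1)) / (ss_within / np.maximum(n - a, 1)),
            np.where(ss_total - ss_within > 0, np.inf, 0.0),
        )
    if np.isinf(f_obs):
        count = int(np.isinf(f_perm).sum())
    else:
        # >= with a hair of slack so exact ties survive floating-point noise
        count = int((f_perm >= f_obs - 1e-9 * max(1.0, abs(f_obs))).sum())
    p = _p_from_count(count, n_perm, p_convention)
    sizes = {cats[g]: int(c) for g, c in zip(uniq, counts)}
    return PermutationAnovaResult(f_obs, p, n_perm, sizes)


def _two_group_perm(D: np.ndarray, nA: int, n_perm: int, rng,
                    p_convention: str) -> tuple[float, float]:
    """Two-sided central-tendency permutation test on a pooled submatrix.

    The first ``nA`` rows form group A, the rest group B; permutations
    shuffle taxa between the two groups.  Returns (t_obs, p).
    """
    m = D.shape[0]
    nB = m - nA
    if nA < 2 or nB < 2:
        raise ValueError("both groups need at least 2 taxa")

    def mean_pairs(sums, k):
        return sums / (k * (k - 1) / 2.0)

    base = np.arange(m)[None, :]
    tA = mean_pairs(_pair_sums(D, base[:, :nA]), nA)[0]
    tB = mean_pairs(_pair_sums(D, base[:, nA:]), nB)[0]
    t_obs = tA - tB
    P = _perm_indices(rng, n_perm, m)
    pA = mean_pairs(_pair_sums(D, P[:, :nA]), nA)
    pB = mean_pairs(_pair_sums(D, P[:, nA:]), nB)
    t_perm = pA - pB
    count = int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
    return float(t_obs), _p_from_count(count, n_perm, p_convention)


def posthoc_pairwise(dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None,
                     p_convention: str = "count") -> list[PairwiseTestResult]:
    """Central-tendency permutation tests for every unordered category pair,
    Bonferroni-corrected over the number of pairs tested.

    Permutations shuffle taxa within each two-category subset only.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_rng(seed)
    D, labels, cats = _align(dm, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 taxa: {[cats[g] for g in small]}")
    pairs = [(i, j) for k, i in enumerate(uniq) for j in uniq[k + 1:]]
    n_comp = len(pairs)
    results = []
    for gi, gj in pairs:
        pos = np.concatenate([np.where(labels == gi)[0], np.where(labels == gj)[0]])
        sub = D[np.ix_(pos, pos)]
        nA = int((labels == gi).sum())
        t_obs, p_raw = _two_group_perm(sub, nA, n_perm, rng, p_convention)
        results.append(PairwiseTestResult(
            pair=(cats[gi], cats[gj]), t_obs=t_obs, p_raw=p_raw,
            p_adj=min(1.0, p_raw * n_comp), n_perm=n_perm,
        ))
    return results


def _drop_small(assignment: dict[str, str], min_group_size: int) -> dict[str, str]:
    from collections import Counter
    sizes = Counter(assignment.values())
    small = {c for c, k in sizes.items() if k < min_group_size}
    if small:
        logger.warning("dropping categories with < %d taxa after resolution: %s",
                       min_group_size, sorted(small))
    return {t: c for t, c in assignment.items() if c not in small}


def aggregate_over_resolutions(m: MorphMatrix, ft: FactorTable, factor,
                               test: str = "anova", n_perm: int = 9999,
                               n_resolutions: int = 100, base_seed=0,
                               min_group_size: int = 3,
                               p_convention: str = "count"):
    """Run a test over ``n_resolutions`` fresh polymorphism resolutions.

    Each iteration draws a fresh monomorphic morphological matrix,
    recomputes the distance matrix, draws a fresh single-category factor
    assignment, drops categories left with fewer than ``min_group_size``
    taxa, and re-runs the test.  All randomness derives deterministically
    from ``base_seed``.

    Returns an :class:`AggregatedResult` for ``test="anova"``; for
    ``test="posthoc"`` a dict mapping category pair -> AggregatedResult
    (pairs aggregated over the resolutions in which both categories
    survived).
    """
    if n_resolutions < 1:
        raise ValueError("n_resolutions must be >= 1")
    if test not in ("anova", "posthoc"):
        raise ValueError(f"unknown test {test!r}")
    stats: list[float] = []
    ps: list[float] = []
    pair_stats: dict[tuple[str, str], list[float]] = {}
    pair_ps: dict[tuple[str, str], list[float]] = {}
    ss = (base_seed if isinstance(base_seed, np.random.SeedSequence)
          else np.random.SeedSequence(base_seed))
    children = ss.spawn(n_resolutions + 1)
    perm_seed = children[-1]
    for i, child in enumerate(children[:-1]):
        rng = np.random.default_rng(child)
        # permutation noise is shared across resolutions so the reported SD
        # reflects polymorphism-resolution randomness only (and is exactly 0
        # for polymorphism-free inputs)
        rng_perm = np.random.default_rng(perm_seed)
        try:
            dm = distance_matrix(m, seed=rng)
            assignment = _drop_small(
                resolve_factor_polymorphism(ft, factor, rng), min_group_size)
            if test == "anova":
                res = permutation_anova(dm, assignment, n_perm, rng_perm,
                                        p_convention)
                stats.append(res.f_obs)
                ps.append(res.p)
            else:
                for r in posthoc_pairwise(dm, assignment, n_perm, rng_perm,
                                          p_convention):
                    pair_stats.setdefault(r.pair, []).append(r.t_obs)
                    pair_ps.setdefault(r.pair, []).append(r.p_adj)
        except ValueError as exc:
            raise ValueError(f"resolution {i}: {exc}") from exc

    def _sd(xs):
        if len(xs) < 2 or len(set(xs)) == 1:
            return 0.0
        return float(np.std(xs, ddof=1))

    def _agg(xs, qs):
        return AggregatedResult(float(np.mean(xs)), _sd(xs), float(np.mean(qs)),
                                _sd(qs), len(xs), list(xs), list(qs))

    if test == "anova":
        return _agg(stats, ps)
    return {pair: _agg(pair_stats[pair], pair_ps[pair]) for pair in sorted(pair_stats)}
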