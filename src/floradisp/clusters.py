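"""Membership and disparity contrast for clusters of associated categories.

A cluster specification constrains some factors to admissible category
sets; a species belongs to the cluster when, for every constrained factor,
its category-set intersects the admissible set (factors left out of the
spec impose no constraint).  E.g. the spec
``{"habitat": {"forests"}, "climate": {"tropical"}, "growth_form":
{"trees"}, "region": {"Africa", "South America"}}`` selects tropical forest
trees native to Africa or South America — the intersection across factors
of the union within factors.

Two clusters are contrasted with the central-tendency permutation test on
the difference of their mean within-group pairwise dissimilarities.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import FactorTable
from .distance import DistanceMatrix
from .permutation import PairwiseTestResult, _two_group_perm
from .rng import as_rng

logger = logging.getLogger("floradisp")

__all__ = ["cluster_members", "cluster_contrast"]


def cluster_members(ft: FactorTable, spec: dict) -> set[str]:
    """Taxa matching a cluster specification.

    ``spec`` maps factor name -> iterable of admissible categories.  A
    taxon qualifies if its category-set intersects the admissible set for
    every constrained factor; taxa missing any constrained factor are
    excluded.  Enlarging any admissible set can only add members.
    """
    for factor, cats in spec.items():
        if factor not in ft.factors:
            raise KeyError(f"unknown factor {factor!r}")
        bad = set(cats) - set(ft.factors[factor])
        if bad:
            raise ValueError(f"unknown categories for factor {factor!r}: {sorted(bad)}")
    cols = {f: ft.column(f) for f in spec}
    members = set()
    for taxon in ft.taxa:
        ok = True
        for factor, cats in spec.items():
            cell = cols[factor][taxon]
            if len(cell) == 0 or not (cell & set(cats)):
                ok = False
                break
        if ok:
            members.add(taxon)
    if not members:
        logger.warning("cluster specification matched no taxa: %s", spec)
    return members


def cluster_contrast(dm: DistanceMatrix, members_a, members_b,
                     n_perm: int = 99999, seed=None,
                     p_convention: str = "count") -> PairwiseTestResult:
    """Two-sided permutation test of the disparity difference between two
    clusters.

    The statistic is T = D̄(A) - D̄(B); permutations shuffle taxa between
    the two clusters without replacement.  Taxa in both clusters are
    removed from both (with a warning) so the groups are disjoint.
    """
    A, B = set(members_a), set(members_b)
    overlap = A & B
    if overlap:
        logger.warning("removing %d taxa present in both clusters", len(overlap))
        A -= overlap
        B -= overlap
    A = sorted(A)
    B = sorted(B)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each cluster needs at least 2 exclusive taxa")
    # canonical internal order so the two-sided p is exactly invariant to
    # swapping the clusters (only the sign of T flips)
    flipped = tuple(B) < tuple(A)
    first, second = (B, A) if flipped else (A, B)
    idx = dm.indices(list(first) + list(second))
    D = dm.d[np.ix_(idx, idx)]
    if np.isnan(D).any():
        raise ValueError("undefined pairwise distances among cluster taxa")
    t_obs, p = _two_group_perm(D, len(first), n_perm, as_rng(seed), p_convention)
    if flipped:
        t_obs = -t_obs
    return PairwiseTestResult(pair=("A", "B"), t_obs=t_obs, p_raw=p, p_adj=p,
                              n_perm=n_perm)
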