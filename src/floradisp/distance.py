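"""Mean-character-difference distances and mean-pairwise-dissimilarity disparity.

The dissimilarity between two taxa is the *mean character difference*, a
Gower-type index over the characters scored in both taxa:

    D(i, j) = (1 / n_shared) * sum_k d_k(i, j)

with per-character contributions

* binary / unordered categorical: d_k = 0 if the states match else 1;
* ordered categorical: d_k = |rank_i - rank_k| / range_span;
* continuous: d_k = |x_i - x_j| / range_span (0 when the span is 0).

Characters missing in either taxon are excluded from numerator and
denominator, so D is always in [0, 1].  Spans are computed over the whole
dataset so that distances are comparable between groups.

Disparity of a group is the mean of all defined within-group pairwise D
values; the standard deviation reported with it describes those pairwise
values (sample SD, n-1 denominator).

Polymorphic cells cannot enter the index directly; :func:`distance_matrix`
first draws one state uniformly at random per polymorphic cell
(:func:`resolve_morph_polymorphism`), and callers that care about this
sampling noise recompute the matrix under many seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CharacterDefinition, MorphMatrix
from .rng import as_rng

logger = logging.getLogger("floradisp")

__all__ = [
    "DistanceMatrix",
    "DisparityEstimate",
    "resolve_morph_polymorphism",
    "pair_distance",
    "distance_matrix",
    "group_disparity",
    "disparity_by_category",
]


@dataclass
class DistanceMatrix:
    """Symmetric taxa x taxa mean character differences.

    ``d`` holds NaN for pairs with no shared scored character (undefined,
    never silently 0); ``n_shared`` counts characters scored in both taxa.
    """

    taxa: list[str]
    d: np.ndarray
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.n_shared = np.asarray(self.n_shared, dtype=int)
        n = len(self.taxa)
        if self.d.shape != (n, n) or self.n_shared.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    def indices(self, members) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in members if t not in pos]
        if missing:
            raise KeyError(f"taxa not in distance matrix: {missing}")
        return np.array([pos[t] for t in members], dtype=int)

    def submatrix(self, members) -> np.ndarray:
        idx = self.indices(members)
        return self.d[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        d = df.to_numpy(float)
        n_shared = np.where(np.isnan(d), 0, 1)
        np.fill_diagonal(n_shared, 0)
        return cls(list(df.index.astype(str)), d, n_shared)


@dataclass
class DisparityEstimate:
    """Mean pairwise dissimilarity of a group, with the SD of the pairwise
    values, the group size and the number of defined pairs.  ``defined`` is
    False for groups of fewer than two taxa (or with no defined pair)."""

    mean: float
    sd: float
    n_taxa: int
    n_pairs: int
    defined: bool = True


def resolve_morph_polymorphism(m: MorphMatrix, seed) -> MorphMatrix:
    """Replace every polymorphic cell by one uniformly drawn member state.

    Missing cells are untouched; the result is deterministic given ``seed``
    (an int or a numpy Generator).  A matrix without polymorphism is
    returned unchanged (same object).
    """
    if not m.is_polymorphic():
        return m
    rng = as_rng(seed)
    cells = m.cells.copy()
    for i in range(m.n_taxa):
        for j in range(m.n_characters):
            cell = cells[i, j]
            if len(cell) > 1:
                states = sorted(cell, key=repr)
                cells[i, j] = frozenset([states[rng.integers(len(states))]])
    return MorphMatrix(list(m.taxa), list(m.characters), cells)


def _single_state(cell):
    if len(cell) == 0:
        return None
    if len(cell) > 1:
        raise ValueError("polymorphic cell: resolve polymorphism first")
    return next(iter(cell))


def pair_distance(a, b, defs) -> tuple[float, int]:
    """Mean character difference between two monomorphic taxon rows.

    ``a`` and ``b`` are sequences of scalar states (or singleton sets), with
    ``None``/empty marking missing.  Returns ``(D, n_shared)``; D is NaN when
    no character is scored in both taxa.
    """
    num = 0.0
    n_shared = 0
    for xa, xb, cd in zip(a, b, defs):
        if isinstance(xa, (set, frozenset)):
            xa = _single_state(xa)
        if isinstance(xb, (set, frozenset)):
            xb = _single_state(xb)
        if xa is None or xb is None:
            continue
        n_shared += 1
        if cd.kind in ("binary", "unordered"):
            num += 0.0 if str(xa) == str(xb) else 1.0
        elif cd.kind == "ordered":
            if cd.range_span > 0:
                num += abs(cd.rank(xa) - cd.rank(xb)) / cd.range_span
        else:  # continuous
            if cd.range_span > 0:
                num += abs(float(xa) - float(xb)) / cd.range_span
    if n_shared == 0:
        return float("nan"), 0
    return num / n_shared, n_shared


def _encode(m: MorphMatrix) -> np.ndarray:
    """Numeric (n_taxa, n_char) array: state rank / value, NaN = missing."""
    X = np.full((m.n_taxa, m.n_characters), np.nan)
    for j, cd in enumerate(m.characters):
        for i in range(m.n_taxa):
            s = _single_state(m.cells[i, j])
            if s is None:
                continue
            X[i, j] = float(s) if cd.kind == "continuous" else cd.rank(s)
    return X


def distance_matrix(m: MorphMatrix, seed=None) -> DistanceMatrix:
    """Mean-character-difference matrix over all taxon pairs.

    Polymorphism is resolved first with ``seed`` (required if the matrix is
    polymorphic).  Pairs sharing no scored character are NaN, with a warning
    listing them.
    """
    if m.n_taxa < 2:
        raise ValueError("need at least 2 taxa for a distance matrix")
    if m.is_polymorphic():
        if seed is None:
            raise ValueError("matrix is polymorphic: a seed is required")
        m = resolve_morph_polymorphism(m, seed)
    X = _encode(m)
    n = m.n_taxa
    num = np.zeros((n, n))
    den = np.zeros((n, n), dtype=int)
    for j, cd in enumerate(m.characters):
        x = X[:, j]
        valid = ~np.isnan(x)
        V = np.outer(valid, valid)
        xf = np.where(valid, x, 0.0)
        if cd.kind in ("binary", "unordered"):
            dk = (xf[:, None] != xf[None, :]).astype(float)
        elif cd.range_span > 0:
            dk = np.abs(xf[:, None] - xf[None, :]) / cd.range_span
        else:
            dk = np.zeros((n, n))
        num += np.where(V, dk, 0.0)
        den += V
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(den, 0)
    iu = np.triu_indices(n, 1)
    undef = np.isnan(d[iu])
    if undef.any():
        pairs = [(m.taxa[iu[0][k]], m.taxa[iu[1][k]]) for k in np.where(undef)[0]]
        logger.warning("%d taxon pairs share no scored character: %s",
                       len(pairs), pairs[:10])
    return DistanceMatrix(list(m.taxa), d, den)


def group_disparity(dm: DistanceMatrix, members) -> DisparityEstimate:
    """Mean pairwise dissimilarity over all defined within-group pairs."""
    members = list(members)
    n = len(members)
    if n < 2:
        return DisparityEstimate(float("nan"), float("nan"), n, 0, defined=False)
    sub = dm.submatrix(members)
    vals = sub[np.triu_indices(n, 1)]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return DisparityEstimate(float("nan"), float("nan"), n, 0, defined=False)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return DisparityEstimate(float(np.mean(vals)), sd, n, int(len(vals)))


def disparity_by_category(dm: DistanceMatrix, ft, factor) -> dict[str, DisparityEstimate]:
    """Descriptive disparity per category of one factor.

    A multi-membership taxon counts in every category it belongs to (this is
    the descriptive convention; permutation tests instead resolve each taxon
    to a single category).  Taxa missing the factor, or absent from the
    distance matrix, are excluded; empty categories are skipped with a
    warning.
    """
    col = ft.column(factor)
    in_dm = set(dm.taxa)
    dropped = sorted(set(col) - in_dm)
    if dropped:
        logger.warning("%d taxa in factor table but not in distance matrix: %s",
                       len(dropped), dropped[:10])
    out = {}
    for cat in ft.factors[factor]:
        members = [t for t, cell in col.items() if cat in cell and t in in_dm]
        if not members:
            logger.warning("category %r of factor %r has no taxa; skipped", cat, factor)
            continue
        out[cat] = group_disparity(dm, members)
    return out
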