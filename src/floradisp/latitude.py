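"""Latitudinal richness and disparity profiles with a richness-controlled null.

Species presence is scored per 10-degree latitude bin (18 half-open bins
[lower, lower + 10) from -90); a species may be present in many bins.
Per-bin disparity is the mean pairwise dissimilarity of the species present.
Gradients are summarised by the Pearson correlation and an OLS fit of the
bin response against the absolute bin midpoint (distance from the Equator).

Because mean pairwise dissimilarity could in principle vary with the number
of species sampled, each bin's observed disparity is also compared with a
null distribution obtained by drawing equally sized species subsets
uniformly from the full pool: if tropical bins are more disparate only
because they are richer, their observed values stay inside this
richness-matched envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import OccurrenceTable
from .distance import DisparityEstimate, DistanceMatrix, group_disparity
from .rng import as_rng

logger = logging.getLogger("floradisp")

__all__ = [
    "LatProfile",
    "GradientStats",
    "bin_presence",
    "profile_disparity",
    "gradient_stats",
    "richness_controlled_null",
]

_GATHER_CAP = 20_000_000


@dataclass
class LatProfile:
    """Per-bin presence sets, richness, disparity and null summaries."""

    edges: np.ndarray                       # bin lower edges, length n_bins
    width: float
    present: list[set[str]]                 # species present per bin
    disparity: list[DisparityEstimate | None] = field(default_factory=list)
    null_mean: list[float] = field(default_factory=list)
    null_lo: list[float] = field(default_factory=list)
    null_hi: list[float] = field(default_factory=list)
    null_p: list[float] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def richness(self) -> np.ndarray:
        return np.array([len(s) for s in self.present], dtype=int)

    @property
    def midpoints(self) -> np.ndarray:
        return self.edges + self.width / 2.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(self.n_bins):
            est = self.disparity[b] if self.disparity else None
            rows.append({
                "bin_lower": self.edges[b],
                "bin_upper": self.edges[b] + self.width,
                "richness": len(self.present[b]),
                "disparity": est.mean if est and est.defined else np.nan,
                "disparity_sd": est.sd if est and est.defined else np.nan,
                "n_pairs": est.n_pairs if est else 0,
                "null_mean": self.null_mean[b] if self.null_mean else np.nan,
                "null_q025": self.null_lo[b] if self.null_lo else np.nan,
                "null_q975": self.null_hi[b] if self.null_hi else np.nan,
                "null_p": self.null_p[b] if self.null_p else np.nan,
            })
        return pd.DataFrame(rows)


@dataclass
class GradientStats:
    """Pearson correlation and OLS fit of a bin response on |latitude|."""

    r: float
    p: float
    slope: float
    intercept: float
    n_bins: int
    defined: bool = True


def bin_presence(occ: OccurrenceTable, width: float = 10.0, min_records: int = 1,
                 range_fill: bool = False) -> LatProfile:
    """Score species presence per latitude bin from occurrence records.

    A species is present in a bin when at least ``min_records`` of its
    records fall in [lower, lower + width); latitude 90 closes the last bin.
    With ``range_fill`` every bin between a species' extreme records is
    marked present (a coarse stand-in for curated range maps).
    """
    if len(occ.records) == 0:
        raise ValueError("no occurrence records")
    edges = np.arange(-90.0, 90.0, width)
    n_bins = len(edges)
    present: list[set[str]] = [set() for _ in range(n_bins)]
    lats = occ.records["latitude"].to_numpy(float)
    sps = occ.records["species"].to_numpy(str)
    bins = np.minimum(((lats - (-90.0)) // width).astype(int), n_bins - 1)
    counts: dict[tuple[str, int], int] = {}
    for sp, b in zip(sps, bins):
        counts[(sp, b)] = counts.get((sp, b), 0) + 1
    for (sp, b), k in counts.items():
        if k >= min_records:
            present[b].add(sp)
    if range_fill:
        for sp in np.unique(sps):
            hit = [b for b in range(n_bins) if sp in present[b]]
            if hit:
                for b in range(hit[0], hit[-1] + 1):
                    present[b].add(sp)
    return LatProfile(edges=edges, width=width, present=present)


def profile_disparity(profile: LatProfile, dm: DistanceMatrix) -> LatProfile:
    """Fill per-bin disparity estimates; bins with < 2 species stay undefined."""
    known = set(dm.taxa)
    disp: list[DisparityEstimate | None] = []
    for b in range(profile.n_bins):
        members = sorted(profile.present[b] & known)
        dropped = profile.present[b] - known
        if dropped:
            logger.info("bin %g: %d present species not in distance matrix",
                        profile.edges[b], len(dropped))
        disp.append(group_disparity(dm, members) if len(members) >= 2 else None)
    profile.disparity = disp
    return profile


def gradient_stats(profile: LatProfile, response: str = "richness",
                   min_richness_filter: int | None = None) -> GradientStats:
    """Correlation/regression of a per-bin response against |bin midpoint|.

    Uses bins with at least one species (and a defined disparity when
    ``response="disparity"``); ``min_richness_filter`` additionally drops
    bins with that many species or fewer.  A constant response has no
    defined correlation and is returned flagged.
    """
    rich = profile.richness
    mids = np.abs(profile.midpoints)
    if response == "richness":
        y = rich.astype(float)
        usable = rich > 0
    elif response == "disparity":
        if not profile.disparity:
            raise ValueError("profile has no disparity; call profile_disparity first")
        y = np.array([e.mean if (e and e.defined) else np.nan
                      for e in profile.disparity])
        usable = ~np.isnan(y)
    else:
        raise ValueError(f"unknown response {response!r}")
    if min_richness_filter is not None:
        usable &= rich > min_richness_filter
    x, y = mids[usable], y[usable]
    if len(x) < 3:
        raise ValueError(f"need >=3 usable bins, have {len(x)}")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return GradientStats(float("nan"), float("nan"), 0.0, float(np.mean(y)),
                             len(x), defined=False)
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return GradientStats(float(r), float(p), float(fit.slope),
                         float(fit.intercept), len(x))


def _subset_disparity_draws(D: np.ndarray, pool: np.ndarray, n_b: int,
                            n_draws: int, rng) -> np.ndarray:
    """Mean pairwise distance of ``n_draws`` uniform size-``n_b`` subsets."""
    out = np.empty(n_draws)
    step = max(1, _GATHER_CAP // (n_b * n_b))
    has_nan = np.isnan(D).any()
    for lo in range(0, n_draws, step):
        b = min(step, n_draws - lo)
        idx = np.argsort(rng.random((b, len(pool))), axis=1)[:, :n_b]
        members = pool[idx]
        sub = D[members[:, :, None], members[:, None, :]]
        if has_nan:
            sums = np.nansum(sub, axis=(1, 2)) / 2.0
            cnts = (~np.isnan(sub)).sum(axis=(1, 2)) / 2.0 - n_b / 2.0
            out[lo:lo + b] = sums / np.maximum(cnts, 1)
        else:
            out[lo:lo + b] = sub.sum(axis=(1, 2)) / (n_b * (n_b - 1))
    return out


def richness_controlled_null(profile: LatProfile, dm: DistanceMatrix,
                             n_draws: int = 10000, seed=None) -> LatProfile:
    """Null disparity envelope per bin, controlling for richness.

    For each bin with n_b >= 2 present species, draws ``n_draws`` uniform
    subsets of size n_b from the full species pool of the distance matrix
    and records the null mean, the 2.5%/97.5% quantiles, and the two-sided
    empirical p of the observed bin disparity.
    """
    rng = as_rng(seed)
    if not profile.disparity:
        profile = profile_disparity(profile, dm)
    pool = np.arange(len(dm.taxa))
    nm, lo, hi, pp = [], [], [], []
    for b in range(profile.n_bins):
        est = profile.disparity[b]
        n_b = len(profile.present[b] & set(dm.taxa))
        if est is None or not est.defined or n_b < 2 or n_b > len(pool):
            nm.append(np.nan); lo.append(np.nan); hi.append(np.nan); pp.append(np.nan)
            continue
        draws = _subset_disparity_draws(dm.d, pool, n_b, n_draws, rng)
        q025, q975 = np.quantile(draws, [0.025, 0.975])
        p_lo = (draws <= est.mean + 1e-12).mean()
        p_hi = (draws >= est.mean - 1e-12).mean()
        nm.append(float(draws.mean())); lo.append(float(q025)); hi.append(float(q975))
        pp.append(float(min(1.0, 2.0 * min(p_lo, p_hi))))
    profile.null_mean, profile.null_lo, profile.null_hi, profile.null_p = nm, lo, hi, pp
    return profile
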