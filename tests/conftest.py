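"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive everything from first principles
(double loops over raw state-sets, explicit sum-of-squares partitions,
exhaustive enumeration of label assignments) so they share no code path
with the implementation they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from floradisp import CharacterDefinition, MorphMatrix

# ---------------------------------------------------------------------------
# brute-force mean character difference
# ---------------------------------------------------------------------------

def oracle_pair_distance(cells_a, cells_b, defs):
    """Direct per-character loop over raw (monomorphic) state-sets."""
    total, shared = 0.0, 0
    for ca, cb, cd in zip(cells_a, cells_b, defs):
        if len(ca) == 0 or len(cb) == 0:
            continue
        (a,), (b,) = tuple(ca), tuple(cb)
        shared += 1
        if cd.kind in ("binary", "unordered"):
            total += 0.0 if str(a) == str(b) else 1.0
        elif cd.kind == "ordered":
            if cd.range_span > 0:
                total += abs(cd.state_labels.index(str(a)) -
                             cd.state_labels.index(str(b))) / cd.range_span
        else:
            if cd.range_span > 0:
                total += abs(float(a) - float(b)) / cd.range_span
    if shared == 0:
        return float("nan"), 0
    return total / shared, shared


def oracle_distance_matrix(m: MorphMatrix) -> np.ndarray:
    n = m.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij, _ = oracle_pair_distance(m.cells[i], m.cells[j], m.characters)
            d[i, j] = d[j, i] = dij
    return d


# ---------------------------------------------------------------------------
# first-principles F-ratio and exhaustive permutation p-values
# ---------------------------------------------------------------------------

def oracle_f_ratio(D: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    ss_total = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(D[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))


def _multiset_perms(labels):
    from sympy.utilities.iterables import multiset_permutations
    return list(multiset_permutations(list(labels)))


def oracle_exhaustive_anova_p(D: np.ndarray, labels) -> float:
    """Exact permutation p: F over every distinct label ordering."""
    f_obs = oracle_f_ratio(D, labels)
    fs = [oracle_f_ratio(D, perm) for perm in _multiset_perms(labels)]
    return float(np.mean([f >= f_obs - 1e-12 for f in fs]))


def _mean_within(D, idx):
    return float(np.mean([D[i, j] for i, j in combinations(sorted(idx), 2)]))


def oracle_exhaustive_t_p(D: np.ndarray, n_a: int) -> tuple[float, float]:
    """Exact two-sided central-tendency p over all splits of the pooled set
    (first n_a indices form group A in the observed assignment)."""
    m = D.shape[0]
    t_obs = _mean_within(D, range(n_a)) - _mean_within(D, range(n_a, m))
    ts = []
    for a_set in combinations(range(m), n_a):
        b_set = [i for i in range(m) if i not in a_set]
        ts.append(_mean_within(D, a_set) - _mean_within(D, b_set))
    p = float(np.mean([abs(t) >= abs(t_obs) - 1e-12 for t in ts]))
    return t_obs, p


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def mixed_defs():
    return [
        CharacterDefinition("b1", "binary", ("0", "1")),
        CharacterDefinition("u1", "unordered", ("a", "b", "c")),
        CharacterDefinition("o1", "ordered", ("0", "1", "2", "3")),
        CharacterDefinition("c1", "continuous"),
    ]


def random_mixed_matrix(rng, n_taxa=8, missing_frac=0.1) -> MorphMatrix:
    """A small random mixed-type monomorphic matrix for oracle comparisons."""
    defs = [
        CharacterDefinition("b1", "binary", ("0", "1")),
        CharacterDefinition("b2", "binary", ("0", "1")),
        CharacterDefinition("u1", "unordered", ("a", "b", "c")),
        CharacterDefinition("u2", "unordered", ("x", "y", "z", "w")),
        CharacterDefinition("o1", "ordered", ("0", "1", "2")),
        CharacterDefinition("o2", "ordered", ("0", "1", "2", "3", "4")),
        CharacterDefinition("c1", "continuous"),
        CharacterDefinition("c2", "continuous"),
    ]
    states = np.empty((n_taxa, len(defs)), dtype=object)
    for j, cd in enumerate(defs):
        for i in range(n_taxa):
            if rng.random() < missing_frac:
                states[i, j] = None
            elif cd.kind == "continuous":
                states[i, j] = float(np.round(rng.uniform(0, 10), 3))
            else:
                states[i, j] = cd.state_labels[rng.integers(len(cd.state_labels))]
    taxa = [f"t{i}" for i in range(n_taxa)]
    return MorphMatrix.from_states(taxa, defs, states)


@pytest.fixture
def small_dataset():
    """Deterministic small synthetic dataset shared across tests."""
    from floradisp import SynthSpec, simulate_dataset
    return simulate_dataset(SynthSpec(seed=20240917, n_taxa=80))
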