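"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a large mixed-type morphological matrix (hundreds of
taxa by a few dozen binary / unordered / ordered / continuous characters
with realistic missing-data and polymorphism rates), an ecological factor
table with multi-valued cells and a planted two-block association structure
(e.g. tropical <-> trees <-> forests enriched), and GBIF-style occurrence
records tying species latitudinal ranges to their climate category.

Within-group trait variation is controlled by a per-category *dispersion*
parameter theta: for each (group, character) the categorical state
probabilities are drawn from a symmetric Dirichlet(theta).  Small theta
concentrates a group on one state (disparity -> 0); large theta approaches
uniform state usage (maximal disparity).  For continuous characters theta
scales the within-group standard deviation.  Groups follow the categories
of one designated *driver* factor (climate by default), so a high tropical
theta plants the "tropical species are more disparate" effect end to end,
through to a tropical peak in the latitudinal disparity profile.

Everything is deterministic given the spec's seed; the three generators
share derived seed streams so the factor, trait and occurrence tables of
one spec describe the same species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .datamodel import (CharacterDefinition, FactorTable, MorphMatrix,
                        OccurrenceTable)
import pandas as pd

__all__ = ["SynthSpec", "SimulatedDataset", "gen_morph_matrix",
           "gen_factor_table", "gen_occurrences", "simulate_dataset"]

# Default factor vocabularies (Ericales-style study design).
DEFAULT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "growth_form": ("trees", "shrubs", "lianas and climbers",
                    "herbs and aquatic herbs", "root parasites"),
    "habitat": ("forests", "open", "wet"),
    "climate": ("tropical", "arid", "temperate", "cold", "polar"),
    "region": ("North America", "Eurasia", "South America", "Africa",
               "Indo-Pacific", "Australia"),
}

# Planted association blocks: block 1 = tropical forest trees of Africa /
# South America; block 2 = temperate-to-polar shrubs & herbs of the northern
# continents in open or wet habitats.
DEFAULT_BLOCKS: tuple[dict[str, tuple[str, ...]], ...] = (
    {"growth_form": ("trees",), "habitat": ("forests",),
     "climate": ("tropical",), "region": ("Africa", "South America")},
    {"growth_form": ("shrubs", "herbs and aquatic herbs"),
     "habitat": ("open", "wet"),
     "climate": ("temperate", "arid", "cold", "polar"),
     "region": ("North America", "Eurasia")},
)

# Dispersion w in [0, 1] per climate category: tropical species explore a
# larger share of the morphospace.  For a K-state character the group's
# state distribution is (1-w)*modal + w*uniform with the modal state shared
# across groups, so within-group expected mismatch grows monotonically with
# w and a latitude bin mixing several groups is never more disparate than
# the highest-dispersion group itself.  The defaults keep within-group mean
# character differences near the ~0.2 scale typical of floral trait data.
DEFAULT_DISPERSION: dict[str, float] = {
    "tropical": 0.35, "arid": 0.2, "temperate": 0.2, "cold": 0.15,
    "polar": 0.06,
}

# Latitude band (absolute degrees) species ranges are centred in, per
# climate category; tropical ranges straddle the Equator.
_CLIMATE_BANDS: dict[str, tuple[float, float]] = {
    "tropical": (0.0, 20.0), "arid": (15.0, 35.0), "temperate": (25.0, 50.0),
    "cold": (45.0, 65.0), "polar": (60.0, 80.0),
}


@dataclass
class SynthSpec:
    """Parameters of one synthetic study.

    Defaults reproduce the study conditions the analysis is meant for:
    380 taxa x 36 mixed characters with 13.4% missing and 2.2% polymorphic
    cells, a four-factor table with 3.6% missing and 16.5% multi-valued
    cells, a planted two-block association structure, a high-dispersion
    tropical group, and species latitudinal ranges tied to climate.
    """

    seed: int
    n_taxa: int = 380
    n_binary: int = 16
    n_unordered: int = 10
    n_ordered: int = 6
    n_continuous: int = 4
    states_unordered: int = 4
    states_ordered: int = 4
    missing_frac: float = 0.134
    morph_polym_frac: float = 0.022
    factor_missing_frac: float = 0.036
    factor_polym_frac: float = 0.165
    vocabularies: dict = field(default_factory=lambda: dict(DEFAULT_VOCABULARIES))
    blocks: tuple = DEFAULT_BLOCKS
    block_probs: tuple = (0.45, 0.55)
    association_strength: float = 0.75
    driver_factor: str = "climate"
    dispersion: dict = field(default_factory=lambda: dict(DEFAULT_DISPERSION))
    default_dispersion: float = 0.2
    group_traits: bool = True   # False: one shared trait distribution for all
                                # taxa (disparity independent of every factor)
    modal_shift: float = 0.15   # probability a group swaps a character's
                                # modal state for its own (between-group
                                # location effect feeding the ANOVA)
    continuous_sd_scale: float = 0.5
    records_per_species: int = 8
    lat_range_width: float = 20.0

    def __post_init__(self) -> None:
        for name in ("missing_frac", "morph_polym_frac", "factor_missing_frac",
                     "factor_polym_frac", "association_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.missing_frac + self.morph_polym_frac > 1:
            raise ValueError("missing_frac + morph_polym_frac exceeds 1")
        if self.factor_missing_frac + self.factor_polym_frac > 1:
            raise ValueError("factor_missing_frac + factor_polym_frac exceeds 1")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.states_unordered < 2 or self.states_ordered < 2:
            raise ValueError("discrete characters need >= 2 states")
        if self.morph_polym_frac > 0 and (
                self.n_binary + self.n_unordered + self.n_ordered +
                self.n_continuous) == 0:
            raise ValueError("polymorphism requested on an empty character plan")
        if self.driver_factor not in self.vocabularies:
            raise ValueError(f"driver factor {self.driver_factor!r} not in vocabularies")
        if abs(sum(self.block_probs) - 1.0) > 1e-9:
            raise ValueError("block_probs must sum to 1")
        for cat, w in {**self.dispersion, "default": self.default_dispersion}.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"dispersion for {cat!r} must be in [0, 1]")
        if not (0.0 <= self.modal_shift <= 1.0):
            raise ValueError("modal_shift must be in [0, 1]")

    @property
    def taxa(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"sp{str(i + 1).zfill(width)}" for i in range(self.n_taxa)]

    def characters(self) -> list[CharacterDefinition]:
        defs = []
        for i in range(self.n_binary):
            defs.append(CharacterDefinition(f"bin{i + 1:02d}", "binary", ("0", "1")))
        for i in range(self.n_unordered):
            labels = tuple(str(s) for s in range(self.states_unordered))
            defs.append(CharacterDefinition(f"uno{i + 1:02d}", "unordered", labels))
        for i in range(self.n_ordered):
            labels = tuple(str(s) for s in range(self.states_ordered))
            defs.append(CharacterDefinition(f"ord{i + 1:02d}", "ordered", labels))
        for i in range(self.n_continuous):
            defs.append(CharacterDefinition(f"con{i + 1:02d}", "continuous"))
        return defs

    def theta(self, category: str) -> float:
        return float(self.dispersion.get(category, self.default_dispersion))


@dataclass
class SimulatedDataset:
    morph: MorphMatrix
    factors: FactorTable
    occurrences: OccurrenceTable
    manifest: dict


def _streams(spec: SynthSpec) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(spec.seed)
    kids = ss.spawn(3)
    return {"factors": np.random.default_rng(kids[0]),
            "morph": np.random.default_rng(kids[1]),
            "occ": np.random.default_rng(kids[2])}


def _draw_category(rng, spec: SynthSpec, factor: str, block: int) -> str:
    vocab = spec.vocabularies[factor]
    pool = spec.blocks[block].get(factor, ())
    if pool and rng.random() < spec.association_strength:
        return pool[rng.integers(len(pool))]
    return vocab[rng.integers(len(vocab))]


def _factor_assignments(spec: SynthSpec):
    """Latent blocks, primary categories, and final factor cells.

    The primary category per (taxon, factor) is the 'true' single
    membership, before multi-membership and missingness are injected; the
    driver factor's primary categories define the trait-dispersion groups.
    """
    rng = _streams(spec)["factors"]
    n = spec.n_taxa
    blocks = rng.choice(len(spec.blocks), size=n, p=list(spec.block_probs))
    factors = list(spec.vocabularies)
    primary = {f: [] for f in factors}
    cells = np.empty((n, len(factors)), dtype=object)
    for i in range(n):
        for j, f in enumerate(factors):
            cat = _draw_category(rng, spec, f, blocks[i])
            primary[f].append(cat)
            u = rng.random()
            if u < spec.factor_missing_frac:
                cells[i, j] = frozenset()
            elif u < spec.factor_missing_frac + spec.factor_polym_frac:
                vocab = spec.vocabularies[f]
                others = [c for c in vocab if c != cat]
                extra = others[rng.integers(len(others))]
                cells[i, j] = frozenset([cat, extra])
            else:
                cells[i, j] = frozenset([cat])
    return blocks, {f: np.array(v) for f, v in primary.items()}, cells


def gen_factor_table(spec: SynthSpec) -> FactorTable:
    """Factor table with planted block associations, multi-membership at
    ``factor_polym_frac`` and missingness at ``factor_missing_frac``."""
    _, _, cells = _factor_assignments(spec)
    return FactorTable(spec.taxa, {f: tuple(v) for f, v in spec.vocabularies.items()},
                       cells)


def gen_morph_matrix(spec: SynthSpec) -> MorphMatrix:
    """Morphological matrix whose within-group state entropy follows the
    per-category dispersion of the driver factor."""
    rng = _streams(spec)["morph"]
    _, primary, _ = _factor_assignments(spec)
    if spec.group_traits:
        groups_of = primary[spec.driver_factor]
        group_names = list(spec.vocabularies[spec.driver_factor])
    else:
        groups_of = np.array(["__all__"] * spec.n_taxa)
        group_names = ["__all__"]
    defs = spec.characters()
    n, K = spec.n_taxa, len(defs)

    # one shared modal state (or mean) per character, then a per-group
    # dispersion mixture around it
    modal_state = [None if cd.kind == "continuous"
                   else int(rng.integers(len(cd.state_labels))) for cd in defs]
    modal_mean = [rng.uniform(0.25, 0.75) if cd.kind == "continuous" else None
                  for cd in defs]
    cat_probs: dict[tuple[str, int], np.ndarray] = {}
    cont_params: dict[tuple[str, int], tuple[float, float]] = {}
    shift = spec.modal_shift if len(group_names) > 1 else 0.0
    for g in group_names:
        w = min(max(spec.theta(g), 1e-4), 1.0)
        for j, cd in enumerate(defs):
            if cd.kind == "continuous":
                mu = modal_mean[j]
                if rng.random() < shift:
                    mu = rng.uniform(0.25, 0.75)
                cont_params[(g, j)] = (mu, spec.continuous_sd_scale * w)
            else:
                k = len(cd.state_labels)
                mode = modal_state[j]
                if rng.random() < shift:
                    mode = int(rng.integers(k))
                p = np.full(k, w / k)
                p[mode] += 1.0 - w
                cat_probs[(g, j)] = p

    cells = np.empty((n, K), dtype=object)
    for i in range(n):
        g = groups_of[i]
        for j, cd in enumerate(defs):
            if cd.kind == "continuous":
                mu, sd = cont_params[(g, j)]
                value = float(rng.normal(mu, sd))
            else:
                p = cat_probs[(g, j)]
                value = cd.state_labels[rng.choice(len(p), p=p)]
            u = rng.random()
            if u < spec.missing_frac:
                cells[i, j] = frozenset()
            elif u < spec.missing_frac + spec.morph_polym_frac:
                if cd.kind == "continuous":
                    extra = value + float(rng.uniform(0.05, 0.15)) * (
                        1 if rng.random() < 0.5 else -1)
                else:
                    others = [s for s in cd.state_labels if s != value]
                    extra = others[rng.integers(len(others))]
                cells[i, j] = frozenset([value, extra])
            else:
                cells[i, j] = frozenset([value])
    return MorphMatrix(spec.taxa, defs, cells)


def gen_occurrences(spec: SynthSpec) -> OccurrenceTable:
    """Occurrence records with species ranges centred in the latitude band
    of their primary climate category (uniform within the range)."""
    rng = _streams(spec)["occ"]
    _, primary, _ = _factor_assignments(spec)
    climates = primary.get("climate", primary[spec.driver_factor])
    rows = []
    half = spec.lat_range_width / 2.0
    for i, sp in enumerate(spec.taxa):
        lo_band, hi_band = _CLIMATE_BANDS.get(str(climates[i]), (0.0, 60.0))
        center = rng.uniform(lo_band, hi_band)
        center *= -1 if rng.random() < 0.5 else 1
        lo = max(-90.0, center - half)
        hi = min(90.0, center + half)
        lats = rng.uniform(lo, hi, size=spec.records_per_species)
        lons = rng.uniform(-180.0, 180.0, size=spec.records_per_species)
        for lat, lon in zip(lats, lons):
            rows.append((sp, float(lat), float(lon)))
    return OccurrenceTable(pd.DataFrame(rows, columns=["species", "latitude",
                                                       "longitude"]))


def simulate_dataset(spec: SynthSpec) -> SimulatedDataset:
    """All three tables from one spec, plus a manifest of true parameters
    (including per-taxon latent blocks and primary driver categories) for
    recovery tests."""
    blocks, primary, _ = _factor_assignments(spec)
    manifest = {
        "spec": {k: v for k, v in asdict(spec).items()
                 if k not in ("vocabularies", "blocks")},
        "vocabularies": {f: list(v) for f, v in spec.vocabularies.items()},
        "blocks": [{f: list(v) for f, v in b.items()} for b in spec.blocks],
        "latent_block": [int(b) for b in blocks],
        "primary": {f: [str(c) for c in v] for f, v in primary.items()},
    }
    return SimulatedDataset(gen_morph_matrix(spec), gen_factor_table(spec),
                            gen_occurrences(spec), manifest)
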