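"""Input tables for disparity analysis and their on-disk formats.

Three tables drive every analysis in this package:

* a **morphological matrix** — taxa x characters, where each cell holds a
  *state-set*: empty means missing, one element means a monomorphic score,
  more than one means the species is polymorphic for that character;
* a **factor table** — taxa x grouping factors (growth form, habitat,
  climate, region, ...), where a cell holds a *category-set* (a species may
  legitimately belong to several categories of one factor);
* an **occurrence table** — point records (species, latitude, longitude)
  emulating a GBIF export.

On disk all three are plain delimited text with a header row and taxa in the
first column.  Polymorphic cells join states with a separator (default
``"/"``) and missing cells carry a single token (default ``"?"``), following
NEXUS-style conventions.  Character typing lives in a YAML sidecar, one entry
per character with its ``kind`` and, for discrete characters, the ordered
state list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("floradisp")

KINDS = ("binary", "unordered", "ordered", "continuous")

__all__ = [
    "CharacterDefinition",
    "MorphMatrix",
    "FactorTable",
    "OccurrenceTable",
    "read_morph_matrix",
    "read_factor_table",
    "read_occurrences",
    "write_morph_matrix",
    "write_chardefs",
    "write_factor_table",
    "write_occurrences",
]


@dataclass(frozen=True)
class CharacterDefinition:
    """Typing metadata for one morphological character.

    Parameters
    ----------
    character_id : str
        Column name in the morphological matrix.
    kind : {'binary', 'unordered', 'ordered', 'continuous'}
        Measurement scale.  Binary and unordered characters contribute 0/1
        mismatches to the distance; ordered and continuous characters
        contribute range-normalised absolute differences.
    state_labels : tuple of str
        Ordered vocabulary for discrete characters (the order defines ranks
        for ordered characters); empty for continuous characters.
    range_span : float
        Observed span used to normalise ordered/continuous differences:
        max minus min observed rank (ordered) or value (continuous) across
        the whole dataset.  Unused for binary/unordered.  Recomputed from the
        data at load time.
    """

    character_id: str
    kind: str
    state_labels: tuple[str, ...] = ()
    range_span: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(
                f"character {self.character_id!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "binary" and len(self.state_labels) != 2:
            raise ValueError(
                f"binary character {self.character_id!r} must have exactly 2 "
                f"state labels, got {len(self.state_labels)}"
            )
        if self.kind in ("unordered", "ordered") and len(self.state_labels) < 2:
            raise ValueError(
                f"{self.kind} character {self.character_id!r} needs >=2 state labels"
            )
        if self.kind == "continuous" and self.state_labels:
            raise ValueError(
                f"continuous character {self.character_id!r} must not list states"
            )
        if self.range_span < 0:
            raise ValueError(f"character {self.character_id!r}: negative range_span")

    def rank(self, label) -> int:
        """Position of ``label`` in the ordered vocabulary."""
        return self.state_labels.index(str(label))


def _cellset(value) -> frozenset:
    if value is None:
        return frozenset()
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    return frozenset([value])


@dataclass
class MorphMatrix:
    """Taxa x characters matrix of state-sets with per-character typing.

    ``cells`` is an object array of shape (n_taxa, n_characters) whose
    entries are frozensets: empty = missing, singleton = monomorphic,
    larger = polymorphic.  Continuous cells hold floats.
    """

    taxa: list[str]
    characters: list[CharacterDefinition]
    cells: np.ndarray

    def __post_init__(self) -> None:
        if len(self.taxa) == 0 or len(self.characters) == 0:
            raise ValueError("empty morphological matrix")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxa in morphological matrix: {dupes}")
        self.cells = np.asarray(self.cells, dtype=object)
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("cells shape does not match taxa x characters")
        for i in range(self.cells.shape[0]):
            for j in range(self.cells.shape[1]):
                self.cells[i, j] = _cellset(self.cells[i, j])
        self._validate_states()
        self.characters = [
            replace(cd, range_span=span)
            for cd, span in zip(self.characters, self._observed_spans())
        ]

    def _validate_states(self) -> None:
        for j, cd in enumerate(self.characters):
            if cd.kind == "continuous":
                for i, taxon in enumerate(self.taxa):
                    for s in self.cells[i, j]:
                        if not isinstance(s, (int, float, np.floating, np.integer)):
                            raise ValueError(
                                f"taxon {taxon!r}, character {cd.character_id!r}: "
                                f"non-numeric state {s!r} for continuous character"
                            )
                continue
            vocab = set(cd.state_labels)
            for i, taxon in enumerate(self.taxa):
                bad = {str(s) for s in self.cells[i, j]} - vocab
                if bad:
                    raise ValueError(
                        f"taxon {taxon!r}, character {cd.character_id!r}: "
                        f"state(s) {sorted(bad)} not in vocabulary "
                        f"{list(cd.state_labels)}"
                    )

    def _observed_spans(self) -> list[float]:
        spans = []
        for j, cd in enumerate(self.characters):
            if cd.kind in ("binary", "unordered"):
                spans.append(0.0)
                continue
            vals: list[float] = []
            for i in range(len(self.taxa)):
                for s in self.cells[i, j]:
                    vals.append(cd.rank(s) if cd.kind == "ordered" else float(s))
            spans.append(float(max(vals) - min(vals)) if vals else 0.0)
        return spans

    @classmethod
    def from_states(cls, taxa, characters, states) -> "MorphMatrix":
        """Build from an array of scalar states (``None`` marks missing)."""
        arr = np.asarray(states, dtype=object)
        cells = np.empty(arr.shape, dtype=object)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                v = arr[i, j]
                cells[i, j] = frozenset() if v is None else frozenset([v])
        return cls(list(taxa), list(characters), cells)

    # -- summaries -------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def missing_fraction(self) -> float:
        return float(np.mean([len(c) == 0 for c in self.cells.ravel()]))

    def polymorphic_fraction(self) -> float:
        return float(np.mean([len(c) > 1 for c in self.cells.ravel()]))

    def is_polymorphic(self) -> bool:
        return any(len(c) > 1 for c in self.cells.ravel())

    def taxon_index(self, taxon: str) -> int:
        return self.taxa.index(taxon)


@dataclass
class FactorTable:
    """Taxa x factors table of category-sets.

    ``factors`` maps factor name to its ordered category vocabulary;
    ``cells`` is an object array (n_taxa, n_factors) of frozensets of
    category labels, empty = missing, >1 = multi-membership.
    """

    taxa: list[str]
    factors: dict[str, tuple[str, ...]]
    cells: np.ndarray

    def __post_init__(self) -> None:
        if len(self.taxa) == 0 or len(self.factors) == 0:
            raise ValueError("empty factor table")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in factor table")
        self.cells = np.asarray(self.cells, dtype=object)
        if self.cells.shape != (len(self.taxa), len(self.factors)):
            raise ValueError("cells shape does not match taxa x factors")
        for i in range(self.cells.shape[0]):
            for j in range(self.cells.shape[1]):
                self.cells[i, j] = frozenset(str(s) for s in _cellset(self.cells[i, j]))
        for j, (name, vocab) in enumerate(self.factors.items()):
            vocab_set = set(vocab)
            for i, taxon in enumerate(self.taxa):
                bad = self.cells[i, j] - vocab_set
                if bad:
                    raise ValueError(
                        f"taxon {taxon!r}, factor {name!r}: categories "
                        f"{sorted(bad)} not in vocabulary {list(vocab)}"
                    )

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    def column(self, factor: str) -> dict[str, frozenset]:
        """Mapping taxon -> category-set for one factor."""
        j = self.factor_names.index(factor)
        return {t: self.cells[i, j] for i, t in enumerate(self.taxa)}

    def missing_fraction(self) -> float:
        return float(np.mean([len(c) == 0 for c in self.cells.ravel()]))

    def polymorphic_fraction(self) -> float:
        return float(np.mean([len(c) > 1 for c in self.cells.ravel()]))


@dataclass
class OccurrenceTable:
    """Point occurrence records: one row per (species, latitude, longitude)."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "latitude", "longitude"])
    )

    def __post_init__(self) -> None:
        need = {"species", "latitude", "longitude"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"occurrence table needs columns {sorted(need)}")
        lat = self.records["latitude"].to_numpy(float)
        lon = self.records["longitude"].to_numpy(float)
        if len(lat) and (np.abs(lat) > 90).any():
            raise ValueError("latitude out of [-90, 90]")
        if len(lon) and (np.abs(lon) > 180).any():
            raise ValueError("longitude out of [-180, 180]")

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def restrict_to(self, taxa) -> "OccurrenceTable":
        """Drop records whose species is not in ``taxa`` (count logged)."""
        taxa = set(taxa)
        keep = self.records["species"].isin(taxa)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d occurrence records with unmatched species", dropped)
        return OccurrenceTable(self.records[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path, sep):
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str, index_col=0,
                     na_filter=False)
    df.index = df.index.astype(str)
    return df


def read_chardefs(path) -> list[CharacterDefinition]:
    """Read the YAML character-definition sidecar.

    Each entry maps a character id to ``{kind: ..., states: [...]}``;
    ``states`` is omitted for continuous characters.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValueError(f"empty character definition file {path}")
    defs = []
    for cid, entry in raw.items():
        kind = entry["kind"]
        states = tuple(str(s) for s in entry.get("states", ()) or ())
        defs.append(CharacterDefinition(str(cid), kind, states))
    return defs


def read_morph_matrix(matrix_path, chardef_path, *, sep=None, sep_poly="/",
                      na_token="?") -> MorphMatrix:
    """Read a morphological matrix plus its character-definition sidecar.

    Cells are split on ``sep_poly`` into state-sets; ``na_token`` (or an
    empty cell) marks missing data.  Every matrix column must have a
    definition in the sidecar; spans are recomputed from the observed data.
    """
    defs = {d.character_id: d for d in read_chardefs(chardef_path)}
    df = _read_table(matrix_path, sep)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty morphological matrix in {matrix_path}")
    missing_defs = [c for c in df.columns if c not in defs]
    if missing_defs:
        raise ValueError(f"characters without definitions: {missing_defs}")
    characters = [defs[c] for c in df.columns]
    cells = np.empty(df.shape, dtype=object)
    for j, cd in enumerate(characters):
        col = df.iloc[:, j]
        for i, raw in enumerate(col):
            raw = raw.strip()
            if raw == "" or raw == na_token:
                cells[i, j] = frozenset()
                continue
            parts = [p.strip() for p in raw.split(sep_poly)]
            if cd.kind == "continuous":
                try:
                    cells[i, j] = frozenset(float(p) for p in parts)
                except ValueError as exc:
                    raise ValueError(
                        f"taxon {df.index[i]!r}, character {cd.character_id!r}: "
                        f"cannot parse {raw!r} as continuous"
                    ) from exc
            else:
                cells[i, j] = frozenset(parts)
    m = MorphMatrix(list(df.index), characters, cells)
    logger.info(
        "read morphological matrix: %d taxa x %d characters, %.1f%% missing, "
        "%.1f%% polymorphic",
        m.n_taxa, m.n_characters,
        100 * m.missing_fraction(), 100 * m.polymorphic_fraction(),
    )
    return m


def read_factor_table(path, *, sep=None, sep_poly="/", na_token="?") -> FactorTable:
    """Read a taxa x factors table; vocabularies are collected from the data
    in order of first appearance."""
    df = _read_table(path, sep)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty factor table in {path}")
    cells = np.empty(df.shape, dtype=object)
    vocabs: dict[str, list[str]] = {}
    for j, factor in enumerate(df.columns):
        seen: list[str] = []
        any_value = False
        for i, raw in enumerate(df.iloc[:, j]):
            raw = raw.strip()
            if raw == "" or raw == na_token:
                cells[i, j] = frozenset()
                continue
            parts = [p.strip() for p in raw.split(sep_poly)]
            any_value = True
            for p in parts:
                if p not in seen:
                    seen.append(p)
            cells[i, j] = frozenset(parts)
        if not any_value:
            raise ValueError(f"factor column {factor!r} is entirely empty")
        vocabs[factor] = seen
    ft = FactorTable(list(df.index), {f: tuple(v) for f, v in vocabs.items()}, cells)
    logger.info(
        "read factor table: %d taxa x %d factors, %.1f%% missing, "
        "%.1f%% multi-valued",
        len(ft.taxa), len(ft.factors),
        100 * ft.missing_fraction(), 100 * ft.polymorphic_fraction(),
    )
    return ft


def read_occurrences(path, *, sep=None, bbox_filter=None) -> OccurrenceTable:
    """Read species occurrence records.

    ``bbox_filter`` optionally maps species to
    ``(lat_min, lat_max, lon_min, lon_max)`` bounds acting as an automated
    stand-in for native-range curation: records outside a species' box are
    dropped.  Non-numeric coordinates skip the record with a warning;
    out-of-bounds coordinates drop it.
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str, na_filter=False)
    need = {"species", "latitude", "longitude"}
    if not need.issubset(df.columns):
        raise ValueError(f"occurrence file needs columns {sorted(need)}")
    rows = []
    n_bad = n_oob = n_filtered = 0
    for _, rec in df.iterrows():
        try:
            lat = float(rec["latitude"])
            lon = float(rec["longitude"])
        except ValueError:
            n_bad += 1
            continue
        if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
            n_oob += 1
            continue
        sp = str(rec["species"])
        if bbox_filter and sp in bbox_filter:
            lat0, lat1, lon0, lon1 = bbox_filter[sp]
            if not (lat0 <= lat <= lat1 and lon0 <= lon <= lon1):
                n_filtered += 1
                continue
        rows.append((sp, lat, lon))
    if n_bad:
        logger.warning("skipped %d occurrence records with non-numeric coordinates", n_bad)
    if n_oob:
        logger.info("dropped %d out-of-bounds occurrence records", n_oob)
    if n_filtered:
        logger.info("dropped %d occurrence records outside species bounding boxes", n_filtered)
    return OccurrenceTable(pd.DataFrame(rows, columns=["species", "latitude", "longitude"]))


def _format_cell(cellset, cd: CharacterDefinition | None, sep_poly, na_token) -> str:
    if len(cellset) == 0:
        return na_token
    if cd is not None and cd.kind == "continuous":
        return sep_poly.join(repr(float(s)) for s in sorted(cellset))
    return sep_poly.join(sorted(str(s) for s in cellset))


def write_morph_matrix(m: MorphMatrix, path, *, sep=None, sep_poly="/", na_token="?") -> None:
    out = pd.DataFrame(
        [[_format_cell(m.cells[i, j], m.characters[j], sep_poly, na_token)
          for j in range(m.n_characters)] for i in range(m.n_taxa)],
        index=m.taxa, columns=[c.character_id for c in m.characters],
    )
    out.index.name = "taxon"
    out.to_csv(path, sep=_infer_sep(path, sep))


def write_chardefs(characters, path) -> None:
    raw = {}
    for cd in characters:
        entry: dict = {"kind": cd.kind}
        if cd.state_labels:
            entry["states"] = list(cd.state_labels)
        raw[cd.character_id] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_factor_table(ft: FactorTable, path, *, sep=None, sep_poly="/", na_token="?") -> None:
    out = pd.DataFrame(
        [[_format_cell(ft.cells[i, j], None, sep_poly, na_token)
          for j in range(len(ft.factors))] for i in range(len(ft.taxa))],
        index=ft.taxa, columns=ft.factor_names,
    )
    out.index.name = "taxon"
    out.to_csv(path, sep=_infer_sep(path, sep))


def write_occurrences(occ: OccurrenceTable, path, *, sep=None) -> None:
    occ.records.to_csv(path, sep=_infer_sep(path, sep), index=False)
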