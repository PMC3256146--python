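"""Data model and tabular I/O for the paired-pot ¹⁵N labelling experiment.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
with one row per plant per pot per harvest (mixed pots contribute two rows,
one per species). Pots are identified by string ``pot_id``; all pairing is
resolved from the design factors, never from row order.

The experiment crosses two sites (lowland / upland) with fertiliser level,
plant combination (a single Dactylis, or Dactylis + Plantago), ¹⁵N label
(¹⁵NH₄NO₃ vs NH₄¹⁵NO₃) and harvest time (1 d and 14 d after labelling)
within randomised blocks. Each pot is paired with an otherwise identical pot
harvested at the other time (the pool-dilution harvest pair), and each mixed
harvest pair is paired within its block with an isolated harvest pair (the
competition pair used as ANCOVA covariate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

POT_TABLE_COLUMNS = [
    "pot_id", "site", "block", "replicate", "fertiliser", "combination",
    "label", "harvest", "harvest_day", "species", "plant_biomass_g",
    "plant_n_mg", "plant_atom_pct", "soil_nh4_ug_g", "soil_no3_ug_g",
    "soil_pool_atom_pct",
]

TEMPERATURE_COLUMNS = ["location", "date", "t_max_c", "t_min_c"]

SITES = ("lowland", "upland")
FERTILISERS = ("low", "high")
COMBINATIONS = ("isolated", "mixed")
LABELS = ("NH4_labelled", "NO3_labelled")
HARVESTS = ("t1", "t14")
SPECIES = ("Dactylis", "Plantago")

#: Ion whose uptake each label measures: the ¹⁵N-enriched moiety.
LABEL_TO_ION = {"NH4_labelled": "NH4", "NO3_labelled": "NO3"}

_DESIGN_COLS = ["site", "block", "replicate", "fertiliser", "combination", "label"]
_ENUM_DOMAINS = {
    "site": SITES,
    "fertiliser": FERTILISERS,
    "combination": COMBINATIONS,
    "label": LABELS,
    "harvest": HARVESTS,
    "species": SPECIES,
}
# measurement columns: non-negative; atom% additionally bounded by 100
_NONNEG_COLS = ["harvest_day", "plant_biomass_g", "plant_n_mg",
                "plant_atom_pct", "soil_nh4_ug_g", "soil_no3_ug_g",
                "soil_pool_atom_pct"]
_ATOM_PCT_COLS = ["plant_atom_pct", "soil_pool_atom_pct"]


@dataclass(frozen=True)
class PotRecord:
    """One harvested plant-in-pot observation.

    Mirrors a single row of the canonical pot table; missing measurements
    are ``None`` (empty cells in the CSV, never zeros).
    """

    pot_id: str
    site: str
    block: int
    replicate: int
    fertiliser: str
    combination: str
    label: str
    harvest: str
    harvest_day: float
    species: str
    plant_biomass_g: float | None = None
    plant_n_mg: float | None = None
    plant_atom_pct: float | None = None
    soil_nh4_ug_g: float | None = None
    soil_no3_ug_g: float | None = None
    soil_pool_atom_pct: float | None = None


@dataclass(frozen=True)
class HarvestPair:
    """A t₁/t₁₄ pot pair sharing every design factor except harvest."""

    t1_pot_id: str
    t14_pot_id: str


@dataclass(frozen=True)
class CompetitionPair:
    """A mixed harvest pair matched with its block's isolated harvest pair."""

    mixed: HarvestPair
    isolated: HarvestPair


@dataclass
class PairMap:
    """Pairing structures resolved from a validated pot table.

    Attributes
    ----------
    harvest_pairs : dict
        ``(site, block, replicate, fertiliser, combination, label)`` →
        :class:`HarvestPair`.
    competition_pairs : dict
        ``(site, block, replicate, fertiliser, label)`` →
        :class:`CompetitionPair`; present only where both the mixed and the
        isolated harvest pair resolved.
    remainder : list of (pot_id, reason)
        Pots that could not be paired, with the reason; never silently
        dropped.
    """

    harvest_pairs: dict[tuple, HarvestPair] = field(default_factory=dict)
    competition_pairs: dict[tuple, CompetitionPair] = field(default_factory=dict)
    remainder: list[tuple[str, str]] = field(default_factory=list)


def validate_pot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a pot table in place and return it.

    Checks the schema (exact column set), enum domains, numeric ranges
    (non-negative measurements, atom% within [0, 100]) and structural
    invariants (one Dactylis row per isolated pot, exactly one row per
    species in mixed pots, t₁₄ after t₁ within design cells). Raises
    :class:`SchemaError` or :class:`ValidationError` naming field and row.
    """
    missing = [c for c in POT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pot table missing mandatory columns: {missing}")

    problems: list[str] = []
    for col, domain in _ENUM_DOMAINS.items():
        bad = ~df[col].isin(domain)
        for idx in df.index[bad]:
            problems.append(f"row {idx}: {col}={df.at[idx, col]!r} "
                            f"not in {domain}")
    for col in ["block", "replicate"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna() | (vals < 1) | (vals != vals.round())]:
            problems.append(f"row {idx}: {col}={df.at[idx, col]!r} "
                            "must be a positive integer")
    for col in _NONNEG_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_parse = vals.isna() & df[col].notna()
        for idx in df.index[bad_parse]:
            problems.append(f"row {idx}: {col}={df.at[idx, col]!r} not numeric")
        for idx in df.index[vals < 0]:
            problems.append(f"row {idx}: {col}={vals[idx]} must be >= 0")
        if col in _ATOM_PCT_COLS:
            for idx in df.index[vals > 100]:
                problems.append(f"row {idx}: {col}={vals[idx]} exceeds 100 atom%")
    if problems:
        raise ValidationError("pot table validation failed:\n  "
                              + "\n  ".join(problems))

    # structural invariants at pot level
    for pot_id, grp in df.groupby("pot_id", sort=False):
        comb = grp["combination"].iloc[0]
        species = sorted(grp["species"])
        if comb == "isolated" and species != ["Dactylis"]:
            problems.append(f"pot {pot_id}: isolated pot must contain exactly "
                            f"one Dactylis record, found {species}")
        if comb == "mixed" and species != ["Dactylis", "Plantago"]:
            problems.append(f"pot {pot_id}: mixed pot must contain one record "
                            f"per species, found {species}")
        if grp["harvest"].nunique() != 1:
            problems.append(f"pot {pot_id}: inconsistent harvest labels")
    key = _DESIGN_COLS
    days = df.drop_duplicates("pot_id").pivot_table(
        index=key, columns="harvest", values="harvest_day", aggfunc="first")
    if {"t1", "t14"}.issubset(days.columns):
        bad = days["t14"] <= days["t1"]
        for k in days.index[bad.fillna(False)]:
            problems.append(f"design cell {k}: harvest_day(t14) <= harvest_day(t1)")
    if problems:
        raise ValidationError("pot table validation failed:\n  "
                              + "\n  ".join(problems))
    return df


def read_pot_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a pot table CSV; row order is preserved."""
    df = pd.read_csv(path, dtype={"pot_id": str},
                     float_precision="round_trip")
    validate_pot_table(df)
    for col in ["block", "replicate"]:
        df[col] = df[col].astype(int)
    return df


def write_pot_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pot table CSV (columns in canonical order, no index)."""
    df.to_csv(path, index=False, columns=POT_TABLE_COLUMNS)


def iter_records(df: pd.DataFrame) -> Iterable[PotRecord]:
    """Yield rows of a validated pot table as :class:`PotRecord` objects."""
    for row in df.itertuples(index=False):
        d = row._asdict()
        yield PotRecord(**{k: (None if pd.isna(v) else v)
                           for k, v in d.items() if k in PotRecord.__annotations__
                           or k in POT_TABLE_COLUMNS})


def read_temperature_table(path: str | Path) -> pd.DataFrame:
    """Read a daily min/max temperature CSV and check t_max ≥ t_min."""
    df = pd.read_csv(path, parse_dates=["date"],
                     float_precision="round_trip")
    missing = [c for c in TEMPERATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"temperature table missing columns: {missing}")
    bad = df["t_max_c"] < df["t_min_c"]
    if bad.any():
        rows = list(df.index[bad])
        raise ValidationError(f"t_max_c < t_min_c at rows {rows}")
    return df


def write_temperature_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=TEMPERATURE_COLUMNS)


def build_pair_map(df: pd.DataFrame) -> PairMap:
    """Resolve harvest pairs and competition pairs from a validated table.

    Pairing is by design factors only, hence idempotent and invariant to
    input row order. Unpaired pots land in ``remainder`` with a reason; a
    design cell claiming two pots for the same harvest raises
    :class:`IntegrityError`.
    """
    pots = df.drop_duplicates("pot_id")
    pair_map = PairMap()
    claimed: set[str] = set()
    by_cell: dict[tuple, dict[str, str]] = {}
    for row in pots.itertuples(index=False):
        cell = (row.site, int(row.block), int(row.replicate),
                row.fertiliser, row.combination, row.label)
        slot = by_cell.setdefault(cell, {})
        if row.harvest in slot:
            raise IntegrityError(
                f"pots {slot[row.harvest]!r} and {row.pot_id!r} both claim "
                f"harvest {row.harvest} of design cell {cell}")
        slot[row.harvest] = row.pot_id

    for cell, slot in by_cell.items():
        if "t1" in slot and "t14" in slot:
            pair_map.harvest_pairs[cell] = HarvestPair(slot["t1"], slot["t14"])
            claimed.update(slot.values())
        else:
            have = next(iter(slot))
            missing = "t14" if have == "t1" else "t1"
            pair_map.remainder.append(
                (slot[have], f"no {missing} partner in design cell {cell}"))

    for cell, hp in pair_map.harvest_pairs.items():
        site, block, rep, fert, comb, label = cell
        if comb != "mixed":
            continue
        iso_cell = (site, block, rep, fert, "isolated", label)
        iso = pair_map.harvest_pairs.get(iso_cell)
        if iso is not None:
            pair_map.competition_pairs[(site, block, rep, fert, label)] = \
                CompetitionPair(mixed=hp, isolated=iso)
        else:
            pair_map.remainder.append(
                (hp.t1_pot_id,
                 f"mixed pair in cell {cell} has no isolated partner"))
    return pair_map


@dataclass(frozen=True)
class DesignConfig:
    """Factor levels and replication of the paired-pot design.

    Defaults reproduce the study layout: 6 blocks × 2 replicates of the
    full 2 (fertiliser) × 2 (combination) × 2 (label) × 2 (harvest) cross
    at each of two sites — 192 pots per site, 12 per treatment cell.
    """

    sites: tuple[str, ...] = SITES
    fertilisers: tuple[str, ...] = FERTILISERS
    combinations: tuple[str, ...] = COMBINATIONS
    labels: tuple[str, ...] = LABELS
    harvests: tuple[str, ...] = HARVESTS
    blocks: int = 6
    replicates: int = 2
    harvest_days: Mapping[str, float] = field(
        default_factory=lambda: {"t1": 1.0, "t14": 14.0})

    def __post_init__(self) -> None:
        if self.blocks < 1 or self.replicates < 1:
            raise ValidationError("blocks and replicates must be >= 1")

    @property
    def pots_per_site(self) -> int:
        return (len(self.fertilisers) * len(self.combinations)
                * len(self.labels) * len(self.harvests)
                * self.blocks * self.replicates)


def enumerate_design(design: DesignConfig | None = None) -> pd.DataFrame:
    """Build the fully-crossed pot-table skeleton (measurements empty).

    One row per plant per pot: isolated pots carry a single Dactylis row,
    mixed pots a Dactylis and a Plantago row. ``pot_id`` encodes the design
    cell for readability but all downstream pairing uses the factor columns.
    """
    design = design or DesignConfig()
    rows = []
    for site in design.sites:
        for block in range(1, design.blocks + 1):
            for rep in range(1, design.replicates + 1):
                for fert in design.fertilisers:
                    for comb in design.combinations:
                        for label in design.labels:
                            for harvest in design.harvests:
                                pot_id = (f"{site}-b{block}-r{rep}-{fert}-"
                                          f"{comb}-{label}-{harvest}")
                                species_list = (["Dactylis"] if comb == "isolated"
                                                else ["Dactylis", "Plantago"])
                                for sp in species_list:
                                    rows.append({
                                        "pot_id": pot_id, "site": site,
                                        "block": block, "replicate": rep,
                                        "fertiliser": fert, "combination": comb,
                                        "label": label, "harvest": harvest,
                                        "harvest_day":
                                            design.harvest_days[harvest],
                                        "species": sp,
                                    })
    df = pd.DataFrame(rows)
    for col in ["plant_biomass_g", "plant_n_mg", "plant_atom_pct",
                "soil_nh4_ug_g", "soil_no3_ug_g", "soil_pool_atom_pct"]:
        df[col] = np.nan
    return df[POT_TABLE_COLUMNS]
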