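"""Record schema and table I/O for literature-curated nanoparticle cytotoxicity data.

One row of the record table is a single *exposure observation*: one metal-oxide
nanoparticle, characterized by four physicochemical (PChem) attributes each
carrying provenance (where the value came from and how it was measured), four
quantum-mechanical (QM) descriptors of the oxide, the in vitro exposure
conditions (assay, cell descriptors, dose, time) and the measured cell
viability.  The binary endpoint is derived from viability: an observation is
``Toxic`` when viability falls below 50 %, ``Nontoxic`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "PCHEM_ATTRS",
    "QM_ATTRS",
    "SOURCE_LEVELS",
    "METHOD_VOCAB",
    "GOLD_METHODS",
    "CANONICAL_COLUMNS",
    "TOXIC",
    "NONTOXIC",
    "ProvenancedMeasurement",
    "NanoRecord",
    "RecordTable",
    "assign_endpoint",
    "load_records",
    "write_records",
    "summarize_missingness",
]

#: The four physicochemical attributes that carry provenance and are scored.
PCHEM_ATTRS: tuple[str, ...] = ("core_size", "hydro_size", "surface_charge", "surface_area")

#: Canonical units per PChem attribute (fixed by the column dictionary).
PCHEM_UNITS: dict[str, str] = {
    "core_size": "nm",
    "hydro_size": "nm",
    "surface_charge": "mV",
    "surface_area": "m2/g",
}

#: Quantum-mechanical descriptors: enthalpy of formation of a solid-phase metal
#: atom, conduction/valence band energies, and metal-oxide electronegativity.
QM_ATTRS: tuple[str, ...] = ("dHsf_eV", "Ec_eV", "Ev_eV", "chi_eV")

#: Nominal toxicological attributes (cell_name is schema-only, never a feature).
TOX_NOMINAL: tuple[str, ...] = ("assay", "cell_name", "cell_species", "cell_origin", "cell_type")

CELL_TYPES: tuple[str, ...] = ("normal", "cancer")

SOURCE_LEVELS: tuple[str, ...] = ("experimental", "manufacturer", "reference", "absent")

#: Allowed measurement-method labels per PChem attribute.
METHOD_VOCAB: dict[str, tuple[str, ...]] = {
    "core_size": ("TEM", "SEM_AFM", "estimated_from_ssa", "other", "none"),
    "hydro_size": ("DLS_NTA", "other", "none"),
    "surface_charge": ("zeta_potential", "other", "none"),
    "surface_area": ("BET", "estimated_from_core", "other", "none"),
}

#: The widely acknowledged ("gold standard") method per attribute.
GOLD_METHODS: dict[str, str] = {
    "core_size": "TEM",
    "hydro_size": "DLS_NTA",
    "surface_charge": "zeta_potential",
    "surface_area": "BET",
}

TOXIC = "Toxic"
NONTOXIC = "Nontoxic"

#: Canonical CSV header.  An empty string in any cell means "absent".
CANONICAL_COLUMNS: list[str] = [
    "record_id",
    "material_id",
    "composition",
    "core_size", "core_size_source", "core_size_method",
    "hydro_size", "hydro_size_source", "hydro_size_method",
    "surface_charge", "surface_charge_source", "surface_charge_method",
    "surface_area", "surface_area_source", "surface_area_method",
    "dHsf_eV", "Ec_eV", "Ev_eV", "chi_eV",
    "assay", "cell_name", "cell_species", "cell_origin", "cell_type",
    "dose_ug_mL", "time_h", "viability_pct",
]

NUMERIC_COLUMNS: tuple[str, ...] = PCHEM_ATTRS + QM_ATTRS + ("dose_ug_mL", "time_h", "viability_pct")

#: Optional derived columns (quality scores) that a table CSV may carry.
SCORE_COLUMN_NAMES: tuple[str, ...] = (
    "core_size_score", "hydro_size_score", "surface_charge_score",
    "surface_area_score", "pchem_score",
)


def assign_endpoint(viability: float) -> str:
    """Classify one viability reading.

    ``Toxic`` iff viability is strictly below 50 %; exactly 50 % is
    ``Nontoxic``.  Raises ``ValueError`` for non-finite input.
    """
    if viability is None or not math.isfinite(viability):
        raise ValueError(f"viability must be finite, got {viability!r}")
    return TOXIC if viability < 50.0 else NONTOXIC


def _assign_endpoints(viability: pd.Series) -> pd.Series:
    if not np.isfinite(viability.to_numpy(dtype=float)).all():
        bad = viability.index[~np.isfinite(viability.to_numpy(dtype=float))][0]
        raise ValueError(f"non-finite viability at row {bad}")
    return pd.Series(np.where(viability < 50.0, TOXIC, NONTOXIC), index=viability.index)


@dataclass(frozen=True)
class ProvenancedMeasurement:
    """A PChem value together with its data-source level and method label."""

    value: float | None
    source_level: str = "absent"
    method_label: str = "none"

    def __post_init__(self) -> None:
        if self.source_level not in SOURCE_LEVELS:
            raise ValueError(f"unknown source level {self.source_level!r}")
        if (self.value is None) != (self.source_level == "absent"):
            raise ValueError(
                "value is absent exactly when source_level is 'absent' "
                f"(value={self.value!r}, source_level={self.source_level!r})"
            )
        if self.source_level == "absent" and self.method_label != "none":
            raise ValueError("absent measurements must carry method_label 'none'")

    @property
    def is_absent(self) -> bool:
        return self.value is None

    @classmethod
    def absent(cls) -> "ProvenancedMeasurement":
        return cls(None, "absent", "none")


@dataclass(frozen=True)
class NanoRecord:
    """One exposure observation (one row of the record table)."""

    record_id: str
    material_id: str
    composition: str
    core_size: ProvenancedMeasurement
    hydro_size: ProvenancedMeasurement
    surface_charge: ProvenancedMeasurement
    surface_area: ProvenancedMeasurement
    dHsf_eV: float
    Ec_eV: float
    Ev_eV: float
    chi_eV: float
    assay: str
    cell_name: str
    cell_species: str
    cell_origin: str
    cell_type: str
    dose_ug_mL: float
    time_h: float
    viability_pct: float

    def __post_init__(self) -> None:
        for attr in PCHEM_ATTRS:
            meas: ProvenancedMeasurement = getattr(self, attr)
            if not meas.is_absent and meas.method_label not in METHOD_VOCAB[attr]:
                raise ValueError(
                    f"method {meas.method_label!r} not valid for attribute {attr!r}"
                )
        if self.dose_ug_mL < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose_ug_mL}")
        if self.time_h < 0:
            raise ValueError(f"time must be >= 0, got {self.time_h}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")

    @property
    def label(self) -> str:
        return assign_endpoint(self.viability_pct)

    def measurement(self, attr: str) -> ProvenancedMeasurement:
        if attr not in PCHEM_ATTRS:
            raise KeyError(attr)
        return getattr(self, attr)

    def with_measurement(self, attr: str, meas: ProvenancedMeasurement) -> "NanoRecord":
        return replace(self, **{attr: meas})

    @classmethod
    def from_row(cls, row: pd.Series) -> "NanoRecord":
        kwargs: dict = {}
        for attr in PCHEM_ATTRS:
            v = row[attr]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kwargs[attr] = ProvenancedMeasurement.absent()
            else:
                kwargs[attr] = ProvenancedMeasurement(
                    float(v), str(row[f"{attr}_source"]), str(row[f"{attr}_method"])
                )
        for col in ("record_id", "material_id", "composition", *TOX_NOMINAL):
            kwargs[col] = str(row[col])
        for col in QM_ATTRS + ("dose_ug_mL", "time_h", "viability_pct"):
            kwargs[col] = float(row[col])
        return cls(**kwargs)

    def to_row(self) -> dict:
        out: dict = {
            "record_id": self.record_id,
            "material_id": self.material_id,
            "composition": self.composition,
        }
        for attr in PCHEM_ATTRS:
            meas = self.measurement(attr)
            out[attr] = np.nan if meas.is_absent else meas.value
            out[f"{attr}_source"] = meas.source_level
            out[f"{attr}_method"] = meas.method_label
        for col in QM_ATTRS:
            out[col] = getattr(self, col)
        for col in TOX_NOMINAL:
            out[col] = getattr(self, col)
        out["dose_ug_mL"] = self.dose_ug_mL
        out["time_h"] = self.time_h
        out["viability_pct"] = self.viability_pct
        return out


@dataclass
class RecordTable:
    """Ordered collection of exposure records backed by a pandas DataFrame.

    The DataFrame always contains the canonical columns plus a derived
    ``label`` column; extra columns (e.g. per-attribute scores) are carried
    along untouched.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"record table is missing columns: {missing}")
        if self.df["record_id"].duplicated().any():
            dup = self.df.loc[self.df["record_id"].duplicated(), "record_id"].iloc[0]
            raise ValueError(f"duplicate record_id {dup!r}")
        if "label" not in self.df.columns:
            self.df = self.df.assign(label=_assign_endpoints(self.df["viability_pct"]))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[NanoRecord]:
        for _, row in self.df.iterrows():
            yield NanoRecord.from_row(row)

    def copy(self) -> "RecordTable":
        return RecordTable(self.df.copy())

    def validate(self) -> None:
        """Check enum vocabularies, value/provenance coupling and the label rule."""
        df = self.df
        for attr in PCHEM_ATTRS:
            absent = df[attr].isna()
            src, meth = df[f"{attr}_source"], df[f"{attr}_method"]
            bad = ~src.isin(SOURCE_LEVELS)
            if bad.any():
                raise ValueError(
                    f"unknown source level {src[bad].iloc[0]!r} in column {attr}_source"
                )
            bad = ~meth.isin(METHOD_VOCAB[attr])
            if bad.any():
                raise ValueError(
                    f"unknown method {meth[bad].iloc[0]!r} in column {attr}_method"
                )
            if ((src == "absent") != absent).any():
                raise ValueError(f"{attr}: value absent iff source_level 'absent' violated")
            if (absent & (meth != "none")).any():
                raise ValueError(f"{attr}: absent value must have method 'none'")
        if (df["dose_ug_mL"] < 0).any():
            raise ValueError("negative dose")
        if (df["time_h"] < 0).any():
            raise ValueError("negative exposure time")
        expected = _assign_endpoints(df["viability_pct"])
        if (df["label"] != expected).any():
            raise ValueError("label column inconsistent with the 50% viability rule")


def load_records(path: str | Path) -> RecordTable:
    """Read a record table from its canonical CSV form.

    Empty cells in the PChem value columns become absent measurements; empty
    provenance cells default to ``absent``/``none``.  Malformed numeric cells
    and unknown enum tokens are rejected with row and column context.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    score_cols = [c for c in raw.columns if c in SCORE_COLUMN_NAMES]
    unknown = [c for c in raw.columns if c not in CANONICAL_COLUMNS and c not in SCORE_COLUMN_NAMES]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")

    def _parse_cell(s: str) -> float:
        try:
            return float(s) if s else np.nan
        except ValueError:
            return np.nan  # flagged below with row/column context

    df = raw.copy()
    for col in list(NUMERIC_COLUMNS) + score_cols:
        cells = raw[col].str.strip()
        # float() is correctly rounded, so a %.17g write/load round trip is exact
        parsed = pd.Series([_parse_cell(s) for s in cells], index=cells.index, dtype=float)
        bad = parsed.isna() & (cells != "") & (cells.str.lower() != "nan")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {cells.iloc[i]!r} in column {col!r}, row {i + 2}"
            )
        if col not in PCHEM_ATTRS and col not in QM_ATTRS and col not in score_cols and parsed.isna().any():
            i = int(np.flatnonzero(parsed.isna())[0])
            raise ValueError(f"{path}: missing value in required column {col!r}, row {i + 2}")
        df[col] = parsed
    for attr in PCHEM_ATTRS:
        absent = df[attr].isna()
        df.loc[absent, f"{attr}_source"] = "absent"
        df.loc[absent, f"{attr}_method"] = "none"
        df[f"{attr}_source"] = df[f"{attr}_source"].replace("", "absent")
        df[f"{attr}_method"] = df[f"{attr}_method"].replace("", "none")
    table = RecordTable(df)
    table.validate()
    return table


def write_records(table: RecordTable, path: str | Path) -> None:
    """Write the canonical columns (plus any score columns) to CSV.

    The derived ``label`` column is not written; it is recomputed on load
    from viability, so a write/load round trip is exact.
    """
    cols = [c for c in table.df.columns if c != "label"]
    # %.17g keeps the text form round-trippable to the exact float64
    table.df[cols].to_csv(path, index=False, float_format="%.17g")


def summarize_missingness(table: RecordTable) -> dict[str, float]:
    """Fraction of absent values per PChem attribute (0 to 1)."""
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    return {attr: float(table.df[attr].isna().mean()) for attr in PCHEM_ATTRS}
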