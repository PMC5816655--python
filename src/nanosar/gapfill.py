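"""Rule-based filling of missing PChem and QM values.

Missing PChem values are replaced in priority order: (1) the manufacturer's
characterization data for the same brand/product number, (2) a value reused
from another publication on the same material, (3) estimation between core
size and specific surface area through the sphere relation

    SSA = 6 / (d * rho)

which, with d in nm and rho in g/cm^3, yields SSA in m^2/g as 6000 / (d * rho).
Missing QM descriptors are filled from a per-composition lookup table.
Records that still contain gaps after these rules are excluded when building
the fully-filled dataset (``build_dataset_ii``).  The mean-substitution path
used for the unfilled dataset replaces absent values by the attribute mean of
a statistics source (normally the training partition) without touching
provenance, so quality scores are unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import PCHEM_ATTRS, QM_ATTRS, NanoRecord, ProvenancedMeasurement, RecordTable
from .scoring import score_table

__all__ = [
    "ManufacturerCatalog",
    "ReferenceCatalog",
    "DensityTable",
    "QMTable",
    "FillAction",
    "estimate_ssa_from_core",
    "estimate_core_from_ssa",
    "fill_record",
    "fill_table",
    "build_dataset_ii",
    "mean_substitute",
]

#: nm * g/cm^3 -> m^2/g unit factor for the sphere SSA relation.
_SSA_FACTOR = 6000.0

#: below this core diameter, per-composition QM constants become unreliable
_QM_SIZE_WARN_NM = 5.0


def estimate_ssa_from_core(d: float, rho: float) -> float:
    """Specific surface area (m^2/g) of a dense sphere of diameter d (nm)."""
    if not d > 0:
        raise ValueError(f"core diameter must be positive, got {d}")
    if not rho > 0:
        raise ValueError(f"density must be positive, got {rho}")
    return _SSA_FACTOR / (d * rho)


def estimate_core_from_ssa(ssa: float, rho: float) -> float:
    """Core diameter (nm) of a dense sphere with the given SSA (m^2/g)."""
    if not ssa > 0:
        raise ValueError(f"surface area must be positive, got {ssa}")
    if not rho > 0:
        raise ValueError(f"density must be positive, got {rho}")
    return _SSA_FACTOR / (ssa * rho)


class _Catalog:
    """Lookup from (material_id, attribute) to a value with an optional method."""

    def __init__(self, entries: dict[tuple[str, str], tuple[float, str | None]] | None = None):
        self._entries = dict(entries or {})

    def add(self, material_id: str, attribute: str, value: float, method: str | None = None) -> None:
        if attribute not in PCHEM_ATTRS:
            raise ValueError(f"unknown attribute {attribute!r}")
        self._entries[(material_id, attribute)] = (float(value), method or None)

    def lookup(self, material_id: str, attribute: str) -> tuple[float, str | None] | None:
        return self._entries.get((material_id, attribute))

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_csv(cls, path: str | Path):
        df = pd.read_csv(path, dtype={"material_id": str, "attribute": str})
        cat = cls()
        for _, row in df.iterrows():
            method = row.get("method")
            if isinstance(method, float) and np.isnan(method):
                method = None
            cat.add(row["material_id"], row["attribute"], float(row["value"]), method)
        return cat

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"material_id": m, "attribute": a, "value": v, "method": meth or ""}
            for (m, a), (v, meth) in sorted(self._entries.items())
        ]
        pd.DataFrame(rows, columns=["material_id", "attribute", "value", "method"]).to_csv(
            path, index=False
        )


class ManufacturerCatalog(_Catalog):
    """Manufacturer characterization data keyed by brand/product identifier."""


class ReferenceCatalog(_Catalog):
    """Values reused from other publications on the same material."""


class DensityTable:
    """Bulk density (g/cm^3) per oxide composition, used by the SSA estimator."""

    def __init__(self, densities: dict[str, float]):
        for comp, rho in densities.items():
            if not rho > 0:
                raise ValueError(f"density for {comp!r} must be positive, got {rho}")
        self._rho = dict(densities)

    def get(self, composition: str) -> float | None:
        return self._rho.get(composition)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DensityTable":
        df = pd.read_csv(path, dtype={"composition": str})
        return cls(dict(zip(df["composition"], df["rho_g_cm3"].astype(float))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self._rho.items()), columns=["composition", "rho_g_cm3"]
        ).to_csv(path, index=False)


class QMTable:
    """Per-composition quantum-mechanical descriptor constants."""

    def __init__(self, values: dict[str, dict[str, float]]):
        for comp, row in values.items():
            missing = [a for a in QM_ATTRS if a not in row]
            if missing:
                raise ValueError(f"QM entry for {comp!r} missing {missing}")
            if not row["Ev_eV"] < row["Ec_eV"]:
                raise ValueError(f"QM entry for {comp!r} must have Ev < Ec")
        self._values = {c: {a: float(r[a]) for a in QM_ATTRS} for c, r in values.items()}

    def get(self, composition: str) -> dict[str, float] | None:
        return self._values.get(composition)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QMTable":
        df = pd.read_csv(path, dtype={"composition": str})
        return cls({row["composition"]: {a: row[a] for a in QM_ATTRS} for _, row in df.iterrows()})

    def to_csv(self, path: str | Path) -> None:
        rows = [{"composition": c, **v} for c, v in sorted(self._values.items())]
        pd.DataFrame(rows, columns=["composition", *QM_ATTRS]).to_csv(path, index=False)


@dataclass(frozen=True)
class FillAction:
    """One change (or flagged failure) made by the gap-filling rules."""

    record_id: str
    attribute: str
    action: str  # manufacturer | reference | estimated_from_core | estimated_from_ssa | qm_table | unfilled
    new_value: float | None = None
    new_source: str | None = None
    new_method: str | None = None

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "attribute": self.attribute,
            "action": self.action,
            "new_value": self.new_value,
            "new_source": self.new_source,
            "new_method": self.new_method,
        }


def _catalog_method(attribute: str, stated: str | None) -> str:
    # catalog entries without a stated method count as a non-standard method
    from .records import METHOD_VOCAB

    if stated and stated in METHOD_VOCAB[attribute]:
        return stated
    return "other"


def _fill_from_catalogs(
    record: NanoRecord,
    attr: str,
    mfr: ManufacturerCatalog,
    ref: ReferenceCatalog,
    actions: list[FillAction],
) -> NanoRecord:
    for catalog, level in ((mfr, "manufacturer"), (ref, "reference")):
        hit = catalog.lookup(record.material_id, attr)
        if hit is not None:
            value, stated = hit
            meas = ProvenancedMeasurement(value, level, _catalog_method(attr, stated))
            actions.append(
                FillAction(record.record_id, attr, level, value, level, meas.method_label)
            )
            return record.with_measurement(attr, meas)
    return record


def fill_record(
    record: NanoRecord,
    mfr: ManufacturerCatalog,
    ref: ReferenceCatalog,
    dens: DensityTable,
    qm: QMTable,
) -> tuple[NanoRecord, list[FillAction]]:
    """Fill the gaps of a single record; return the new record and a report.

    Catalog lookups take priority over estimation; an estimated value keeps
    the source level of the value it was derived from and is labelled
    ``estimated_from_core`` / ``estimated_from_ssa`` (method score 1).
    Unfillable attributes stay absent and are flagged in the report.
    """
    actions: list[FillAction] = []
    for attr in PCHEM_ATTRS:
        if record.measurement(attr).is_absent:
            record = _fill_from_catalogs(record, attr, mfr, ref, actions)

    rho = dens.get(record.composition)
    if rho is not None:
        core, ssa = record.core_size, record.surface_area
        if core.is_absent and not ssa.is_absent:
            d = estimate_core_from_ssa(ssa.value, rho)
            meas = ProvenancedMeasurement(d, ssa.source_level, "estimated_from_ssa")
            record = record.with_measurement("core_size", meas)
            actions.append(
                FillAction(record.record_id, "core_size", "estimated_from_ssa",
                           d, ssa.source_level, "estimated_from_ssa")
            )
        core, ssa = record.core_size, record.surface_area
        if ssa.is_absent and not core.is_absent:
            v = estimate_ssa_from_core(core.value, rho)
            meas = ProvenancedMeasurement(v, core.source_level, "estimated_from_core")
            record = record.with_measurement("surface_area", meas)
            actions.append(
                FillAction(record.record_id, "surface_area", "estimated_from_core",
                           v, core.source_level, "estimated_from_core")
            )

    qm_row = qm.get(record.composition)
    for attr in QM_ATTRS:
        if np.isnan(getattr(record, attr)):
            if qm_row is None:
                actions.append(FillAction(record.record_id, attr, "unfilled"))
                continue
            if not record.core_size.is_absent and record.core_size.value < _QM_SIZE_WARN_NM:
                warnings.warn(
                    f"record {record.record_id}: QM constants applied to a "
                    f"{record.core_size.value:.1f} nm particle; size-dependent "
                    "deviations are expected below 5 nm",
                    stacklevel=2,
                )
            record = replace(record, **{attr: qm_row[attr]})
            actions.append(FillAction(record.record_id, attr, "qm_table", qm_row[attr]))

    for attr in PCHEM_ATTRS:
        if record.measurement(attr).is_absent:
            actions.append(FillAction(record.record_id, attr, "unfilled"))
    return record, actions


def fill_table(
    table: RecordTable,
    mfr: ManufacturerCatalog,
    ref: ReferenceCatalog,
    dens: DensityTable,
    qm: QMTable,
) -> tuple[RecordTable, list[FillAction]]:
    """Apply ``fill_record`` to every record; keeps rows that remain gappy."""
    report: list[FillAction] = []
    filled_rows: list[dict] = []
    for record in table:
        filled, actions = fill_record(record, mfr, ref, dens, qm)
        filled_rows.append(filled.to_row())
        report.extend(actions)
    df = pd.DataFrame(filled_rows)
    # carry non-canonical extras (e.g. stale score columns are recomputed later)
    df = df.reindex(columns=[c for c in table.df.columns if c in df.columns])
    return RecordTable(df), report


def build_dataset_ii(
    table: RecordTable,
    mfr: ManufacturerCatalog,
    ref: ReferenceCatalog,
    dens: DensityTable,
    qm: QMTable,
) -> tuple[RecordTable, list[FillAction]]:
    """Gap-fill every record, drop rows that could not be completed, rescore.

    The result has no absent PChem or QM value; quality scores are recomputed
    after filling, so filled attributes move from score 0 to their catalog or
    estimation level.
    """
    filled, report = fill_table(table, mfr, ref, dens, qm)
    df = filled.df
    complete = ~df[list(PCHEM_ATTRS)].isna().any(axis=1) & ~df[list(QM_ATTRS)].isna().any(axis=1)
    if not complete.any():
        raise ValueError("gap filling left no complete records")
    return score_table(RecordTable(df[complete].copy())), report


def mean_substitute(table: RecordTable, stats_source: RecordTable) -> RecordTable:
    """Replace absent PChem values by attribute means of ``stats_source``.

    Provenance columns are untouched, so the quality scores of imputed rows
    do not change.  Means are computed over present values only; an attribute
    that needs imputation but has no present value in the source is an error.
    """
    df = table.df.copy()
    for attr in PCHEM_ATTRS:
        absent = df[attr].isna()
        if not absent.any():
            continue
        present = stats_source.df[attr].dropna()
        if present.empty:
            raise ValueError(f"no present {attr!r} values to compute a substitution mean")
        df.loc[absent, attr] = float(present.mean())
    return RecordTable(df)
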