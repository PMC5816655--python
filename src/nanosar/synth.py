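"""Synthetic literature-style nanotoxicity datasets.

The generator emulates the structure of a literature-curated cytotoxicity
compilation for metal-oxide nanoparticles: a closed vocabulary of oxide
compositions, materials (brand/product lots) with true physicochemical
properties, and per-row exposure observations (assay, cell line descriptors,
dose, exposure time, viability).  The pieces that matter to the downstream
pipeline are reproduced explicitly:

* per-attribute missingness of the four PChem attributes, missing completely
  at random at the literature-profile rates (defaults 18 / 39 / 41 / 74 % for
  core size, hydrodynamic size, surface charge and specific surface area);
* a provenance mix: for each material and attribute the value is either
  measured by the authors, taken from the manufacturer's specification,
  reused from another publication, or unrecoverable when missing — and the
  observation noise grows from experimental to manufacturer to reference
  sources, which is exactly what makes quality screening informative;
* manufacturer and reference catalogs populated for the recoverable strata,
  plus density and QM lookup tables, so the gap-filling rules can be
  exercised end to end;
* a log-logistic (Hill) dose-response for viability whose EC50 depends on
  composition, core size and exposure time, with the composition-level field
  shifted deterministically so the realized toxic fraction matches the
  configured target;
* a truth table holding the noiseless values and labels.

All randomness flows from one integer seed; the same configuration always
produces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .gapfill import (
    DensityTable,
    ManufacturerCatalog,
    QMTable,
    ReferenceCatalog,
    estimate_ssa_from_core,
)
from .records import GOLD_METHODS, PCHEM_ATTRS, QM_ATTRS, RecordTable

__all__ = ["SyntheticConfig", "GeneratedData", "viability_model", "generate_dataset", "DEFAULT_OXIDES"]

#: 26 metal oxides with their bulk densities (g/cm^3).
DEFAULT_OXIDES: dict[str, float] = {
    "TiO2": 4.23, "ZnO": 5.61, "SiO2": 2.65, "CuO": 6.31, "Fe2O3": 5.24,
    "Fe3O4": 5.17, "Al2O3": 3.95, "CeO2": 7.22, "ZrO2": 5.68, "NiO": 6.67,
    "MgO": 3.58, "SnO2": 6.95, "Co3O4": 6.11, "Mn2O3": 4.50, "Cr2O3": 5.22,
    "La2O3": 6.51, "Y2O3": 5.01, "Sb2O3": 5.20, "WO3": 7.16, "V2O5": 3.36,
    "CoO": 6.44, "Ni2O3": 4.84, "Gd2O3": 7.41, "HfO2": 9.68, "In2O3": 7.18,
    "Yb2O3": 9.17,
}

_ASSAYS = ("MTT", "WST", "LDH", "CCK8", "NRU")
_SPECIES = ("human", "mouse", "rat")
_ORIGINS = ("lung", "liver", "skin", "kidney", "blood", "brain")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic literature compilation.

    Noise scales are log-scale standard deviations of multiplicative
    observation error (additive in mV for surface charge, scaled by 25 mV);
    they increase from experimental to reference sources because values
    measured in the reporting lab track the tested suspension far better
    than specifications or values borrowed from other publications.
    """

    n_records: int = 6842
    n_materials: int = 120
    compositions: tuple[str, ...] = tuple(DEFAULT_OXIDES)
    missingness: dict[str, float] = field(default_factory=lambda: {
        "core_size": 0.18, "hydro_size": 0.39, "surface_charge": 0.41, "surface_area": 0.74,
    })
    provenance_mix: dict[str, float] = field(default_factory=lambda: {
        "experimental": 0.40, "manufacturer": 0.25, "reference": 0.25, "unfillable": 0.10,
    })
    noise_sd_by_provenance: dict[str, float] = field(default_factory=lambda: {
        "experimental": 0.02, "manufacturer": 0.6, "reference": 1.2,
    })
    dose_grid: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 100.0, 200.0)
    time_grid: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0, 48.0, 72.0)
    comp_log10_ec50_sd: float = 0.05
    material_log10_ec50_sd: float = 0.05
    size_coef: float = 3.0     # decades of EC50 per decade of core size (small = toxic)
    time_coef: float = -0.2    # decades of EC50 per decade of exposure time
    hill: float = 4.0
    viability_noise_sd: float = 2.0
    toxic_target_fraction: float = 0.15
    gold_method_prob: float = 0.8
    catalog_method_prob: float = 0.3
    method_noise_factor: float = 2.0
    seed: int = 42

    def validate(self) -> None:
        if self.n_records < 1 or self.n_materials < 1:
            raise ValueError("n_records and n_materials must be positive")
        if not self.compositions:
            raise ValueError("compositions must be non-empty")
        for attr in PCHEM_ATTRS:
            r = self.missingness.get(attr)
            if r is None or not (0.0 <= r <= 1.0):
                raise ValueError(f"missingness[{attr!r}] must be in [0, 1]")
        mix = self.provenance_mix
        if set(mix) != {"experimental", "manufacturer", "reference", "unfillable"}:
            raise ValueError("provenance_mix must cover the four strata")
        if any(p < 0 for p in mix.values()) or not np.isclose(sum(mix.values()), 1.0):
            raise ValueError("provenance_mix must be a probability distribution")
        if any(sd < 0 for sd in self.noise_sd_by_provenance.values()):
            raise ValueError("noise scales must be non-negative")
        if not self.dose_grid or not self.time_grid:
            raise ValueError("dose and time grids must be non-empty")
        if any(d <= 0 for d in self.dose_grid):
            raise ValueError("dose grid values must be positive")
        if not self.hill > 0:
            raise ValueError("hill slope must be positive")
        if not (0.0 < self.toxic_target_fraction < 1.0):
            raise ValueError("toxic_target_fraction must be in (0, 1)")


class GeneratedData(NamedTuple):
    records: RecordTable
    manufacturer: ManufacturerCatalog
    reference: ReferenceCatalog
    density: DensityTable
    qm: QMTable
    truth: pd.DataFrame


def viability_model(dose: float, ec50: float, hill: float) -> float:
    """Noiseless log-logistic viability (%): 100 / (1 + (dose/ec50)^hill)."""
    if not ec50 > 0:
        raise ValueError(f"ec50 must be positive, got {ec50}")
    if not hill > 0:
        raise ValueError(f"hill slope must be positive, got {hill}")
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    return 100.0 / (1.0 + (dose / ec50) ** hill)


def _make_qm_table(rng: np.random.Generator, compositions: tuple[str, ...]) -> QMTable:
    vals: dict[str, dict[str, float]] = {}
    for comp in compositions:
        ec = float(np.round(rng.uniform(-6.6, -0.1), 2))
        vals[comp] = {
            "dHsf_eV": float(np.round(rng.uniform(-65.0, -1.0), 1)),
            "Ec_eV": ec,
            "Ev_eV": float(np.round(ec - rng.uniform(1.0, 6.0), 2)),
            "chi_eV": float(np.round(rng.uniform(3.2, 8.3), 2)),
        }
    return QMTable(vals)


def _noisy(rng: np.random.Generator, attr: str, true: float, sd: float) -> float:
    # multiplicative error for strictly positive attributes, additive for charge
    if attr == "surface_charge":
        return true + rng.normal(0.0, sd * 25.0)
    return true * float(np.exp(rng.normal(0.0, sd)))


def generate_dataset(config: SyntheticConfig | None = None) -> GeneratedData:
    """Generate a record table, catalogs, lookup tables and the ground truth."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    compositions = tuple(config.compositions)
    density = DensityTable({c: DEFAULT_OXIDES.get(c, 5.0) for c in compositions})
    qm = _make_qm_table(rng, compositions)

    # --- materials: true properties -------------------------------------
    n_mat = config.n_materials
    mat_comp = rng.choice(compositions, size=n_mat)
    core = np.exp(rng.normal(np.log(30.0), 0.6, size=n_mat)).clip(3.0, 400.0)
    rho = np.array([density.get(c) for c in mat_comp])
    ssa = np.array([estimate_ssa_from_core(d, r) for d, r in zip(core, rho)])
    charge = rng.normal(0.0, 30.0, size=n_mat).clip(-65.0, 65.0)
    hydro = core * (1.0 + rng.lognormal(0.0, 0.75, size=n_mat))
    comp_mu = {c: rng.normal(0.0, config.comp_log10_ec50_sd) for c in compositions}
    mat_log_ec50 = np.array([
        comp_mu[c] + config.size_coef * np.log10(d / 30.0) + rng.normal(0.0, config.material_log10_ec50_sd)
        for c, d in zip(mat_comp, core)
    ])
    mat_truth = {attr: arr for attr, arr in zip(
        PCHEM_ATTRS, (core, hydro, charge, ssa)
    )}

    # provenance stratum per material x attribute
    strata = {
        attr: rng.choice(
            ("experimental", "manufacturer", "reference", "unfillable"),
            size=n_mat,
            p=[config.provenance_mix[k] for k in ("experimental", "manufacturer", "reference", "unfillable")],
        )
        for attr in PCHEM_ATTRS
    }

    # --- catalogs for the recoverable strata ----------------------------
    mfr, ref = ManufacturerCatalog(), ReferenceCatalog()
    mat_ids = [f"MAT{i:04d}" for i in range(n_mat)]
    for attr in PCHEM_ATTRS:
        for i in range(n_mat):
            stratum = strata[attr][i]
            if stratum not in ("manufacturer", "reference"):
                continue
            sd = config.noise_sd_by_provenance[stratum]
            stated = GOLD_METHODS[attr] if rng.random() < config.catalog_method_prob else None
            if stated is None:
                sd *= config.method_noise_factor
            value = _noisy(rng, attr, mat_truth[attr][i], sd)
            (mfr if stratum == "manufacturer" else ref).add(mat_ids[i], attr, value, stated)

    # --- per-record exposures -------------------------------------------
    n = config.n_records
    mi = rng.integers(0, n_mat, size=n)
    dose = rng.choice(np.asarray(config.dose_grid, dtype=float), size=n)
    time = rng.choice(np.asarray(config.time_grid, dtype=float), size=n)
    assay = rng.choice(_ASSAYS, size=n)
    species = rng.choice(_SPECIES, size=n)
    origin = rng.choice(_ORIGINS, size=n)
    cell_type = rng.choice(("normal", "cancer"), size=n, p=[0.6, 0.4])
    cell_name = np.array([f"LINE{k:02d}" for k in rng.integers(0, 60, size=n)])

    log_ec50 = mat_log_ec50[mi] + config.time_coef * np.log10(time / 24.0)
    # calibrate the EC50 field so that the noiseless toxic fraction (viability
    # < 50 iff dose > EC50 under the Hill model) hits the configured target
    margin = np.log10(dose) - log_ec50
    shift = float(np.quantile(margin, 1.0 - config.toxic_target_fraction))
    log_ec50 = log_ec50 + shift
    ec50 = 10.0 ** log_ec50
    viability_true = 100.0 / (1.0 + (dose / ec50) ** config.hill)
    viability_obs = viability_true + rng.normal(0.0, config.viability_noise_sd, size=n)

    # --- observed PChem values with provenance, missingness, noise -------
    obs: dict[str, np.ndarray] = {}
    src_col: dict[str, np.ndarray] = {}
    meth_col: dict[str, np.ndarray] = {}
    for attr in PCHEM_ATTRS:
        truth_vals = mat_truth[attr][mi]
        stratum = strata[attr][mi]
        missing = rng.random(n) < config.missingness[attr]
        values = np.full(n, np.nan)
        sources = np.full(n, "absent", dtype=object)
        methods = np.full(n, "none", dtype=object)
        gold = GOLD_METHODS[attr]
        alt = "SEM_AFM" if attr == "core_size" else "other"
        for i in range(n):
            if missing[i]:
                continue
            st = stratum[i]
            if st in ("experimental", "unfillable"):
                sd = config.noise_sd_by_provenance["experimental"]
                sources[i] = "experimental"
                methods[i] = gold if rng.random() < config.gold_method_prob else alt
            else:
                sd = config.noise_sd_by_provenance[st]
                sources[i] = st
                methods[i] = gold if rng.random() < config.catalog_method_prob else "other"
            if methods[i] != gold:
                # less common techniques carry larger measurement error
                sd *= config.method_noise_factor
            values[i] = _noisy(rng, attr, truth_vals[i], sd)
        obs[attr], src_col[attr], meth_col[attr] = values, sources, methods

    record_ids = [f"R{i:06d}" for i in range(n)]
    df = pd.DataFrame({
        "record_id": record_ids,
        "material_id": [mat_ids[i] for i in mi],
        "composition": [mat_comp[i] for i in mi],
    })
    for attr in PCHEM_ATTRS:
        df[attr] = obs[attr]
        df[f"{attr}_source"] = src_col[attr]
        df[f"{attr}_method"] = meth_col[attr]
    qm_rows = pd.DataFrame([qm.get(c) for c in df["composition"]])
    for a in QM_ATTRS:
        df[a] = qm_rows[a].to_numpy()
    df["assay"] = assay
    df["cell_name"] = cell_name
    df["cell_species"] = species
    df["cell_origin"] = origin
    df["cell_type"] = cell_type
    df["dose_ug_mL"] = dose
    df["time_h"] = time
    df["viability_pct"] = viability_obs

    truth = pd.DataFrame({
        "record_id": record_ids,
        "material_id": df["material_id"],
        "composition": df["composition"],
        **{f"true_{attr}": mat_truth[attr][mi] for attr in PCHEM_ATTRS},
        "ec50_ug_mL": ec50,
        "viability_true_pct": viability_true,
        "true_label": np.where(viability_true < 50.0, "Toxic", "Nontoxic"),
    })

    return GeneratedData(RecordTable(df), mfr, ref, density, qm, truth)
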