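"""Gap filling: sphere SSA relation, catalogs, priorities, mean substitution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosar.gapfill import (
    DensityTable,
    ManufacturerCatalog,
    QMTable,
    ReferenceCatalog,
    build_dataset_ii,
    estimate_core_from_ssa,
    estimate_ssa_from_core,
    fill_record,
    mean_substitute,
)
from nanosar.records import PCHEM_ATTRS, ProvenancedMeasurement, RecordTable
from nanosar.scoring import score_table
from tests.test_scoring import _record


def _si_oracle_ssa(d_nm: float, rho_g_cm3: float) -> float:
    """Independent SI-unit evaluation: convert to m and kg/m^3, apply the
    sphere relation SSA = 6/(d rho), convert m^2/kg to m^2/g."""
    d_m = d_nm * 1e-9
    rho_kg_m3 = rho_g_cm3 * 1000.0
    return (6.0 / (d_m * rho_kg_m3)) / 1000.0


@pytest.mark.parametrize("d,rho", [(60.0, 1.0), (21.0, 4.23), (5.0, 7.0), (300.0, 2.65)])
def test_ssa_estimator_matches_si_oracle(d, rho):
    assert estimate_ssa_from_core(d, rho) == pytest.approx(_si_oracle_ssa(d, rho), rel=1e-12)


def test_ssa_reference_values():
    assert estimate_ssa_from_core(60.0, 1.0) == pytest.approx(100.0)
    assert estimate_ssa_from_core(21.0, 4.23) == pytest.approx(67.55, abs=0.05)
    assert estimate_core_from_ssa(100.0, 1.0) == pytest.approx(60.0)
    assert estimate_core_from_ssa(6000.0, 1.0) == pytest.approx(1.0)


@settings(max_examples=200, deadline=None)
@given(
    d=st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
    rho=st.floats(min_value=0.1, max_value=25.0, allow_nan=False),
)
def test_ssa_core_roundtrip_identity(d, rho):
    assert estimate_core_from_ssa(estimate_ssa_from_core(d, rho), rho) == pytest.approx(d, rel=1e-12)


@pytest.mark.parametrize("fn", [estimate_ssa_from_core, estimate_core_from_ssa])
@pytest.mark.parametrize("x,rho", [(0.0, 1.0), (-5.0, 1.0), (10.0, 0.0), (10.0, -1.0)])
def test_estimators_reject_nonpositive(fn, x, rho):
    with pytest.raises(ValueError):
        fn(x, rho)


@pytest.fixture()
def lookups():
    mfr = ManufacturerCatalog()
    mfr.add("M1", "core_size", 25.0, "TEM")
    ref = ReferenceCatalog()
    ref.add("M1", "core_size", 30.0)
    ref.add("M1", "hydro_size", 140.0)
    dens = DensityTable({"TiO2": 1.0})
    qm = QMTable({"TiO2": {"dHsf_eV": -10.0, "Ec_eV": -4.0, "Ev_eV": -8.0, "chi_eV": 5.5}})
    return mfr, ref, dens, qm


def test_manufacturer_fill_and_priority_over_reference(lookups):
    """A manufacturer entry wins over a reference entry for the same gap."""
    rec = _record()
    filled, actions = fill_record(rec, *lookups)
    assert filled.core_size.value == 25.0
    assert filled.core_size.source_level == "manufacturer"
    assert filled.core_size.method_label == "TEM"
    assert filled.hydro_size.value == 140.0
    assert filled.hydro_size.source_level == "reference"
    assert {"manufacturer", "reference"} <= {a.action for a in actions}


def test_estimation_from_core_size(lookups):
    rec = _record(core_size=ProvenancedMeasurement(60.0, "experimental", "TEM"))
    mfr, ref, dens, qm = lookups
    filled, actions = fill_record(rec, ManufacturerCatalog(), ReferenceCatalog(), dens, qm)
    assert filled.surface_area.value == pytest.approx(100.0)
    assert filled.surface_area.method_label == "estimated_from_core"
    # estimated values inherit the source level of their basis value
    assert filled.surface_area.source_level == "experimental"


def test_unfillable_attribute_stays_absent_and_flagged(lookups):
    mfr, ref, dens, qm = lookups
    rec = _record()
    filled, actions = fill_record(rec, ManufacturerCatalog(), ReferenceCatalog(), dens, qm)
    assert filled.surface_charge.is_absent
    flagged = {a.attribute for a in actions if a.action == "unfilled"}
    assert "surface_charge" in flagged


def test_fill_idempotence(small_data):
    for rec in list(small_data.records)[:20]:
        once, _ = fill_record(
            rec, small_data.manufacturer, small_data.reference, small_data.density, small_data.qm
        )
        twice, actions = fill_record(
            once, small_data.manufacturer, small_data.reference, small_data.density, small_data.qm
        )
        assert twice == once
        assert all(a.action == "unfilled" for a in actions)


def test_dataset_ii_is_complete(scored_table, small_data):
    table, _ = build_dataset_ii(
        scored_table, small_data.manufacturer, small_data.reference,
        small_data.density, small_data.qm,
    )
    assert not table.df[list(PCHEM_ATTRS)].isna().any().any()
    assert not table.df[["dHsf_eV", "Ec_eV", "Ev_eV", "chi_eV"]].isna().any().any()
    assert len(table) <= len(scored_table)


def test_dataset_ii_without_gaps_is_identity(clean_data):
    scored = score_table(clean_data.records)
    table, report = build_dataset_ii(
        scored, clean_data.manufacturer, clean_data.reference, clean_data.density, clean_data.qm
    )
    assert len(table) == len(scored)
    assert all(a.action == "unfilled" for a in report) or not report


def test_dataset_ii_drops_unfillable_rows(scored_table, small_data):
    empty = (ManufacturerCatalog(), ReferenceCatalog())
    # with no catalogs, only core<->SSA estimation can fill; rows missing
    # hydro size or charge must be dropped
    table, _ = build_dataset_ii(
        scored_table, *empty, small_data.density, small_data.qm
    )
    df = scored_table.df
    expected = (~df["hydro_size"].isna() & ~df["surface_charge"].isna()
                & (~df["core_size"].isna() | ~df["surface_area"].isna()))
    assert len(table) == int(expected.sum())


def test_mean_substitute_arithmetic_and_provenance():
    import pandas as pd

    present = {
        "hydro_size": ProvenancedMeasurement(120.0, "experimental", "DLS_NTA"),
        "surface_charge": ProvenancedMeasurement(-20.0, "experimental", "zeta_potential"),
        "surface_area": ProvenancedMeasurement(50.0, "experimental", "BET"),
    }
    df = score_table(RecordTable(
        pd.DataFrame([
            _record(core_size=ProvenancedMeasurement(1.0, "experimental", "TEM"), **present).to_row() | {"record_id": "a"},
            _record(core_size=ProvenancedMeasurement(2.0, "experimental", "TEM"), **present).to_row() | {"record_id": "b"},
            _record(**present).to_row() | {"record_id": "c"},
        ])
    ))
    out = mean_substitute(df, df)
    assert out.df.set_index("record_id").loc["c", "core_size"] == pytest.approx(1.5)
    # provenance (and therefore scores) unchanged
    assert out.df.set_index("record_id").loc["c", "core_size_source"] == "absent"
    rescored = score_table(RecordTable(out.df.drop(
        columns=[c for c in out.df.columns if c.endswith("_score") or c == "pchem_score" or c == "label"]
    )))
    assert (rescored.df["pchem_score"].to_numpy() == df.df["pchem_score"].to_numpy()).all()


def test_mean_substitute_no_gaps_is_identity(clean_data):
    out = mean_substitute(clean_data.records, clean_data.records)
    np.testing.assert_array_equal(
        out.df["core_size"].to_numpy(), clean_data.records.df["core_size"].to_numpy()
    )


def test_mean_substitute_requires_present_values():
    import pandas as pd

    rows = [_record().to_row() | {"record_id": f"r{i}"} for i in range(3)]
    table = RecordTable(pd.DataFrame(rows))
    with pytest.raises(ValueError, match="core_size"):
        mean_substitute(table, table)


def test_qm_table_rejects_inverted_bands():
    with pytest.raises(ValueError, match="Ev < Ec"):
        QMTable({"TiO2": {"dHsf_eV": -1.0, "Ec_eV": -8.0, "Ev_eV": -4.0, "chi_eV": 5.0}})
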