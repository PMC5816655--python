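"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nanosar.records import RecordTable
from nanosar.scoring import score_table
from nanosar.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_data():
    """A 300-record synthetic dataset with catalogs and ground truth."""
    return generate_dataset(SyntheticConfig(n_records=300, n_materials=40, seed=11))


@pytest.fixture(scope="session")
def scored_table(small_data):
    return score_table(small_data.records)


@pytest.fixture(scope="session")
def clean_data():
    """Zero-noise, zero-missingness dataset: observed values equal the truth."""
    cfg = SyntheticConfig(
        n_records=400,
        n_materials=90,
        seed=5,
        missingness={a: 0.0 for a in ("core_size", "hydro_size", "surface_charge", "surface_area")},
        noise_sd_by_provenance={"experimental": 0.0, "manufacturer": 0.0, "reference": 0.0},
        viability_noise_sd=0.0,
        method_noise_factor=1.0,
    )
    return generate_dataset(cfg)


def relabel_by_viability(df: pd.DataFrame, viability: np.ndarray) -> RecordTable:
    """Rebuild a table with new viability values (labels are re-derived)."""
    out = df.copy()
    out["viability_pct"] = viability
    return RecordTable(out.drop(columns=["label"]))
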