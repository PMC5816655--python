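"""Data-quality scoring of PChem provenance and score-based screening.

Each of the four PChem attributes gets a data-source score (experimentally
measured 3, manufacturer specification 2, reused from another publication 1,
no data 0) plus a data-method score (widely acknowledged technique 2, less
common method or estimation from another attribute 1, no information 0).
The per-attribute total is their sum (0-5) and the final quality score of a
record is the arithmetic mean of the four attribute totals, so the best
possible record scores 5 and a fully uncharacterized one scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .records import (
    GOLD_METHODS,
    METHOD_VOCAB,
    PCHEM_ATTRS,
    NanoRecord,
    RecordTable,
)

__all__ = [
    "SOURCE_SCORES",
    "MAX_FINAL_SCORE",
    "MIN_FINAL_SCORE",
    "ScoreCard",
    "score_source",
    "score_method",
    "score_record",
    "score_table",
    "screen_by_score",
]

SOURCE_SCORES: dict[str, int] = {
    "experimental": 3,
    "manufacturer": 2,
    "reference": 1,
    "absent": 0,
}

MAX_FINAL_SCORE = 5.0
MIN_FINAL_SCORE = 0.0

SCORE_COLUMNS: tuple[str, ...] = (
    "core_size_score",
    "hydro_size_score",
    "surface_charge_score",
    "surface_area_score",
    "pchem_score",
)


def score_source(source_level: str) -> int:
    """Data-source score: experimental 3, manufacturer 2, reference 1, absent 0."""
    try:
        return SOURCE_SCORES[source_level]
    except KeyError:
        raise ValueError(f"unknown source level {source_level!r}") from None


def score_method(attribute: str, method_label: str) -> int:
    """Data-method score for one attribute.

    The attribute's gold-standard technique (TEM for core size, DLS/NTA for
    hydrodynamic size, zeta potential for surface charge, BET for surface
    area) scores 2; any other or estimated method scores 1; no information
    scores 0.
    """
    if attribute not in PCHEM_ATTRS:
        raise ValueError(f"unknown PChem attribute {attribute!r}")
    if method_label not in METHOD_VOCAB[attribute]:
        raise ValueError(f"method {method_label!r} not valid for {attribute!r}")
    if method_label == "none":
        return 0
    if method_label == GOLD_METHODS[attribute]:
        return 2
    return 1


@dataclass(frozen=True)
class ScoreCard:
    """Per-attribute and final PChem quality scores for one record."""

    source_scores: dict[str, int]
    method_scores: dict[str, int]

    @property
    def attribute_totals(self) -> dict[str, int]:
        return {a: self.source_scores[a] + self.method_scores[a] for a in PCHEM_ATTRS}

    @property
    def final_score(self) -> float:
        totals = self.attribute_totals
        return sum(totals.values()) / len(PCHEM_ATTRS)


def score_record(record: NanoRecord) -> ScoreCard:
    src: dict[str, int] = {}
    meth: dict[str, int] = {}
    for attr in PCHEM_ATTRS:
        m = record.measurement(attr)
        src[attr] = score_source(m.source_level)
        meth[attr] = score_method(attr, m.method_label)
    return ScoreCard(src, meth)


def score_table(table: RecordTable) -> RecordTable:
    """Return a copy of the table with per-attribute and final score columns.

    Scoring depends only on the provenance columns, so imputed values (which
    leave provenance untouched) never change scores.
    """
    df = table.df.copy()
    total = None
    for attr in PCHEM_ATTRS:
        src = df[f"{attr}_source"].map(SOURCE_SCORES)
        if src.isna().any():
            bad = df.loc[src.isna(), f"{attr}_source"].iloc[0]
            raise ValueError(f"unknown source level {bad!r} in {attr}_source")
        meth = df[f"{attr}_method"].map(lambda m, a=attr: score_method(a, m))
        attr_total = src + meth
        df[f"{attr}_score"] = attr_total.astype(int)
        total = attr_total if total is None else total + attr_total
    df["pchem_score"] = total / len(PCHEM_ATTRS)
    return RecordTable(df)


def screen_by_score(table: RecordTable, keep_fraction: float) -> RecordTable:
    """Keep the top ``keep_fraction`` of records by final PChem score.

    Records are ordered by score descending with ties broken by record_id
    ascending, and the first ``floor(keep_fraction * n)`` records (at least
    one) are retained, preserving the original row order in the output.
    """
    if len(table) == 0:
        raise ValueError("cannot screen an empty table")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if "pchem_score" not in table.df.columns:
        raise ValueError("table must be scored before screening (missing pchem_score)")
    n_keep = max(1, math.floor(keep_fraction * len(table)))
    ranked = table.df.sort_values(
        ["pchem_score", "record_id"], ascending=[False, True], kind="stable"
    )
    keep_ids = set(ranked["record_id"].iloc[:n_keep])
    return RecordTable(table.df[table.df["record_id"].isin(keep_ids)].copy())
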