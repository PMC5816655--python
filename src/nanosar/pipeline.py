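"""End-to-end orchestration of the meta-analysis workflow.

From one configuration (a generator block or an input CSV plus catalogs) the
pipeline builds the four dataset variants —

* I: the original table, scored; missing values mean-substituted only at
  modeling time, with training-partition statistics;
* II: gap-filled via catalogs and the sphere SSA relation, rows with
  unfillable gaps dropped, quality scores recomputed;
* III-A / III-B: the top 50 % / 20 % of II by final PChem score —

then fits and validates the replicated random-forest models on each variant,
derives applicability-domain profiles, optionally runs the attribute
importance analyses, and writes every artifact (CSV tables, JSON reports, a
run manifest) into the output directory.  Screening precedes the train/test
split; all randomness derives from the configured seeds, so a rerun with
the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .domain import DEFAULT_Z, build_ad_profile
from .gapfill import (
    DensityTable,
    ManufacturerCatalog,
    QMTable,
    ReferenceCatalog,
    build_dataset_ii,
    mean_substitute,
)
from .importance import category_combination_study, loo_oob_importance
from .model import ModelConfig, run_experiment, split_train_test
from .records import RecordTable, load_records, summarize_missingness, write_records
from .scoring import score_table, screen_by_score
from .synth import SyntheticConfig, generate_dataset

__all__ = ["run_pipeline", "load_config", "DEFAULT_COMBINATIONS"]

logger = logging.getLogger("nanosar")

DEFAULT_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("dose", "pchem"),
    ("dose", "qm"),
    ("dose", "tox"),
    ("dose", "pchem", "qm"),
    ("dose", "pchem", "tox"),
)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def _synthetic_config(block: dict[str, Any]) -> SyntheticConfig:
    fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown generator settings: {sorted(unknown)}")
    if "compositions" in block:
        block = {**block, "compositions": tuple(block["compositions"])}
    for grid in ("dose_grid", "time_grid"):
        if grid in block:
            block = {**block, grid: tuple(block[grid])}
    return SyntheticConfig(**block)


def _model_config(block: dict[str, Any]) -> ModelConfig:
    fields = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown model settings: {sorted(unknown)}")
    if "feature_categories" in block:
        block = {**block, "feature_categories": tuple(block["feature_categories"])}
    return ModelConfig(**block)


def _load_inputs(cfg: dict, out: Path):
    if "generator" in cfg:
        gen_cfg = _synthetic_config(cfg.get("generator") or {})
        data = generate_dataset(gen_cfg)
        write_records(data.records, out / "records.csv")
        data.manufacturer.to_csv(out / "manufacturer_catalog.csv")
        data.reference.to_csv(out / "reference_catalog.csv")
        data.density.to_csv(out / "density.csv")
        data.qm.to_csv(out / "qm_table.csv")
        data.truth.to_csv(out / "truth.csv", index=False)
        return data.records, data.manufacturer, data.reference, data.density, data.qm
    if "input" not in cfg:
        raise ValueError("configuration needs either a 'generator' or an 'input' block")
    inp = cfg["input"]
    table = load_records(inp["records"])
    catalogs = Path(inp["catalogs"])
    return (
        table,
        ManufacturerCatalog.from_csv(catalogs / "manufacturer_catalog.csv"),
        ReferenceCatalog.from_csv(catalogs / "reference_catalog.csv"),
        DensityTable.from_csv(catalogs / "density.csv"),
        QMTable.from_csv(catalogs / "qm_table.csv"),
    )


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Run the full workflow; returns (and writes) the run manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, mfr, ref, dens, qm = _load_inputs(cfg, out)
    logger.info("loaded %d records", len(table))

    model_cfg = _model_config(cfg.get("model") or {})
    keep_a, keep_b = cfg.get("keep_fractions", [0.5, 0.2])
    ad_cfg = cfg.get("ad") or {}
    k, Z = int(ad_cfg.get("k", 5)), float(ad_cfg.get("Z", DEFAULT_Z))

    dataset_i = score_table(table)
    dataset_ii, fill_report = build_dataset_ii(dataset_i, mfr, ref, dens, qm)
    dataset_iiia = screen_by_score(dataset_ii, keep_a)
    dataset_iiib = screen_by_score(dataset_ii, keep_b)
    datasets = {"I": dataset_i, "II": dataset_ii, "III-A": dataset_iiia, "III-B": dataset_iiib}
    _write_json(out / "fill_report.json", [a.to_dict() for a in fill_report])
    _write_json(out / "missingness.json", summarize_missingness(table))

    metrics: dict[str, dict] = {}
    for name, ds in datasets.items():
        slug = name.replace("-", "").lower()
        write_records(ds, out / f"dataset_{slug}.csv")
        impute = name == "I"
        logger.info("modeling dataset %s (n=%d)", name, len(ds))
        report = run_experiment(ds, model_cfg, impute_missing=impute)
        metrics[name] = report.to_dict()
        _write_json(out / f"metrics_{slug}.json", metrics[name])

        # AD on the first replication's training partition; dataset I needs
        # complete numeric values first
        train, _ = split_train_test(ds, model_cfg.base_seed, model_cfg.train_fraction)
        if impute:
            train = mean_substitute(train, train)
        profile = build_ad_profile(train, k=k, Z=Z)
        profile.to_json(out / f"ad_{slug}.json")

    if cfg.get("importance", {}).get("enabled", False):
        imp_ds = datasets[cfg.get("importance", {}).get("dataset", "III-A")]
        logger.info("attribute importance on %d records", len(imp_ds))
        loo = loo_oob_importance(imp_ds, model_cfg)
        _write_json(out / "importance_loo.json", loo.to_dict())
        combos = [tuple(c) for c in cfg.get("importance", {}).get("combinations", DEFAULT_COMBINATIONS)]
        study = category_combination_study(imp_ds, combos, model_cfg)
        _write_json(out / "importance_categories.json", study.to_dict())

    manifest = {
        "version": __version__,
        "config": cfg,
        "row_counts": {name: len(ds) for name, ds in datasets.items()},
        "toxic_counts": {
            name: int((ds.df["label"] == "Toxic").sum()) for name, ds in datasets.items()
        },
        "metrics_mean": {name: m["mean"] for name, m in metrics.items()},
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
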