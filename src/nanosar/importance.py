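"""Attribute importance via leave-one-out OOB error and category combinations.

Each modeling attribute is removed in turn and a forest is refitted on the
remaining attributes (same seeds, same splits); the higher the resulting
out-of-bag error, the more the removed attribute mattered.  The protocol
deliberately measures marginal loss, so redundant attributes (whose
information survives in a correlated partner) can rank low even when
informative.  The combination study evaluates the full replicated
validation protocol on dose plus chosen attribute categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import ExperimentReport, ModelConfig, fit_oob_error, modeling_features, run_experiment
from .records import RecordTable

__all__ = ["ImportanceReport", "CategoryStudyReport", "loo_oob_importance", "category_combination_study"]


@dataclass
class ImportanceReport:
    """OOB error without each attribute, baseline with all, and the ranking."""

    baseline_oob: float
    oob_without: dict[str, float]

    @property
    def ranking(self) -> list[str]:
        """Attributes in descending order of leave-one-out OOB error."""
        return sorted(self.oob_without, key=lambda a: (-self.oob_without[a], a))

    def to_dict(self) -> dict:
        return {
            "baseline_oob": self.baseline_oob,
            "oob_without": self.oob_without,
            "ranking": self.ranking,
        }


def loo_oob_importance(
    table: RecordTable,
    config: ModelConfig | None = None,
    *,
    impute_missing: bool = False,
) -> ImportanceReport:
    """Leave-one-attribute-out OOB errors averaged over replications."""
    config = config or ModelConfig()
    attributes = modeling_features(config.feature_categories)
    if len(attributes) < 2:
        raise ValueError("need at least 2 modeling attributes")
    baseline = fit_oob_error(table, attributes, config, impute_missing=impute_missing)
    oob_without = {
        attr: fit_oob_error(
            table, [a for a in attributes if a != attr], config, impute_missing=impute_missing
        )
        for attr in attributes
    }
    return ImportanceReport(baseline, oob_without)


@dataclass
class CategoryStudyReport:
    """Averaged accuracy and F1 per attribute-category combination."""

    results: dict[str, ExperimentReport]

    def to_dict(self) -> dict:
        return {
            combo: {"accuracy": rep.mean_accuracy, "f1": rep.mean_f1}
            for combo, rep in self.results.items()
        }


def category_combination_study(
    table: RecordTable,
    combinations: Sequence[Sequence[str]],
    config: ModelConfig | None = None,
    *,
    impute_missing: bool = False,
) -> CategoryStudyReport:
    """Run the replicated validation protocol for each category combination.

    Each combination is a sequence of category tokens (e.g. ``("dose",
    "pchem")``); results are keyed by the ``+``-joined token string.
    """
    if not combinations:
        raise ValueError("combinations must be non-empty")
    config = config or ModelConfig()
    results: dict[str, ExperimentReport] = {}
    for combo in combinations:
        combo = tuple(combo)
        key = "+".join(combo)
        cfg = ModelConfig(
            n_trees=config.n_trees,
            features_per_split=config.features_per_split,
            base_seed=config.base_seed,
            n_replications=config.n_replications,
            train_fraction=config.train_fraction,
            cv_folds=config.cv_folds,
            feature_categories=combo,
        )
        results[key] = run_experiment(table, cfg, impute_missing=impute_missing, do_cv=False)
    return CategoryStudyReport(results)
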