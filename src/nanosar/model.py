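"""Random-forest nano-SAR classification with replicated validation.

The modeling protocol: numeric attributes are mean-centered and scaled with
statistics of the training partition, nominal attributes are one-hot
encoded (cell_name is excluded as a feature), the table is split 60/40 into
training and test partitions, a random forest is fitted on the training
partition, cross-validation is run on the training partition and external
validation on the test partition, and the whole procedure is replicated
five times with derived seeds; metrics are averaged arithmetically across
replications.  Precision, sensitivity, accuracy and F1 all treat ``Toxic``
as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .gapfill import mean_substitute
from .records import PCHEM_ATTRS, QM_ATTRS, TOXIC, RecordTable

__all__ = [
    "ModelConfig",
    "MetricsReport",
    "ExperimentReport",
    "CATEGORY_FEATURES",
    "modeling_features",
    "normalize",
    "training_stats",
    "split_train_test",
    "train_classifier",
    "compute_metrics",
    "f1_from_precision_sensitivity",
    "run_experiment",
    "fit_oob_error",
]

#: Attribute categories used in the combination study.  Exposure time is a
#: Tox attribute (an experimental condition); dose stands alone.
CATEGORY_FEATURES: dict[str, tuple[str, ...]] = {
    "dose": ("dose_ug_mL",),
    "pchem": PCHEM_ATTRS,
    "qm": QM_ATTRS,
    "tox": ("assay", "cell_species", "cell_origin", "cell_type", "time_h"),
}

NOMINAL_FEATURES: tuple[str, ...] = ("assay", "cell_species", "cell_origin", "cell_type")


def modeling_features(categories: Sequence[str]) -> list[str]:
    """Expand category tokens into the ordered feature-column list."""
    cols: list[str] = []
    for cat in categories:
        if cat not in CATEGORY_FEATURES:
            raise ValueError(f"unknown attribute category {cat!r}")
        cols.extend(CATEGORY_FEATURES[cat])
    return cols


@dataclass(frozen=True)
class ModelConfig:
    """Random-forest and validation-protocol settings."""

    n_trees: int = 500
    features_per_split: int | str = "sqrt"
    base_seed: int = 0
    n_replications: int = 5
    train_fraction: float = 0.60
    cv_folds: int = 5
    feature_categories: tuple[str, ...] = ("dose", "pchem", "qm", "tox")

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the four performance measures, Toxic positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def f1(self) -> float:
        return f1_from_precision_sensitivity(self.precision, self.sensitivity)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "accuracy": self.accuracy, "f1": self.f1,
            "precision_pct": round(100 * self.precision),
            "sensitivity_pct": round(100 * self.sensitivity),
            "accuracy_pct": round(100 * self.accuracy),
            "f1_pct": round(100 * self.f1),
        }


def f1_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both vanish)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def compute_metrics(predictions: Sequence[str], truth: Sequence[str]) -> MetricsReport:
    """Confusion counts and metrics with the Toxic class as positive."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("cannot compute metrics on empty vectors")
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    tp = int(np.sum((pred == TOXIC) & (true == TOXIC)))
    fp = int(np.sum((pred == TOXIC) & (true != TOXIC)))
    fn = int(np.sum((pred != TOXIC) & (true == TOXIC)))
    tn = int(np.sum((pred != TOXIC) & (true != TOXIC)))
    return MetricsReport(tp, fp, fn, tn)


def training_stats(df: pd.DataFrame, columns: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Per-column mean and sample SD (ddof=1) for normalization."""
    stats: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = df[col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]  # unimputed gaps are left to the forest
        if vals.size == 0:
            raise ValueError(f"no present values to normalize column {col!r}")
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        stats[col] = (float(np.mean(vals)), sd)
    return stats


def normalize(df: pd.DataFrame, stats: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Mean-center and scale numeric columns; constant columns are centered only."""
    out = df.copy()
    for col in df.columns:
        if col not in stats:
            continue
        mean, sd = stats[col]
        if not np.isfinite(sd):
            raise ValueError(f"non-finite SD for column {col!r}")
        out[col] = (df[col] - mean) / (sd if sd > 0 else 1.0)
    return out


def split_train_test(
    table: RecordTable, seed: int, train_fraction: float = 0.60
) -> tuple[RecordTable, RecordTable]:
    """Random disjoint 60/40 partition; same seed gives the same split."""
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    df = table.df
    train = RecordTable(df.iloc[np.sort(perm[:n_train])].copy())
    test = RecordTable(df.iloc[np.sort(perm[n_train:])].copy())
    return train, test


def _design_matrix(
    df: pd.DataFrame, feature_cols: Sequence[str], categories: dict[str, list]
) -> pd.DataFrame:
    """Numeric columns as-is plus one-hot nominal columns with fixed levels."""
    parts: list[pd.DataFrame] = []
    for col in feature_cols:
        if col in NOMINAL_FEATURES:
            cat = pd.Categorical(df[col], categories=categories[col])
            parts.append(pd.get_dummies(pd.Series(cat, index=df.index), prefix=col, dtype=float))
        else:
            parts.append(df[[col]].astype(float))
    return pd.concat(parts, axis=1)


def train_classifier(
    X: pd.DataFrame, y: Sequence[str], config: ModelConfig, seed: int
) -> RandomForestClassifier:
    """Fit a random forest with out-of-bag scoring enabled."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def oob_error(clf: RandomForestClassifier) -> float:
    return 1.0 - float(clf.oob_score_)


def _prepare_partitions(
    train: RecordTable,
    test: RecordTable,
    feature_cols: Sequence[str],
    impute_missing: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if impute_missing:
        # substitution means come from the training partition only
        test = mean_substitute(test, train)
        train = mean_substitute(train, train)
    numeric = [c for c in feature_cols if c not in NOMINAL_FEATURES]
    stats = training_stats(train.df, numeric)
    return normalize(train.df, stats), normalize(test.df, stats)


@dataclass
class ExperimentReport:
    """External-validation (and cross-validation) metrics per replication."""

    external: list[MetricsReport]
    cv: list[MetricsReport] = field(default_factory=list)
    oob_errors: list[float] = field(default_factory=list)

    def _mean(self, reports: list[MetricsReport], metric: str) -> float:
        return float(np.mean([getattr(r, metric) for r in reports]))

    @property
    def mean_precision(self) -> float:
        return self._mean(self.external, "precision")

    @property
    def mean_sensitivity(self) -> float:
        return self._mean(self.external, "sensitivity")

    @property
    def mean_accuracy(self) -> float:
        return self._mean(self.external, "accuracy")

    @property
    def mean_f1(self) -> float:
        return self._mean(self.external, "f1")

    @property
    def mean_oob_error(self) -> float:
        return float(np.mean(self.oob_errors)) if self.oob_errors else float("nan")

    def to_dict(self) -> dict:
        out = {
            "replications": [m.to_dict() for m in self.external],
            "mean": {
                "precision": self.mean_precision,
                "sensitivity": self.mean_sensitivity,
                "accuracy": self.mean_accuracy,
                "f1": self.mean_f1,
            },
            "oob_errors": self.oob_errors,
        }
        if self.cv:
            out["cross_validation"] = [m.to_dict() for m in self.cv]
        return out


def run_experiment(
    table: RecordTable,
    config: ModelConfig | None = None,
    *,
    impute_missing: bool = False,
    do_cv: bool = True,
) -> ExperimentReport:
    """Replicated split / fit / validate protocol on one dataset variant.

    For each replication i the table is split with seed ``base_seed + i``,
    missing values (if ``impute_missing``) are mean-substituted with training
    statistics, numeric features are normalized with training statistics, a
    random forest is fitted, stratified cross-validation is run on the
    training partition, and metrics are computed on the held-out partition.
    The report is a pure function of (table, config).
    """
    config = config or ModelConfig()
    feature_cols = modeling_features(config.feature_categories)
    categories = {
        col: sorted(table.df[col].unique()) for col in NOMINAL_FEATURES if col in feature_cols
    }
    external: list[MetricsReport] = []
    cv_reports: list[MetricsReport] = []
    oob_errors: list[float] = []
    for i in range(config.n_replications):
        seed = config.base_seed + i
        train, test = split_train_test(table, seed, config.train_fraction)
        train_df, test_df = _prepare_partitions(train, test, feature_cols, impute_missing)
        X_train = _design_matrix(train_df, feature_cols, categories)
        X_test = _design_matrix(test_df, feature_cols, categories)
        y_train = train_df["label"].to_numpy()
        y_test = test_df["label"].to_numpy()
        clf = train_classifier(X_train, y_train, config, seed)
        oob_errors.append(oob_error(clf))
        external.append(compute_metrics(clf.predict(X_test), y_test))
        if do_cv:
            folds = min(config.cv_folds, int(np.bincount(pd.factorize(y_train)[0]).min()))
            if folds >= 2:
                skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
                cv_clf = RandomForestClassifier(
                    n_estimators=config.n_trees,
                    max_features=config.features_per_split,
                    random_state=seed,
                    n_jobs=1,
                )
                cv_pred = cross_val_predict(cv_clf, X_train, y_train, cv=skf)
                cv_reports.append(compute_metrics(cv_pred, y_train))
    return ExperimentReport(external, cv_reports, oob_errors)


def fit_oob_error(
    table: RecordTable,
    feature_cols: Sequence[str],
    config: ModelConfig,
    *,
    impute_missing: bool = False,
) -> float:
    """Average out-of-bag error of the training-partition forests over replications."""
    categories = {
        col: sorted(table.df[col].unique()) for col in NOMINAL_FEATURES if col in feature_cols
    }
    errors = []
    for i in range(config.n_replications):
        seed = config.base_seed + i
        train, test = split_train_test(table, seed, config.train_fraction)
        train_df, _ = _prepare_partitions(train, test, feature_cols, impute_missing)
        X = _design_matrix(train_df, feature_cols, categories)
        clf = train_classifier(X, train_df["label"].to_numpy(), config, seed)
        errors.append(oob_error(clf))
    return float(np.mean(errors))
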