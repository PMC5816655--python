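"""Applicability-domain analysis via a kNN distance cutoff.

For every training sample the mean weighted-Euclidean distance to its k
nearest neighbours (self excluded) is computed on the z-normalized numeric
attributes.  The cutoff

    D_c = D_bar + Z * s

(D_bar and s the mean and standard deviation of those per-sample mean
distances; Z = 1.645 corresponds to a one-tailed 95 % confidence level)
defines the retained subset: samples whose mean kNN distance does not exceed
D_c.  The numeric applicability domain is the per-attribute min/max over the
retained subset, reported in original units; the domain of each nominal
attribute is the set of levels observed in training.  A new sample is in
domain when all numeric attributes fall inside their closed intervals and
all nominal levels are known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import NOMINAL_FEATURES, normalize, training_stats
from .records import NanoRecord, RecordTable

__all__ = [
    "DEFAULT_Z",
    "ADProfile",
    "weighted_distance",
    "knn_mean_distances",
    "distance_cutoff",
    "build_ad_profile",
    "in_domain",
]

#: one-tailed 95 % confidence level
DEFAULT_Z = 1.645

DEFAULT_NUMERIC_ATTRS: tuple[str, ...] = (
    "dose_ug_mL", "time_h", "core_size", "hydro_size", "surface_charge",
    "surface_area", "dHsf_eV", "Ec_eV", "Ev_eV", "chi_eV",
)
DEFAULT_NOMINAL_ATTRS: tuple[str, ...] = NOMINAL_FEATURES


def weighted_distance(a: Sequence[float], b: Sequence[float], weights: Sequence[float]) -> float:
    """sqrt(sum w_j (a_j - b_j)^2); symmetric, zero iff weighted components agree."""
    a, b, w = (np.asarray(x, dtype=float) for x in (a, b, weights))
    if a.shape != b.shape or a.shape != w.shape:
        raise ValueError("vectors and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return float(np.sqrt(np.sum(w * (a - b) ** 2)))


def knn_mean_distances(
    X: np.ndarray, k: int, weights: Sequence[float] | None = None
) -> np.ndarray:
    """Per-sample mean weighted distance to its k nearest neighbours.

    Self-distances are excluded; ties in neighbour rank are broken by sample
    index (the mean is unaffected because tied neighbours are equidistant).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n = X.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k <= n-1 (k={k}, n={n})")
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    Xw = X * np.sqrt(w)
    D = cdist(Xw, Xw)
    np.fill_diagonal(D, np.inf)
    nearest = np.sort(D, axis=1)[:, :k]
    return nearest.mean(axis=1)


def distance_cutoff(dists: Sequence[float], Z: float = DEFAULT_Z) -> float:
    """D_c = mean + Z * sample SD of the per-sample mean distances."""
    d = np.asarray(dists, dtype=float)
    if d.size == 0:
        raise ValueError("distance vector must be non-empty")
    s = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return float(np.mean(d)) + Z * s


@dataclass
class ADProfile:
    """Distance cutoff and attribute-range description of a training domain."""

    k: int
    Z: float
    weights: dict[str, float]
    D_bar: float
    s: float
    D_c: float
    n_train: int
    n_retained: int
    numeric_ranges: dict[str, tuple[float, float]]
    nominal_domains: dict[str, list[str]]
    retained_ids: list[str] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "k": self.k, "Z": self.Z, "weights": self.weights,
            "D_bar": self.D_bar, "s": self.s, "D_c": self.D_c,
            "n_train": self.n_train, "n_retained": self.n_retained,
            "numeric_ranges": {a: list(r) for a, r in self.numeric_ranges.items()},
            "nominal_domains": self.nominal_domains,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ADProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"], Z=d["Z"], weights=d["weights"], D_bar=d["D_bar"], s=d["s"],
            D_c=d["D_c"], n_train=d["n_train"], n_retained=d["n_retained"],
            numeric_ranges={a: tuple(r) for a, r in d["numeric_ranges"].items()},
            nominal_domains=d["nominal_domains"],
        )


def build_ad_profile(
    train: RecordTable,
    k: int = 5,
    Z: float = DEFAULT_Z,
    weights: Mapping[str, float] | None = None,
    numeric_attrs: Sequence[str] = DEFAULT_NUMERIC_ATTRS,
    nominal_attrs: Sequence[str] = DEFAULT_NOMINAL_ATTRS,
) -> ADProfile:
    """Build the applicability-domain profile of a training table.

    Distances are computed on z-normalized numeric attributes (default
    uniform weights); ranges of the retained subset are reported in original
    units.  Nominal domains are the level sets observed in the full training
    table.  All numeric attributes must be complete (gap-fill or
    mean-substitute first).
    """
    df = train.df
    numeric_attrs = list(numeric_attrs)
    if df[numeric_attrs].isna().any().any():
        bad = df[numeric_attrs].isna().any()
        raise ValueError(f"numeric attributes contain missing values: {list(bad[bad].index)}")
    w = {a: 1.0 for a in numeric_attrs} if weights is None else {a: float(weights[a]) for a in numeric_attrs}
    stats = training_stats(df, numeric_attrs)
    X = normalize(df, stats)[numeric_attrs].to_numpy(dtype=float)
    dists = knn_mean_distances(X, k, [w[a] for a in numeric_attrs])
    D_bar = float(np.mean(dists))
    s = float(np.std(dists, ddof=1)) if dists.size > 1 else 0.0
    D_c = D_bar + Z * s
    retained = dists <= D_c
    if not retained.any():
        raise ValueError("no training samples retained under the distance cutoff")
    sub = df[retained]
    return ADProfile(
        k=k, Z=Z, weights=w, D_bar=D_bar, s=s, D_c=D_c,
        n_train=len(df), n_retained=int(retained.sum()),
        numeric_ranges={a: (float(sub[a].min()), float(sub[a].max())) for a in numeric_attrs},
        nominal_domains={a: sorted(df[a].unique()) for a in nominal_attrs},
        retained_ids=list(sub["record_id"]),
    )


def in_domain(sample: NanoRecord | Mapping, profile: ADProfile) -> tuple[bool, list[str]]:
    """Check one sample against the profiled ranges and nominal level sets.

    Numeric bounds are inclusive.  Returns (verdict, violation descriptions).
    Missing profiled attributes raise.
    """
    if isinstance(sample, NanoRecord):
        sample = sample.to_row()
    violations: list[str] = []
    for attr, (lo, hi) in profile.numeric_ranges.items():
        if attr not in sample or sample[attr] is None or (
            isinstance(sample[attr], float) and np.isnan(sample[attr])
        ):
            raise ValueError(f"sample is missing profiled attribute {attr!r}")
        v = float(sample[attr])
        if not (lo <= v <= hi):
            violations.append(f"{attr}={v} outside [{lo}, {hi}]")
    for attr, levels in profile.nominal_domains.items():
        if attr not in sample:
            raise ValueError(f"sample is missing profiled attribute {attr!r}")
        if str(sample[attr]) not in levels:
            violations.append(f"{attr}={sample[attr]!r} not among training levels")
    return (not violations), violations
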