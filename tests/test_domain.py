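"""Applicability domain: distances, cutoff, profiles, membership."""

import numpy as np
import pandas as pd
import pytest

from nanosar.domain import (
    DEFAULT_NUMERIC_ATTRS,
    build_ad_profile,
    distance_cutoff,
    in_domain,
    knn_mean_distances,
    weighted_distance,
)
from nanosar.gapfill import mean_substitute
from nanosar.records import RecordTable
from nanosar.scoring import screen_by_score


def test_weighted_distance_cases():
    assert weighted_distance([1.0, 2.0], [1.0, 2.0], [1.0, 1.0]) == 0.0
    assert weighted_distance([0.0, 0.0], [3.0, 4.0], [1.0, 1.0]) == pytest.approx(5.0)
    assert weighted_distance([0.0, 1.0], [1.0, 9.0], [4.0, 0.0]) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        weighted_distance([0.0], [1.0, 2.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        weighted_distance([0.0], [1.0], [-1.0])


def test_knn_mean_distances_hand_cases():
    assert knn_mean_distances(np.array([[0.0], [0.0]]), k=1).tolist() == [0.0, 0.0]
    np.testing.assert_allclose(
        knn_mean_distances(np.array([[0.0], [1.0], [3.0]]), k=1), [1.0, 1.0, 2.0]
    )
    # k = n-1 collapses to the mean distance to all other samples
    X = np.array([[0.0], [1.0], [3.0]])
    np.testing.assert_allclose(
        knn_mean_distances(X, k=2), [(1 + 3) / 2, (1 + 2) / 2, (3 + 2) / 2]
    )
    with pytest.raises(ValueError):
        knn_mean_distances(X, k=3)


def _brute_force_knn_means(X, k, w):
    out = []
    for i in range(len(X)):
        dists = sorted(
            weighted_distance(X[i], X[j], w) for j in range(len(X)) if j != i
        )
        out.append(np.mean(dists[:k]))
    return np.array(out)


def test_knn_equivalence_with_brute_force_small_n():
    """Matches an all-pairs brute-force computation on random instances."""
    rng = np.random.default_rng(4)
    for _ in range(5):
        n, p = int(rng.integers(5, 50)), int(rng.integers(1, 6))
        X = rng.normal(size=(n, p))
        w = rng.uniform(0.1, 2.0, size=p)
        k = int(rng.integers(1, n - 1))
        np.testing.assert_allclose(
            knn_mean_distances(X, k, w), _brute_force_knn_means(X, k, w), rtol=1e-10
        )


def test_distance_cutoff_arithmetic():
    assert distance_cutoff([2.0, 2.0, 2.0], Z=1.645) == pytest.approx(2.0)
    d = np.array([0.0, 2.0])  # mean 1, sample SD sqrt(2)
    assert distance_cutoff(d, Z=0.0) == pytest.approx(1.0)
    assert distance_cutoff(d, Z=1.645) == pytest.approx(1.0 + 1.645 * np.sqrt(2.0))
    with pytest.raises(ValueError):
        distance_cutoff([])


@pytest.fixture(scope="module")
def complete_table(small_data):
    return mean_substitute(small_data.records, small_data.records)


def test_outlier_excluded_from_retained_subset(small_data):
    """A far outlier exceeds D_c and shrinks the profiled ranges."""
    df = small_data.records.df.head(30).copy()
    table = mean_substitute(RecordTable(df.drop(columns=["label"])), small_data.records)
    out = table.df.copy()
    out.loc[out.index[0], "dose_ug_mL"] = 1e6
    outlier_table = RecordTable(out.drop(columns=["label"]))
    profile = build_ad_profile(outlier_table, k=3)
    outlier_id = out["record_id"].iloc[0]
    assert outlier_id not in profile.retained_ids
    assert profile.numeric_ranges["dose_ug_mL"][1] < 1e6


def test_huge_z_retains_everything(complete_table):
    profile = build_ad_profile(complete_table, k=5, Z=1e6)
    assert profile.n_retained == profile.n_train
    for attr in DEFAULT_NUMERIC_ATTRS:
        lo, hi = profile.numeric_ranges[attr]
        assert lo == pytest.approx(complete_table.df[attr].min())
        assert hi == pytest.approx(complete_table.df[attr].max())


def test_monotone_in_z(complete_table):
    """Larger Z retains a superset of samples and nests all numeric ranges."""
    p1 = build_ad_profile(complete_table, k=5, Z=0.5)
    p2 = build_ad_profile(complete_table, k=5, Z=1.645)
    assert set(p1.retained_ids) <= set(p2.retained_ids)
    for attr in DEFAULT_NUMERIC_ATTRS:
        assert p2.numeric_ranges[attr][0] <= p1.numeric_ranges[attr][0]
        assert p1.numeric_ranges[attr][1] <= p2.numeric_ranges[attr][1]


def test_retained_ranges_within_full_ranges(complete_table):
    profile = build_ad_profile(complete_table, k=5)
    for attr in DEFAULT_NUMERIC_ATTRS:
        lo, hi = profile.numeric_ranges[attr]
        assert complete_table.df[attr].min() <= lo <= hi <= complete_table.df[attr].max()


def test_screened_subsets_have_smaller_retained_counts(scored_table, small_data):
    """Stricter score screening cannot retain more samples in its domain."""
    full = mean_substitute(scored_table, scored_table)
    a = mean_substitute(screen_by_score(scored_table, 0.5), scored_table)
    b = mean_substitute(screen_by_score(scored_table, 0.2), scored_table)
    counts = [build_ad_profile(t, k=5).n_retained for t in (full, a, b)]
    assert counts[0] >= counts[1] >= counts[2]


def test_in_domain_membership(complete_table):
    profile = build_ad_profile(complete_table, k=5, Z=1.645)
    retained = complete_table.df.set_index("record_id").loc[profile.retained_ids[0]]
    ok, violations = in_domain(retained.to_dict(), profile)
    assert ok and not violations

    sample = retained.to_dict()
    sample["dose_ug_mL"] = profile.numeric_ranges["dose_ug_mL"][1] + 1.0
    ok, violations = in_domain(sample, profile)
    assert not ok
    assert any("dose_ug_mL" in v for v in violations)

    boundary = retained.to_dict()
    boundary["dose_ug_mL"] = profile.numeric_ranges["dose_ug_mL"][1]  # inclusive bound
    ok, _ = in_domain(boundary, profile)
    assert ok

    unknown_level = retained.to_dict()
    unknown_level["assay"] = "UNSEEN_ASSAY"
    ok, violations = in_domain(unknown_level, profile)
    assert not ok and any("assay" in v for v in violations)


def test_in_domain_missing_attribute_rejected(complete_table):
    profile = build_ad_profile(complete_table, k=5)
    with pytest.raises(ValueError, match="dose_ug_mL"):
        in_domain({"core_size": 10.0}, profile)


def test_profile_json_roundtrip(complete_table, tmp_path):
    from nanosar.domain import ADProfile

    profile = build_ad_profile(complete_table, k=4, Z=1.2)
    path = tmp_path / "ad.json"
    profile.to_json(path)
    loaded = ADProfile.from_json(path)
    assert loaded.D_c == pytest.approx(profile.D_c)
    assert loaded.numeric_ranges == profile.numeric_ranges
    assert loaded.nominal_domains == profile.nominal_domains
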