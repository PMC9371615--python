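import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosphodiff import (
    ConfigError,
    FilterParams,
    InputError,
    SampleMeta,
    detection_matrix,
    filter_min_valid,
    log2_transform,
    median_normalize,
    sample_qc,
)

from conftest import make_matrix

A3 = [SampleMeta(f"a{i}", "A") for i in range(3)]
NAN = np.nan


def test_log2_transform_values_and_missing():
    m = make_matrix([[8.0, 1.0], [NAN, 4.0]], [SampleMeta("s1", "A"), SampleMeta("s2", "B")])
    out = log2_transform(m)
    assert out.values.loc[0, "s1"] == 3.0
    assert out.values.loc[0, "s2"] == 0.0
    assert np.isnan(out.values.loc[1, "s1"])
    assert out.log_scale


def test_log2_transform_rejects_nonpositive_present_values():
    m = make_matrix([[0.0, 2.0]], [SampleMeta("s1", "A"), SampleMeta("s2", "B")])
    with pytest.raises(InputError):
        log2_transform(m)


def test_median_normalize_subtracts_present_value_median():
    m = make_matrix([[1.0], [2.0], [3.0]], [SampleMeta("s1", "A")], log_scale=True)
    out = median_normalize(m)
    assert out.values["s1"].tolist() == [-1.0, 0.0, 1.0]

    m2 = make_matrix([[2.0], [NAN], [4.0]], [SampleMeta("s1", "A")], log_scale=True)
    out2 = median_normalize(m2)
    assert out2.values["s1"].iloc[0] == -1.0
    assert np.isnan(out2.values["s1"].iloc[1])
    assert out2.values["s1"].iloc[2] == 1.0


@given(
    st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=30
    )
)
def test_median_normalize_postcondition_and_idempotence(col):
    m = make_matrix([[v] for v in col], [SampleMeta("s1", "A")], log_scale=True)
    once = median_normalize(m)
    assert once.values["s1"].median(skipna=True) == pytest.approx(0.0, abs=1e-12)
    twice = median_normalize(once)
    pd.testing.assert_frame_equal(once.values, twice.values)


def test_median_normalize_errors_on_all_missing_included_column():
    m = make_matrix([[NAN, 1.0]], [SampleMeta("s1", "A"), SampleMeta("s2", "B")], log_scale=True)
    with pytest.raises(InputError, match="s1"):
        median_normalize(m)


def test_detection_counts(two_group_samples):
    vals = np.full((3, 9), np.nan)
    vals[0, [0, 2]] = 5.0  # present in DMSO samples 1 and 3 only
    vals[2, :] = 5.0  # fully observed
    det = detection_matrix(make_matrix(vals, two_group_samples))
    assert det.group_counts.loc[0].tolist() == [2, 0]
    assert det.group_counts.loc[1].tolist() == [0, 0]
    assert det.group_counts.loc[2].tolist() == [4, 5]
    assert det.group_sizes == {"DMSO": 4, "neratinib": 5}


@pytest.mark.parametrize(
    "count_a, count_b, retained",
    [(3, 0, True), (2, 2, False), (0, 5, True)],
)
def test_filter_min_valid_rule(two_group_samples, count_a, count_b, retained):
    vals = np.full((1, 9), np.nan)
    vals[0, :count_a] = 1.0
    vals[0, 4 : 4 + count_b] = 1.0
    m = make_matrix(vals, two_group_samples, log_scale=True)
    kept, dropped = filter_min_valid(m, FilterParams(min_valid=3))
    assert (kept.n_sites == 1) is retained
    assert (len(dropped) == 1) is (not retained)


def test_filter_partitions_rows_and_preserves_order(two_group_samples):
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(40, 9))
    vals[rng.random(vals.shape) < 0.5] = np.nan
    m = make_matrix(vals, two_group_samples, log_scale=True)
    kept, dropped = filter_min_valid(m)
    assert kept.n_sites + len(dropped) == 40
    assert set(kept.sites["protein"]) | set(dropped["protein"]) == set(m.sites["protein"])
    assert set(kept.sites["protein"]) & set(dropped["protein"]) == set()
    # kept rows preserve input order
    orig_order = {p: i for i, p in enumerate(m.sites["protein"])}
    kept_idx = [orig_order[p] for p in kept.sites["protein"]]
    assert kept_idx == sorted(kept_idx)


def test_filter_and_normalization_commute_on_presence_pattern(two_group_samples):
    rng = np.random.default_rng(5)
    vals = rng.normal(20, 2, size=(30, 9))
    vals[rng.random(vals.shape) < 0.4] = np.nan
    m = make_matrix(vals, two_group_samples, log_scale=True)
    a = filter_min_valid(median_normalize(m))[0].values.notna()
    b = median_normalize(filter_min_valid(m)[0]).values.notna()
    pd.testing.assert_frame_equal(a, b)


def test_filter_min_valid_impossible_for_all_groups(two_group_samples):
    m = make_matrix(np.ones((2, 9)), two_group_samples, log_scale=True)
    with pytest.raises(ConfigError):
        filter_min_valid(m, FilterParams(min_valid=6))


class TestSampleQC:
    def test_identical_columns_correlate_perfectly(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        m = make_matrix(np.column_stack([col, col, -col]), A3, log_scale=True)
        report = sample_qc(m)
        # a0 vs a1 identical (r=1), each vs the negation gives r=-1
        tab = report.table.set_index("sample_id")
        assert tab.loc["a0", "mean_correlation"] == pytest.approx((1.0 - 1.0) / 2)
        assert tab.loc["a2", "mean_correlation"] == pytest.approx(-1.0)
        assert bool(tab.loc["a2", "flagged"])

    def test_hand_computed_product_moment_value(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        m = make_matrix(np.column_stack([a, b, a]), A3, log_scale=True)
        tab = sample_qc(m).table.set_index("sample_id")
        # r(a, b) = 3 / sqrt(2 * 14/3) = 0.98198 by direct evaluation
        assert tab.loc["a0", "mean_correlation"] == pytest.approx((0.98198 + 1.0) / 2, abs=1e-4)

    def test_pairs_with_too_few_shared_values_are_recorded(self):
        vals = np.array(
            [[1.0, NAN, 1.0], [2.0, NAN, 2.5], [3.0, 1.0, 3.1], [4.0, 2.0, 4.2], [5.0, 3.0, 4.9]]
        )
        vals[2:, 1] = [1.0, 2.0, NAN]  # a1 shares only 2 values with others
        report = sample_qc(make_matrix(vals, A3, log_scale=True))
        assert ("a0", "a1") in report.incomputable_pairs

    def test_requires_three_samples(self):
        m = make_matrix(np.ones((4, 2)), A3[:2], log_scale=True)
        with pytest.raises(InputError):
            sample_qc(m)
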