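import itertools
import math

import numpy as np
import pytest

from phosphodiff import InputError, SampleMeta, TestParams, permutation_fdr, two_sample_t

from conftest import make_matrix

A3B3 = [SampleMeta(f"a{i}", "A") for i in range(3)] + [
    SampleMeta(f"b{i}", "B") for i in range(3)
]


class TestTwoSampleT:
    def test_identical_samples_give_zero_t_unit_p(self):
        t, p, diff = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, diff) == (0.0, 1.0, 0.0)

    def test_hand_computed_pooled_t(self):
        # diff = -3, pooled sd = 1, se = sqrt(2/3): t = -3.674, df = 4
        t, p, diff = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert diff == -3.0
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_fudge_factor_shrinks_t_monotonically(self):
        t0, _, _ = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], s0=0.0)
        t1, _, _ = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], s0=0.5)
        assert abs(t1) < abs(t0)

    def test_zero_variance_cases(self):
        t, p, _ = two_sample_t([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)
        t, p, _ = two_sample_t([2.0, 2.0], [1.0, 1.0])
        assert t == math.inf and p == 0.0

    def test_requires_two_values_per_group(self):
        with pytest.raises(InputError):
            two_sample_t([1.0], [2.0, 3.0])


def brute_force_permutation_fdr(data: np.ndarray, n_a: int, s0: float = 0.0) -> list[float]:
    """Independent oracle: plain-Python enumeration of all labelings."""

    def tstat(a, b):
        na, nb = len(a), len(b)
        ma, mb = sum(a) / na, sum(b) / nb
        va = sum((v - ma) ** 2 for v in a) / (na - 1)
        vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
        se = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2) * (1 / na + 1 / nb))
        if se + s0 == 0:
            return 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        return (ma - mb) / (se + s0)

    n = data.shape[1]
    obs = [abs(tstat(list(row[:n_a]), list(row[n_a:]))) for row in data]
    labelings = list(itertools.combinations(range(n), n_a))
    perm_abs = []
    for idx in labelings:
        rest = [j for j in range(n) if j not in idx]
        for row in data:
            perm_abs.append(abs(tstat([row[j] for j in idx], [row[j] for j in rest])))

    order = sorted(range(len(obs)), key=lambda i: (-obs[i], i))
    raw = []
    for i in order:
        thr = obs[i]
        n_obs = sum(1 for v in obs if v >= thr)
        mean_perm = sum(1 for v in perm_abs if v >= thr) / len(labelings)
        raw.append(min(1.0, mean_perm / n_obs))
    for i in range(len(raw) - 2, -1, -1):
        raw[i] = min(raw[i], raw[i + 1])
    fdr = [0.0] * len(obs)
    for pos, i in enumerate(order):
        fdr[i] = raw[pos]
    return fdr


def test_exhaustive_matches_enumeration_oracle_on_3v3():
    """All C(6,3)=20 labelings; FDR values equal plain enumeration."""
    rng = np.random.default_rng(8)
    data = rng.normal(0, 1, size=(30, 6))
    data[:3, 3:] += 4.0  # a few shifted sites
    m = make_matrix(data, A3B3, log_scale=True)
    res = permutation_fdr(m, TestParams(seed=1))
    assert res.exhaustive and res.n_permutations == 20
    expected = brute_force_permutation_fdr(data, 3)
    assert res.table["fdr"].to_numpy() == pytest.approx(expected, abs=1e-12)


def test_relabeling_groups_flips_sign_keeps_significance(two_group_samples):
    rng = np.random.default_rng(9)
    data = rng.normal(0, 1, size=(40, 9))
    data[:5, 4:] += 3.0
    m = make_matrix(data, two_group_samples, log_scale=True)
    res = permutation_fdr(m, TestParams(seed=2))

    # present the same data with the groups' roles exchanged
    reordered = two_group_samples[4:] + two_group_samples[:4]
    data2 = np.concatenate([data[:, 4:], data[:, :4]], axis=1)
    m2 = make_matrix(data2, reordered, log_scale=True)
    res2 = permutation_fdr(m2, TestParams(seed=2))
    assert np.allclose(res2.table["diff"], -res.table["diff"])
    assert np.allclose(np.abs(res2.table["t"]), np.abs(res.table["t"]))
    assert np.allclose(res2.table["p"], res.table["p"])
    assert (res2.table["significant"] == res.table["significant"]).all()


def test_null_data_produces_few_calls(two_group_samples):
    rng = np.random.default_rng(10)
    calls = 0
    for seed in range(5):
        data = np.random.default_rng(seed).normal(0, 1, size=(300, 9))
        m = make_matrix(data, two_group_samples, log_scale=True)
        res = permutation_fdr(m, TestParams(seed=seed))
        calls += int(res.table["significant"].sum())
    assert calls <= 5  # ~0 expected at q=0.05 under the null


def test_single_huge_shift_is_ranked_first_and_significant(two_group_samples):
    rng = np.random.default_rng(12)
    data = rng.normal(0, 1, size=(500, 9))
    data[7, 4:] += 10.0
    m = make_matrix(data, two_group_samples, log_scale=True)
    res = permutation_fdr(m, TestParams(seed=3))
    assert res.table["fdr"].idxmin() == 7 or res.table.loc[7, "significant"]
    assert bool(res.table.loc[7, "significant"])
    assert np.abs(res.table["t"]).idxmax() == 7


def test_random_mode_switches_to_exhaustive_when_nperm_covers_all():
    rng = np.random.default_rng(13)
    data = rng.normal(0, 1, size=(10, 6))
    m = make_matrix(data, A3B3, log_scale=True)
    res = permutation_fdr(m, TestParams(seed=4, n_perm=100, exhaustive_below=5))
    assert res.exhaustive
    assert any("exhaustive" in note for note in res.notes)


def test_incomplete_matrix_rejected(two_group_samples):
    data = np.ones((3, 9))
    data[0, 0] = np.nan
    m = make_matrix(data, two_group_samples, log_scale=True)
    with pytest.raises(InputError, match="impute"):
        permutation_fdr(m, TestParams(seed=1))
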