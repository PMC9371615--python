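"""Two-sample testing per phosphosite with permutation-based FDR control.

Each site gets a pooled-variance two-sided Student t statistic (optionally
SAM-style regularized by a fudge factor s0). Significance is decided by a
permutation estimate of the false discovery rate at q (default 0.05): group
labels are permuted — exhaustively when the number of distinct labelings is
small, otherwise by random draws — and the expected number of null sites
exceeding each observed |t| threshold is compared with the observed count.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .io_tables import SiteIntensityMatrix


@dataclasses.dataclass(frozen=True)
class TestParams:
    q: float = 0.05
    s0: float = 0.0
    n_perm: int = 250
    exhaustive_below: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ConfigError("q must be in (0, 1)")
        if self.s0 < 0:
            raise ConfigError("s0 must be >= 0")
        if self.n_perm < 10:
            raise ConfigError("n_perm must be >= 10")


@dataclasses.dataclass
class DifferentialResult:
    """Per-site differential table plus direction lists among significant sites.

    ``table`` columns: the site key columns, n_<groupA>, n_<groupB>,
    diff (mean A - mean B, log2 units), t, p, fdr, significant, direction.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    higher_in_a: pd.DataFrame
    higher_in_b: pd.DataFrame
    n_permutations: int
    exhaustive: bool
    notes: list[str]


def two_sample_t(x, y, s0: float = 0.0) -> tuple[float, float, float]:
    """Pooled-variance two-sample t test: returns (t, p, diff).

    diff = mean(x) - mean(y); t = diff / (pooled SE + s0). The two-sided
    p-value is from the t distribution with |x|+|y|-2 df evaluated at the
    unregularized (s0 = 0) statistic; ranking uses the returned t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each group needs at least 2 values")
    nx, ny = x.size, y.size
    diff = float(np.mean(x) - np.mean(y))
    df = nx + ny - 2
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    se = float(np.sqrt(sp2 * (1.0 / nx + 1.0 / ny)))
    if se == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, diff
        if s0 == 0.0:
            return float(np.sign(diff) * np.inf), 0.0, diff
        return diff / s0, 0.0, diff
    t0 = diff / se
    p = float(2.0 * stats.t.sf(abs(t0), df))
    return diff / (se + s0), p, diff


def _t_for_labeling(data: np.ndarray, mask_a: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized per-row pooled t for one labeling (mask_a marks group A)."""
    a = data[:, mask_a]
    b = data[:, ~mask_a]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (se + s0)
    if s0 == 0.0:
        t = np.where(se == 0.0, np.sign(diff) * np.inf, t)
    t = np.where((se + s0 == 0.0) & (diff == 0.0), 0.0, t)
    return t


def _labelings(n: int, n_a: int, params: TestParams) -> tuple[list[tuple[int, ...]], bool, list[str]]:
    """Distinct index-sets for group A under the permutation scheme."""
    notes: list[str] = []
    total = comb(n, n_a)
    identity = tuple(range(n_a))
    if total <= params.exhaustive_below:
        return list(itertools.combinations(range(n), n_a)), True, notes
    if params.n_perm >= total - 1:
        notes.append(
            f"n_perm={params.n_perm} >= {total - 1} distinct non-identity labelings; "
            "switched to exhaustive enumeration"
        )
        return list(itertools.combinations(range(n), n_a)), True, notes
    if params.seed is None:
        raise ConfigError("random permutation mode requires a seed")
    rng = np.random.default_rng([params.seed, 0x7065726D])
    draws: list[tuple[int, ...]] = []
    while len(draws) < params.n_perm:
        pick = tuple(sorted(rng.permutation(n)[:n_a].tolist()))
        if pick != identity:
            draws.append(pick)
    return draws, False, notes


def permutation_fdr(
    logm: SiteIntensityMatrix, params: TestParams = TestParams()
) -> DifferentialResult:
    """Permutation-FDR two-sample test over a complete (imputed) log2 matrix.

    For each site's observed |t| taken as a threshold (sites ranked by
    descending |t|, ties broken by row order), the estimated FDR is the mean
    permutation count of |t| values at or above the threshold divided by the
    observed count, clipped to [0, 1]; each site then gets the smallest such
    estimate at its own or any weaker threshold (a cumulative minimum from
    the bottom of the ranking), so FDR is monotone non-decreasing in rank.
    A site is significant when its monotone FDR is at or below q.
    """
    groups = logm.groups()
    if len(groups) != 2:
        raise InputError(f"need exactly two groups, got {sorted(groups)}")
    (ga, cols_a), (gb, cols_b) = groups.items()
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise InputError("each group needs at least 2 included samples")

    data = logm.values[cols_a + cols_b].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise InputError("matrix contains missing values; impute before testing")

    n = data.shape[1]
    n_a = len(cols_a)
    identity_mask = np.zeros(n, dtype=bool)
    identity_mask[:n_a] = True

    t_obs = _t_for_labeling(data, identity_mask, params.s0)
    diff = data[:, :n_a].mean(axis=1) - data[:, n_a:].mean(axis=1)
    # reference p-values from the unregularized statistic
    t_raw = _t_for_labeling(data, identity_mask, 0.0)
    p = 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t_raw), t_raw, np.inf)), n - 2)
    p = np.where(np.isinf(t_raw), 0.0, p)

    labelings, exhaustive, notes = _labelings(n, n_a, params)
    perm_abs = np.empty((len(labelings), len(t_obs)))
    for i, idx in enumerate(labelings):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        perm_abs[i] = np.abs(_t_for_labeling(data, mask, params.s0))

    abs_obs = np.abs(t_obs)
    order = np.lexsort((np.arange(len(abs_obs)), -abs_obs))  # desc |t|, row-order ties
    obs_sorted = np.sort(abs_obs)
    perm_sorted = np.sort(perm_abs.ravel())
    n_perms = len(labelings)

    fdr = np.empty(len(abs_obs))
    thresholds = abs_obs[order]
    n_obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, thresholds, side="left")
    mean_perm_ge = (
        perm_sorted.size - np.searchsorted(perm_sorted, thresholds, side="left")
    ) / n_perms
    raw = np.clip(mean_perm_ge / n_obs_ge, 0.0, 1.0)
    # q-value: smallest raw FDR estimate at this or any weaker threshold,
    # so the estimate is monotone non-decreasing down the |t| ranking
    fdr[order] = np.minimum.accumulate(raw[::-1])[::-1]
    significant = fdr <= params.q

    table = logm.sites.copy()
    table[f"n_{ga}"] = len(cols_a)
    table[f"n_{gb}"] = len(cols_b)
    table["diff"] = diff
    table["t"] = t_obs
    table["p"] = p
    table["fdr"] = fdr
    table["significant"] = significant
    table["direction"] = np.where(
        ~significant, "", np.where(diff > 0, f"higher_in_{ga}", f"higher_in_{gb}")
    )

    sig = table.loc[significant]
    return DifferentialResult(
        table=table,
        group_a=ga,
        group_b=gb,
        higher_in_a=sig.loc[sig["diff"] > 0].reset_index(drop=True),
        higher_in_b=sig.loc[sig["diff"] < 0].reset_index(drop=True),
        n_permutations=n_perms,
        exhaustive=exhaustive,
        notes=notes,
    )
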