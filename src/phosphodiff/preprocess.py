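"""Log transform, median normalization, detection counting, validity
filtering and sample-correlation QC of the intensity matrix.

The statistical stage operates on log2 intensities normalized per sample by
median subtraction, and retains only sites quantified in at least
``min_valid`` samples of at least one treatment group (default 3).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .io_tables import SampleMeta, SiteIntensityMatrix


@dataclasses.dataclass(frozen=True)
class FilterParams:
    """Validity filter: keep a site if some group has >= min_valid values."""

    min_valid: int = 3

    def __post_init__(self) -> None:
        if self.min_valid < 1:
            raise ConfigError("min_valid must be >= 1")


@dataclasses.dataclass
class DetectionMatrix:
    """Boolean detected/missing pattern with per-group detection counts.

    ``detected`` is aligned row-for-row with the source matrix's sites;
    ``group_counts`` has one integer column per group, counting detections
    over included samples only.
    """

    detected: pd.DataFrame
    group_counts: pd.DataFrame
    group_sizes: dict[str, int]


@dataclasses.dataclass
class QCReport:
    """Per-sample mean pairwise correlation and outlier flags.

    ``table`` columns: sample_id, mean_correlation, n_pairs_used, flagged.
    ``incomputable_pairs`` lists sample pairs with fewer shared present
    values than ``min_shared``; such pairs contribute nothing to the means.
    Flagged samples are reported only — exclusion is an explicit config act.
    """

    table: pd.DataFrame
    incomputable_pairs: list[tuple[str, str]]
    threshold: float


def log2_transform(matrix: SiteIntensityMatrix) -> SiteIntensityMatrix:
    """log2 every present intensity; missing cells stay missing."""
    if matrix.log_scale:
        raise InputError("matrix is already on the log2 scale")
    vals = matrix.values.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise InputError("present intensities must be > 0 before log2 transform")
    out = matrix.copy()
    out.values = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    out.log_scale = True
    return out


def median_normalize(logm: SiteIntensityMatrix) -> SiteIntensityMatrix:
    """Subtract each sample column's present-value median from that column.

    Present-value medians are used so that missing-not-at-random cells do not
    distort centering; afterwards every column's present-value median is 0.
    """
    if not logm.log_scale:
        raise InputError("median normalization expects log2 values")
    out = logm.copy()
    for s in logm.samples:
        col = out.values[s.sample_id]
        med = col.median(skipna=True)
        if s.included and np.isnan(med):
            raise InputError(f"sample '{s.sample_id}' has no present values")
        if not np.isnan(med):
            out.values[s.sample_id] = col - med
    return out


def detection_matrix(matrix: SiteIntensityMatrix) -> DetectionMatrix:
    """Detected (present) pattern and per-group counts over included samples."""
    detected = matrix.values.notna()
    groups = matrix.groups()
    counts = pd.DataFrame(
        {g: detected[cols].sum(axis=1).astype(int) for g, cols in groups.items()}
    )
    return DetectionMatrix(
        detected=detected,
        group_counts=counts,
        group_sizes={g: len(cols) for g, cols in groups.items()},
    )


def filter_min_valid(
    logm: SiteIntensityMatrix, params: FilterParams = FilterParams()
) -> tuple[SiteIntensityMatrix, pd.DataFrame]:
    """Retain sites with >= min_valid present values in at least one group.

    Returns the retained matrix (input order preserved) and the site keys of
    the dropped rows.
    """
    det = detection_matrix(logm)
    if not det.group_sizes:
        raise ConfigError("no included samples")
    if all(size < params.min_valid for size in det.group_sizes.values()):
        raise ConfigError(
            f"min_valid={params.min_valid} exceeds every group size {det.group_sizes}"
        )
    keep = (det.group_counts >= params.min_valid).any(axis=1).to_numpy()
    dropped = logm.sites.loc[~keep].reset_index(drop=True)
    return logm.subset_rows(keep), dropped


def sample_qc(
    logm: SiteIntensityMatrix, threshold: float = 0.7, min_shared: int = 3
) -> QCReport:
    """Mean pairwise product-moment correlation per included sample.

    Correlations use pairwise-complete present values; pairs sharing fewer
    than ``min_shared`` values are recorded as incomputable and excluded from
    the means. A sample whose mean correlation falls below ``threshold`` is
    flagged (not removed).
    """
    ids = [s.sample_id for s in logm.included_samples()]
    if len(ids) < 3:
        raise InputError("sample QC needs at least 3 included samples")

    sums = {sid: 0.0 for sid in ids}
    counts = {sid: 0 for sid in ids}
    incomputable: list[tuple[str, str]] = []
    for a, b in itertools.combinations(ids, 2):
        xa = logm.values[a].to_numpy(dtype=float)
        xb = logm.values[b].to_numpy(dtype=float)
        shared = np.isfinite(xa) & np.isfinite(xb)
        if shared.sum() < min_shared:
            incomputable.append((a, b))
            continue
        r = np.corrcoef(xa[shared], xb[shared])[0, 1]
        if np.isnan(r):  # zero variance in a shared slice
            incomputable.append((a, b))
            continue
        for sid in (a, b):
            sums[sid] += r
            counts[sid] += 1

    table = pd.DataFrame(
        {
            "sample_id": ids,
            "mean_correlation": [
                sums[sid] / counts[sid] if counts[sid] else np.nan for sid in ids
            ],
            "n_pairs_used": [counts[sid] for sid in ids],
        }
    )
    table["flagged"] = table["mean_correlation"] < threshold
    return QCReport(table=table, incomputable_pairs=incomputable, threshold=threshold)


def apply_exclusions(
    samples: list[SampleMeta], excluded_ids: list[str]
) -> list[SampleMeta]:
    """Return sample metadata with the named samples marked not included."""
    known = {s.sample_id for s in samples}
    unknown = [e for e in excluded_ids if e not in known]
    if unknown:
        raise ConfigError(f"excluded samples not present in the sample map: {unknown}")
    return [
        dataclasses.replace(s, included=False) if s.sample_id in excluded_ids else s
        for s in samples
    ]
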