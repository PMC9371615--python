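"""Synthetic label-free phosphoproteomics datasets with known ground truth.

The simulator emulates the two-group study design (4 DMSO vs 5 neratinib
samples after quality exclusion): per-site baseline log2 abundance, a
fraction of group-shifted sites, a fraction of group-exclusive
("presence/absence") sites whose abundance in the off group sits far below
the detection limit, and left-censored missingness through a logistic
detection model P(detect | x) = 1 / (1 + exp(-(x - m)/s)). Output uses the
same table dialect the reader consumes, so end-to-end tests exercise I/O.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diffstats import DifferentialResult
from .errors import ConfigError, InputError
from .io_tables import SampleMeta, SiteIntensityMatrix
from .presence import NEITHER, PresenceClassification

CLASS_NULL = "null"
CLASS_SHIFTED = "shifted"
CLASS_PRESENCE_ABSENCE = "presence_absence"

_RESIDUES = np.array(["S", "T", "Y"])
_RESIDUE_PROBS = np.array([0.75, 0.2, 0.05])  # typical phosphosite composition


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults mirror the study design.

    Abundances are on the log2 scale. ``effect_size`` is the shift magnitude
    in log2 units for affected sites (sign random); with the default residual
    SD of 0.5 the default shift of 1.0 is two residual SDs. The logistic
    detection midpoint/scale produce left-censored missingness of roughly
    10-15% at the default baseline distribution.
    """

    n_sites: int = 1000
    group_a: str = "DMSO"
    group_b: str = "neratinib"
    n_group_a: int = 4
    n_group_b: int = 5
    baseline_mean: float = 23.0
    baseline_sd: float = 2.0
    residual_sd: float = 0.5
    effect_fraction: float = 0.1
    effect_size: float = 1.0
    effect_distribution: str = "fixed"  # or "half_normal"
    presence_absence_fraction: float = 0.05
    detection_midpoint: float = 20.0
    detection_scale: float = 1.0
    n_proteins: int | None = None
    n_terms: int = 0
    term_size: int = 25
    n_enriched_terms: int = 0
    enriched_term_hit_rate: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ConfigError("group sizes must be >= 2")
        for name in ("effect_fraction", "presence_absence_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.effect_fraction + self.presence_absence_fraction > 1.0:
            raise ConfigError("site-class fractions sum to more than 1")
        if self.detection_scale < 0:
            raise ConfigError("detection_scale must be >= 0")
        if self.residual_sd <= 0 or self.baseline_sd <= 0:
            raise ConfigError("baseline_sd and residual_sd must be > 0")
        if self.effect_distribution not in ("fixed", "half_normal"):
            raise ConfigError(f"unknown effect distribution '{self.effect_distribution}'")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset.

    ``sites`` columns: protein, position, residue, multiplicity, class,
    true_effect (signed log2 shift; exactly 0 for null sites), off_group
    (the non-expressing group of a presence/absence site, else "").
    ``terms`` columns (when an annotation model was simulated): term,
    truly_enriched.
    """

    sites: pd.DataFrame
    terms: pd.DataFrame | None = None
    annotations: "pd.DataFrame | None" = None  # protein, term pairs


@dataclasses.dataclass
class RecoveryMetrics:
    """How well the pipeline recovered the simulated truth; all in [0, 1]."""

    power: float
    fdp: float
    pa_sensitivity: float
    pa_specificity: float
    n_called: int

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _detection_prob(x: np.ndarray, m: float, s: float) -> np.ndarray:
    if s == 0.0:  # hard threshold limit
        return (x > m).astype(float)
    return 1.0 / (1.0 + np.exp(-(x - m) / s))


def simulate_phospho_dataset(
    params: SimulationParams,
) -> tuple[SiteIntensityMatrix, SyntheticTruth]:
    """Draw one dataset; same params and seed give byte-identical output."""
    if params.seed is None:
        raise ConfigError("simulation requires an explicit seed")
    rng = np.random.default_rng([params.seed, 0x73696D])

    n = params.n_sites
    n_pa = int(round(n * params.presence_absence_fraction))
    n_shift = int(round(n * params.effect_fraction))
    classes = np.array(
        [CLASS_PRESENCE_ABSENCE] * n_pa
        + [CLASS_SHIFTED] * n_shift
        + [CLASS_NULL] * (n - n_pa - n_shift)
    )
    rng.shuffle(classes)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, n)
    signs = rng.choice([-1.0, 1.0], n)
    if params.effect_distribution == "fixed":
        magnitudes = np.full(n, params.effect_size)
    else:
        magnitudes = np.abs(rng.normal(0.0, params.effect_size, n))
    effects = np.where(classes == CLASS_SHIFTED, signs * magnitudes, 0.0)

    # presence/absence sites: expressed in one group, far below the detection
    # limit in the other
    off_group = np.where(
        classes == CLASS_PRESENCE_ABSENCE,
        np.where(rng.random(n) < 0.5, params.group_a, params.group_b),
        "",
    )
    off_abundance = params.detection_midpoint - 6.0 * max(params.detection_scale, 1.0)

    samples = [
        SampleMeta(f"{params.group_a}_{i + 1}", params.group_a)
        for i in range(params.n_group_a)
    ] + [
        SampleMeta(f"{params.group_b}_{i + 1}", params.group_b)
        for i in range(params.n_group_b)
    ]
    is_b = np.array([s.group == params.group_b for s in samples])

    log2_true = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        site_level = baseline + effects * (1.0 if is_b[j] else 0.0)
        site_level = np.where(off_group == s.group, off_abundance, site_level)
        log2_true[:, j] = site_level + rng.normal(0.0, params.residual_sd, n)

    detect = rng.random(log2_true.shape) < _detection_prob(
        log2_true, params.detection_midpoint, params.detection_scale
    )
    raw = np.where(detect, np.exp2(log2_true), np.nan)

    n_proteins = params.n_proteins or max(1, int(np.ceil(n / 3)))
    protein_idx = rng.integers(0, n_proteins, n)
    proteins = np.array([f"PROT{i:05d}" for i in protein_idx])
    # unique positions within each protein
    position = np.zeros(n, dtype=int)
    seen: dict[int, int] = {}
    for i, pi in enumerate(protein_idx):
        seen[pi] = seen.get(pi, 0) + 1
        position[i] = seen[pi] * 7 + 1
    residues = rng.choice(_RESIDUES, n, p=_RESIDUE_PROBS)

    sites = pd.DataFrame(
        {
            "protein": proteins,
            "position": position,
            "residue": residues,
            "multiplicity": np.ones(n, dtype=int),
        }
    )
    matrix = SiteIntensityMatrix(
        sites=sites,
        samples=samples,
        values=pd.DataFrame(raw, columns=[s.sample_id for s in samples]),
    )
    truth_sites = sites.copy()
    truth_sites["class"] = classes
    truth_sites["true_effect"] = effects
    truth_sites["off_group"] = off_group

    terms_df = annotations_df = None
    if params.n_terms > 0:
        terms_df, annotations_df = _simulate_annotations(
            params, rng, truth_sites, n_proteins
        )
    return matrix, SyntheticTruth(sites=truth_sites, terms=terms_df, annotations=annotations_df)


def _simulate_annotations(
    params: SimulationParams,
    rng: np.random.Generator,
    truth_sites: pd.DataFrame,
    n_proteins: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Term model: enriched terms sample mostly from affected proteins."""
    all_proteins = np.array(sorted(truth_sites["protein"].unique()))
    affected = np.array(
        sorted(truth_sites.loc[truth_sites["class"] != CLASS_NULL, "protein"].unique())
    )
    pairs = []
    term_rows = []
    for t in range(params.n_terms):
        term = f"TERM{t:04d}"
        enriched = t < params.n_enriched_terms
        size = min(params.term_size, len(all_proteins))
        if enriched and len(affected) > 0:
            n_hit = int(round(size * params.enriched_term_hit_rate))
            n_hit = min(n_hit, len(affected))
            members = set(rng.choice(affected, n_hit, replace=False))
            rest = np.array(sorted(set(all_proteins) - members))
            extra = rng.choice(rest, min(size - n_hit, len(rest)), replace=False)
            members |= set(extra)
        else:
            members = set(rng.choice(all_proteins, size, replace=False))
        term_rows.append({"term": term, "truly_enriched": enriched})
        pairs.extend({"protein": p, "term": term} for p in sorted(members))
    return pd.DataFrame(term_rows), pd.DataFrame(pairs)


def evaluate_calls(
    diff: DifferentialResult | None,
    classification: PresenceClassification | None,
    truth: SyntheticTruth,
) -> RecoveryMetrics:
    """Score significance calls and presence labels against the truth.

    Power = fraction of shifted sites called significant; FDP = fraction of
    called sites whose truth class is null (0 when nothing is called);
    presence sensitivity/specificity score the detection-pattern labels.
    Site keys must align between results and truth.
    """
    key_cols = ["protein", "position", "multiplicity"]
    truth_keyed = truth.sites.set_index(key_cols)

    power = fdp = 0.0
    n_called = 0
    if diff is not None:
        table = diff.table.set_index(key_cols)
        missing = table.index.difference(truth_keyed.index)
        if len(missing):
            raise InputError(f"{len(missing)} tested sites absent from truth")
        tclass = truth_keyed.loc[table.index, "class"]
        called = table["significant"].to_numpy()
        n_called = int(called.sum())
        shifted_tested = (tclass == CLASS_SHIFTED).to_numpy()
        n_shifted_total = int((truth.sites["class"] == CLASS_SHIFTED).sum())
        if n_shifted_total:
            power = float((called & shifted_tested).sum() / n_shifted_total)
        if n_called:
            fdp = float((called & (tclass == CLASS_NULL).to_numpy()).sum() / n_called)

    pa_sens = pa_spec = 0.0
    if classification is not None:
        ctab = classification.table.set_index(key_cols)
        missing = ctab.index.difference(truth_keyed.index)
        if len(missing):
            raise InputError(f"{len(missing)} classified sites absent from truth")
        tsub = truth_keyed.loc[ctab.index]
        is_pa = (tsub["class"] == CLASS_PRESENCE_ABSENCE).to_numpy()
        labels = ctab["label"].to_numpy()
        # a presence/absence site is recovered when labeled enriched in the
        # group where it IS expressed, i.e. the group opposite its off_group
        on_group = np.where(
            np.isin(tsub["off_group"], classification.groups),
            np.where(
                tsub["off_group"] == classification.groups[0],
                classification.groups[1],
                classification.groups[0],
            ),
            "",
        )
        if is_pa.sum():
            pa_sens = float((is_pa & (labels == on_group)).sum() / is_pa.sum())
        if (~is_pa).sum():
            pa_spec = float((~is_pa & (labels == NEITHER)).sum() / (~is_pa).sum())

    return RecoveryMetrics(
        power=power, fdp=fdp, pa_sensitivity=pa_sens, pa_specificity=pa_spec, n_called=n_called
    )
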