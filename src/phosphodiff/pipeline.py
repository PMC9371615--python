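"""End-to-end orchestration of the differential phosphoproteomic analysis.

Stage order: read -> log2 -> median-normalize -> sample QC (report only) ->
presence classification on the pre-imputation detection pattern ->
minimum-valid-values filter -> downshifted imputation -> permutation-FDR
two-sample test -> protein collapsing -> hypergeometric term enrichment ->
write results. Sample exclusions are explicit config actions applied at read
time; presence classification must precede imputation because imputation
destroys the detection pattern. Identical config and seed give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diffstats, enrichment, impute, io_tables, preprocess, presence
from .errors import ConfigError

logger = logging.getLogger("phosphodiff")


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; the master seed is mandatory."""

    site_table: Path
    out_dir: Path
    samples: list[io_tables.SampleMeta]
    seed: int
    annotations: Path | None = None
    filter_params: preprocess.FilterParams = dataclasses.field(
        default_factory=preprocess.FilterParams
    )
    imputation_params: impute.ImputationParams = dataclasses.field(
        default_factory=impute.ImputationParams
    )
    test_params: diffstats.TestParams = dataclasses.field(default_factory=diffstats.TestParams)
    presence_params: presence.PresenceParams = dataclasses.field(
        default_factory=presence.PresenceParams
    )
    qc_threshold: float = 0.7
    enrichment_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path = Path(".")) -> "PipelineConfig":
        def _path(key: str, required: bool = True) -> Path | None:
            if key not in raw:
                if required:
                    raise ConfigError(f"config lacks required key '{key}'")
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base_dir / p

        if "seed" not in raw:
            raise ConfigError("config must set a master seed")
        samples_raw = raw.get("samples")
        if not samples_raw:
            raise ConfigError("config must list samples with group labels")
        samples = [
            io_tables.SampleMeta(
                sample_id=str(s["sample_id"]),
                group=str(s["group"]),
                included=bool(s.get("included", True)),
            )
            for s in samples_raw
        ]
        seed = int(raw["seed"])
        imp = dict(raw.get("imputation", {}))
        imp.setdefault("seed", seed)
        test = dict(raw.get("test", {}))
        test.setdefault("seed", seed)
        pres = dict(raw.get("presence", {}))
        return cls(
            site_table=_path("site_table"),
            out_dir=_path("out_dir"),
            annotations=_path("annotations", required=False),
            samples=samples,
            seed=seed,
            filter_params=preprocess.FilterParams(**raw.get("filter", {})),
            imputation_params=impute.ImputationParams(**imp),
            test_params=diffstats.TestParams(**test),
            presence_params=presence.PresenceParams(**pres),
            qc_threshold=float(raw.get("qc", {}).get("threshold", 0.7)),
            enrichment_alpha=float(raw.get("enrichment", {}).get("alpha", 0.05)),
        )


@dataclasses.dataclass
class RunManifest:
    """Provenance of one run: parameters, per-stage row counts, outputs."""

    timestamp: str
    seed: int
    excluded_samples: list[str]
    stage_counts: dict[str, int]
    outputs: dict[str, Path]
    notes: list[str]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage under one config; see the module docstring for order."""
    notes: list[str] = []

    logger.info("reading site table %s", config.site_table)
    matrix = io_tables.read_site_table(config.site_table, config.samples)
    excluded = [s.sample_id for s in config.samples if not s.included]
    if excluded:
        logger.info("excluded samples: %s", excluded)

    logm = preprocess.median_normalize(preprocess.log2_transform(matrix))

    qc = preprocess.sample_qc(logm, threshold=config.qc_threshold)
    for row in qc.table.loc[qc.table["flagged"]].itertuples():
        logger.warning(
            "sample %s flagged: mean correlation %.3f < %.3f",
            row.sample_id, row.mean_correlation, config.qc_threshold,
        )

    det = preprocess.detection_matrix(matrix)
    classification = presence.classify_sites(det, matrix.sites, config.presence_params)

    filtered, dropped = preprocess.filter_min_valid(logm, config.filter_params)
    logger.info("validity filter kept %d of %d sites", filtered.n_sites, logm.n_sites)

    imputed, mask, imp_notes = impute.impute_downshift(filtered, config.imputation_params)
    notes.extend(imp_notes)

    diff = diffstats.permutation_fdr(imputed, config.test_params)
    notes.extend(diff.notes)
    logger.info(
        "%d significant sites at q=%.3g (%s permutations)",
        int(diff.table["significant"].sum()),
        config.test_params.q,
        "exhaustive" if diff.exhaustive else diff.n_permutations,
    )

    tables: dict[str, pd.DataFrame] = {
        "qc_report": qc.table,
        "dropped_sites": dropped,
        "imputation_mask": pd.concat([filtered.sites, mask.astype(int)], axis=1),
        "differential": diff.table,
        "presence_classification": classification.table,
        "presence_summary": classification.summary(),
    }
    for g in classification.groups:
        tables[f"proteins_{g}"] = pd.DataFrame({"protein": classification.proteins[g]})

    if config.annotations is not None:
        ann = io_tables.read_annotation_table(config.annotations)
        background = set(filtered.sites["protein"].unique())
        for g in classification.groups:
            selected = set(classification.proteins[g]) & background
            skipped = set(classification.proteins[g]) - background
            if skipped:
                notes.append(
                    f"{len(skipped)} {g}-enriched proteins outside the quantified "
                    "background were excluded from enrichment"
                )
            tables[f"enrichment_{g}"] = enrichment.enrich_terms(
                selected, background, ann, alpha=config.enrichment_alpha
            )

    manifest_info: dict[str, object] = {
        "seed": config.seed,
        "excluded_samples": ",".join(excluded),
        "min_valid": config.filter_params.min_valid,
        "imputation_width": config.imputation_params.width,
        "imputation_downshift": config.imputation_params.downshift,
        "imputation_mode": config.imputation_params.mode,
        "test_q": config.test_params.q,
        "test_s0": config.test_params.s0,
        "test_permutations": diff.n_permutations,
        "test_exhaustive": diff.exhaustive,
        "presence_max_out": config.presence_params.max_out,
        "enrichment_alpha": config.enrichment_alpha,
        "notes": " | ".join(notes),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    outputs = io_tables.write_results(tables, config.out_dir, manifest_info)

    return RunManifest(
        timestamp=str(manifest_info["timestamp"]),
        seed=config.seed,
        excluded_samples=excluded,
        stage_counts={
            "input_sites": matrix.n_sites,
            "classified_sites": len(classification.table),
            "filtered_sites": filtered.n_sites,
            "tested_sites": len(diff.table),
            "significant_sites": int(diff.table["significant"].sum()),
        },
        outputs=outputs,
        notes=notes,
    )
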