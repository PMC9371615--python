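"""End-to-end run on a simulated dataset with known ground truth.

Simulates a study-shaped experiment (4 DMSO vs 5 neratinib samples, 1000
phosphosites, 10% shifted by two residual SDs, 5% group-exclusive), writes
the site table in the MaxQuant-style dialect, runs the full pipeline, and
summarizes the presence/absence classification.
"""

import tempfile
from pathlib import Path

from phosphodiff import (
    ImputationParams,
    PipelineConfig,
    SimulationParams,
    TestParams,
    classify_sites,
    detection_matrix,
    run_pipeline,
    simulate_phospho_dataset,
    write_site_table,
)

workdir = Path(tempfile.mkdtemp(prefix="phosphodiff_demo_"))
params = SimulationParams(n_sites=1000, seed=42)
matrix, truth = simulate_phospho_dataset(params)
table = workdir / "sites.tsv"
write_site_table(matrix, table)

config = PipelineConfig(
    site_table=table,
    out_dir=workdir / "results",
    samples=list(matrix.samples),
    seed=42,
    imputation_params=ImputationParams(seed=42),
    test_params=TestParams(seed=42),
)
manifest = run_pipeline(config)

print("stage counts:")
for stage, count in manifest.stage_counts.items():
    print(f"  {stage}: {count}")

cls = classify_sites(detection_matrix(matrix), matrix.sites)
print("\npresence/absence summary (sites detected in nearly all of one group,")
print("almost none of the other, and the proteins they collapse to):")
print(cls.summary().to_string(index=False))

print(f"\nresults written to {manifest.outputs['run_manifest'].parent}")
print(
    "significant_sites counts phosphosites whose permutation-estimated FDR "
    "is at or below q=0.05; with groups of 4 and 5 samples only the largest "
    "shifts clear that bar, mirroring real studies of this size."
)
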