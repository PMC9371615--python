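"""The detection-pattern ("presence/absence") enrichment rule in isolation.

Builds a tiny intensity matrix by hand and shows how detection counts map to
group-enrichment labels under the study-shaped thresholds: detected in >= 3
of 4 DMSO samples and <= 1 of 5 neratinib samples (or >= 4 of 5 neratinib
and <= 1 of 4 DMSO).
"""

import numpy as np
import pandas as pd

from phosphodiff import SampleMeta, SiteIntensityMatrix, classify_sites, detection_matrix

samples = [SampleMeta(f"DMSO_{i}", "DMSO") for i in range(1, 5)] + [
    SampleMeta(f"ner_{i}", "neratinib") for i in range(1, 6)
]

# four sites with hand-picked detection patterns (NaN = not detected)
patterns = {
    "NPM1_S4": [1, 1, 1, 0, 0, 0, 0, 0, 0],  # 3 of 4 DMSO, 0 of 5 ner
    "ABC1_S10": [1, 1, 0, 0, 1, 1, 0, 0, 0],  # 2 vs 2: neither
    "XYZ2_T55": [0, 1, 0, 0, 1, 1, 1, 1, 1],  # 1 of 4 DMSO, 5 of 5 ner
    "DEF3_S99": [1, 1, 1, 1, 1, 1, 1, 1, 1],  # everywhere: neither
}
values = np.where(np.array(list(patterns.values()), dtype=float) > 0, 1e6, np.nan)
sites = pd.DataFrame(
    {
        "protein": [k.split("_")[0] for k in patterns],
        "position": [int(k.split("_")[1][1:]) for k in patterns],
        "residue": [k.split("_")[1][0] for k in patterns],
        "multiplicity": 1,
    }
)
matrix = SiteIntensityMatrix(
    sites=sites, samples=samples, values=pd.DataFrame(values, columns=[s.sample_id for s in samples])
)

cls = classify_sites(detection_matrix(matrix), matrix.sites)
print(cls.table[["protein", "position", "detected_DMSO", "detected_neratinib", "label"]].to_string(index=False))
print(
    "\nA label names the group a site is exclusive to; 'neither' means the "
    "detection pattern is not one-sided enough. The rule never looks at "
    "intensity magnitudes, only at which cells are present."
)
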