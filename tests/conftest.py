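import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phosphodiff import SampleMeta, SiteIntensityMatrix

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture
def two_group_samples() -> list[SampleMeta]:
    """Study-shaped design: 4 DMSO vs 5 neratinib samples."""
    return [SampleMeta(f"DMSO_{i}", "DMSO") for i in range(1, 5)] + [
        SampleMeta(f"ner_{i}", "neratinib") for i in range(1, 6)
    ]


def make_matrix(values, samples, log_scale=False, proteins=None) -> SiteIntensityMatrix:
    """Small matrix builder: values is an n_sites x n_samples array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    sites = pd.DataFrame(
        {
            "protein": proteins if proteins is not None else [f"P{i}" for i in range(n)],
            "position": np.arange(1, n + 1) * 3,
            "residue": ["S"] * n,
            "multiplicity": [1] * n,
        }
    )
    return SiteIntensityMatrix(
        sites=sites,
        samples=list(samples),
        values=pd.DataFrame(values, columns=[s.sample_id for s in samples]),
        log_scale=log_scale,
    )


@pytest.fixture
def site_table_text() -> str:
    """Minimal tab-delimited site table in the MaxQuant-style dialect."""
    header = "Protein\tPosition\tAmino acid\tMultiplicity\tReverse\tPotential contaminant\tIntensity s1\tIntensity s2"
    rows = [
        "P1\t12\tS\t1\t\t\t1000\t2000",
        "P2\t40\tT\t1\t\t\t0\t512",
    ]
    return "\n".join([header] + rows) + "\n"
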