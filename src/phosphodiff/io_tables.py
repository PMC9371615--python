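"""Reading and writing phosphosite intensity tables and annotation maps.

The input dialect is a subset of the MaxQuant "Phospho (STY)Sites" expanded
site table: one row per phosphosite x multiplicity state, tab-delimited,
with per-sample raw intensity columns named ``Intensity <sample_id>``.
Zero intensities and blank cells both mean "not detected" (MaxQuant writes 0
for unquantified sites); they are stored as missing, never as a number.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

SITE_KEY_COLUMNS = ["protein", "position", "residue", "multiplicity"]
VALID_RESIDUES = frozenset({"S", "T", "Y"})

# canonical column names of the table dialect
_COL_PROTEIN = "Protein"
_COL_POSITION = "Position"
_COL_RESIDUE = "Amino acid"
_COL_MULTIPLICITY = "Multiplicity"
_COL_REVERSE = "Reverse"
_COL_CONTAMINANT = "Potential contaminant"
_INTENSITY_PREFIX = "Intensity "


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """One mass-spectrometry sample: column id, treatment group, inclusion flag.

    ``included=False`` removes the sample from every downstream computation
    (the explicit-exclusion mechanism for poorly correlating replicates).
    """

    sample_id: str
    group: str
    included: bool = True


@dataclasses.dataclass
class SiteIntensityMatrix:
    """Phosphosite x sample intensity grid with site and sample metadata.

    ``sites`` holds one row per site x multiplicity state with columns
    ``protein, position, residue, multiplicity``; ``values`` is a float frame
    aligned row-for-row with ``sites`` whose columns are sample ids and whose
    missing entries are NaN. ``log_scale`` records whether values are log2.
    """

    sites: pd.DataFrame
    samples: list[SampleMeta]
    values: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise InputError("value columns do not match the sample metadata order")
        if len(self.sites) != len(self.values):
            raise InputError("site table and value grid have different row counts")
        vals = self.values.to_numpy()
        if not self.log_scale and np.any(vals[np.isfinite(vals)] < 0):
            raise InputError("negative raw intensities are not allowed")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def included_samples(self) -> list[SampleMeta]:
        return [s for s in self.samples if s.included]

    def groups(self) -> dict[str, list[str]]:
        """Included sample ids per group, groups in order of first appearance."""
        out: dict[str, list[str]] = {}
        for s in self.included_samples():
            out.setdefault(s.group, []).append(s.sample_id)
        return out

    def included_values(self) -> pd.DataFrame:
        return self.values[[s.sample_id for s in self.included_samples()]]

    def copy(self) -> "SiteIntensityMatrix":
        return SiteIntensityMatrix(
            sites=self.sites.copy(),
            samples=list(self.samples),
            values=self.values.copy(),
            log_scale=self.log_scale,
        )

    def subset_rows(self, mask: np.ndarray) -> "SiteIntensityMatrix":
        """Row subset preserving order; ``mask`` is boolean or positional."""
        return SiteIntensityMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            values=self.values.loc[mask].reset_index(drop=True),
            log_scale=self.log_scale,
        )


@dataclasses.dataclass
class AnnotationMap:
    """Protein accession -> set of annotation term ids, with term names."""

    protein_to_terms: dict[str, set[str]]
    term_names: dict[str, str] = dataclasses.field(default_factory=dict)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.protein_to_terms.values():
            out |= ts
        return out

    def proteins_with_term(self, term: str, universe: Iterable[str]) -> set[str]:
        return {p for p in universe if term in self.protein_to_terms.get(p, ())}


def read_site_table(path: str | Path, sample_map: list[SampleMeta]) -> SiteIntensityMatrix:
    """Parse a tab-delimited phosphosite table into a :class:`SiteIntensityMatrix`.

    Rows flagged as reverse decoys or potential contaminants ("+") are dropped.
    Intensity cells that are 0 or empty become missing. Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    missing_cols = [
        c for c in (_COL_PROTEIN, _COL_POSITION, _COL_RESIDUE, _COL_MULTIPLICITY)
        if c not in df.columns
    ]
    if missing_cols:
        raise InputError(f"site table lacks required columns: {missing_cols}")

    for s in sample_map:
        if _INTENSITY_PREFIX + s.sample_id not in df.columns:
            raise ConfigError(
                f"sample column '{_INTENSITY_PREFIX}{s.sample_id}' not found in site table"
            )

    # decoy / contaminant rows; absent flag columns mean all-false
    keep = pd.Series(True, index=df.index)
    for flag_col in (_COL_REVERSE, _COL_CONTAMINANT):
        if flag_col in df.columns:
            keep &= df[flag_col].str.strip() != "+"
    df = df.loc[keep].reset_index(drop=True)

    sites = pd.DataFrame(
        {
            "protein": df[_COL_PROTEIN].str.strip(),
            "position": pd.to_numeric(df[_COL_POSITION], errors="raise").astype(int),
            "residue": df[_COL_RESIDUE].str.strip(),
            "multiplicity": pd.to_numeric(df[_COL_MULTIPLICITY], errors="raise").astype(int),
        }
    )
    if (sites["position"] < 1).any():
        raise InputError("site positions must be positive 1-based residue indices")
    bad_res = sorted(set(sites["residue"]) - VALID_RESIDUES)
    if bad_res:
        raise InputError(f"residues outside S/T/Y: {bad_res}")
    if not sites["multiplicity"].isin([1, 2, 3]).all():
        raise InputError("multiplicity must be 1, 2 or 3")

    dup_mask = sites.duplicated(subset=["protein", "position", "multiplicity"], keep=False)
    if dup_mask.any():
        dups = sites.loc[dup_mask, ["protein", "position", "multiplicity"]]
        raise InputError(
            "duplicate site keys: "
            + "; ".join(f"{r.protein}:{r.position}x{r.multiplicity}" for r in dups.itertuples())
        )

    values = pd.DataFrame(index=sites.index)
    for s in sample_map:
        col = df[_INTENSITY_PREFIX + s.sample_id].replace("", np.nan)
        num = pd.to_numeric(col, errors="raise").astype(float)
        if (num < 0).any():
            raise InputError(f"negative intensity in column '{_INTENSITY_PREFIX}{s.sample_id}'")
        values[s.sample_id] = num.where(num > 0, np.nan)

    return SiteIntensityMatrix(sites=sites, samples=list(sample_map), values=values)


def write_site_table(matrix: SiteIntensityMatrix, path: str | Path) -> None:
    """Write a raw-intensity matrix back to the tab-delimited site dialect.

    Missing cells are written as 0 (the non-detection convention), so a
    write/read round trip preserves keys, values and the missing pattern.
    """
    if matrix.log_scale:
        raise InputError("site tables store raw intensities; got a log-scale matrix")
    out = pd.DataFrame(
        {
            _COL_PROTEIN: matrix.sites["protein"],
            _COL_POSITION: matrix.sites["position"],
            _COL_RESIDUE: matrix.sites["residue"],
            _COL_MULTIPLICITY: matrix.sites["multiplicity"],
            _COL_REVERSE: "",
            _COL_CONTAMINANT: "",
        }
    )
    for s in matrix.samples:
        out[_INTENSITY_PREFIX + s.sample_id] = matrix.values[s.sample_id].fillna(0.0)
    out.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> AnnotationMap:
    """Read a two- or three-column (protein, term[, term name]) TSV.

    Duplicate (protein, term) pairs collapse; an empty file yields an empty map.
    """
    protein_to_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3) or not parts[0].strip() or not parts[1].strip():
                raise InputError(f"malformed annotation line {lineno}: {line!r}")
            protein, term = parts[0].strip(), parts[1].strip()
            protein_to_terms.setdefault(protein, set()).add(term)
            if len(parts) == 3 and parts[2].strip():
                term_names[term] = parts[2].strip()
    return AnnotationMap(protein_to_terms=protein_to_terms, term_names=term_names)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest_info: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write one TSV per result table plus a plain-text run manifest.

    Returns a name -> path manifest. Given identical tables and manifest info,
    the result files are byte-identical across runs (the manifest's timestamp
    line is the only run-varying output, and it lives in the manifest alone).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        written[name] = path

    manifest_path = out_dir / "run_manifest.txt"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        if manifest_info:
            for key, value in manifest_info.items():
                fh.write(f"{key}\t{value}\n")
        for name, path in written.items():
            n_rows = len(tables[name])
            fh.write(f"output\t{name}\t{path.name}\trows={n_rows}\n")
    written["run_manifest"] = manifest_path
    return written
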