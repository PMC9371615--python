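"""Detection-pattern ("presence/absence") enrichment classification.

A phosphosite is called enriched in one treatment group when it is detected
in nearly all samples of that group and in almost none of the other: with
groups of 4 and 5 samples the rule is detected in 3-4 of 4 and 0-1 of the
other, or 4-5 of 5 and 0-1 of the other. The thresholds generalize as
min_in = group size - 1 and max_out = 1, both overridable. Enriched site
sets collapse to deduplicated protein sets.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .errors import ConfigError
from .preprocess import DetectionMatrix

NEITHER = "neither"


@dataclasses.dataclass(frozen=True)
class PresenceParams:
    """Thresholds for the detection rule.

    ``min_in`` maps group name -> minimum detections in the enriched group
    (None: group size - 1 for every group); ``max_out`` is the maximum
    detections tolerated in the other group.
    """

    min_in: dict[str, int] | None = None
    max_out: int = 1

    def resolve(self, group_sizes: dict[str, int]) -> dict[str, int]:
        if len(group_sizes) != 2:
            raise ConfigError(f"presence classification needs 2 groups, got {sorted(group_sizes)}")
        min_in = self.min_in or {g: size - 1 for g, size in group_sizes.items()}
        for g, size in group_sizes.items():
            if g not in min_in:
                raise ConfigError(f"min_in missing group '{g}'")
            if not 1 <= min_in[g] <= size:
                raise ConfigError(f"min_in[{g}]={min_in[g]} outside [1, {size}]")
        for g, size in group_sizes.items():
            if not 0 <= self.max_out < size:
                raise ConfigError(f"max_out={self.max_out} outside [0, {size})")
        # mutual exclusivity: a site can satisfy both directions only if some
        # count can be both >= min_in and <= max_out
        if any(min_in[g] <= self.max_out for g in group_sizes):
            raise ConfigError(
                "min_in must exceed max_out in every group; labels would not be exclusive"
            )
        return min_in


@dataclasses.dataclass
class PresenceClassification:
    """Per-site labels plus enriched site tables and collapsed protein sets.

    ``table`` holds the site keys, per-group detection counts, and a label
    that is the enriched group's name or ``"neither"``. ``proteins`` maps
    group -> sorted deduplicated protein accessions of its enriched sites.
    """

    table: pd.DataFrame
    groups: tuple[str, str]
    enriched_sites: dict[str, pd.DataFrame]
    proteins: dict[str, list[str]]

    def summary(self) -> pd.DataFrame:
        """Enriched counts per group: sites, multiplicity-collapsed sites, proteins."""
        rows = []
        for g in self.groups:
            sites = self.enriched_sites[g]
            rows.append(
                {
                    "group": g,
                    "n_sites": len(sites),
                    "n_sites_multiplicity_collapsed": len(
                        sites[["protein", "position"]].drop_duplicates()
                    ),
                    "n_proteins": len(self.proteins[g]),
                }
            )
        return pd.DataFrame(rows)


def classify_sites(
    det: DetectionMatrix,
    sites: pd.DataFrame,
    params: PresenceParams = PresenceParams(),
) -> PresenceClassification:
    """Label every site by the detection rule; intensities play no role."""
    min_in = params.resolve(det.group_sizes)
    ga, gb = list(det.group_sizes)
    ca = det.group_counts[ga].to_numpy()
    cb = det.group_counts[gb].to_numpy()

    a_enriched = (ca >= min_in[ga]) & (cb <= params.max_out)
    b_enriched = (cb >= min_in[gb]) & (ca <= params.max_out)

    labels = pd.Series(NEITHER, index=sites.index, dtype=object)
    labels[a_enriched] = ga
    labels[b_enriched] = gb

    table = sites.copy()
    table[f"detected_{ga}"] = ca
    table[f"detected_{gb}"] = cb
    table["label"] = labels

    enriched_sites = {
        g: table.loc[labels == g].reset_index(drop=True) for g in (ga, gb)
    }
    proteins = {g: collapse_to_proteins(enriched_sites[g]) for g in (ga, gb)}
    return PresenceClassification(
        table=table, groups=(ga, gb), enriched_sites=enriched_sites, proteins=proteins
    )


def collapse_to_proteins(sites: pd.DataFrame) -> list[str]:
    """Distinct protein accessions of a site set, sorted for stable output."""
    return sorted(sites["protein"].unique())
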