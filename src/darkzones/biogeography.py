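"""Biogeography classification of genera by presence patterns.

Genera are classified per domain into four mutually exclusive categories:

* ``cosmopolitan`` -- detected in every replicate of both conditions at
  every location;
* ``dz_specific_all`` -- never detected on any control surface, and present
  in all dark-zone replicates at every location;
* ``dz_specific_subset`` -- never detected on any control surface, present
  in all dark-zone replicates of at least one but not all locations (the
  "endemic" case when the subset is a single location);
* ``unclassified`` -- everything else.

Detection is a count at or above ``detection_threshold`` (default 1 read in
the processed table, i.e. "not detected" is literally zero reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable

__all__ = [
    "CATEGORIES",
    "BiogeographyResult",
    "classify_genera",
    "biogeography_frame",
]

CATEGORIES = (
    "cosmopolitan",
    "dz_specific_all",
    "dz_specific_subset",
    "unclassified",
)


@dataclass(frozen=True)
class BiogeographyResult:
    genus: str
    domain: str
    category: str
    locations_all_dz: frozenset[str]
    present_any_control: bool
    mean_relabund_dz: float


def _classify_table(
    table: AbundanceTable, detection_threshold: int
) -> list[BiogeographyResult]:
    if not table.genera or not table.samples:
        raise ValueError(f"empty {table.domain} table")
    locations = table.locations
    for loc in locations:
        for cond in ("control", "dark_zone"):
            if not table.select_ids(location=loc, condition=cond):
                raise ValueError(
                    f"location {loc!r} lacks {cond!r} samples in the "
                    f"{table.domain} table"
                )
    presence = table.counts >= detection_threshold
    control_ids = table.select_ids(condition="control")
    dz_ids = table.select_ids(condition="dark_zone")
    dz_counts = table.counts[dz_ids].to_numpy(dtype=float)
    dz_sums = dz_counts.sum(axis=0)
    if np.any(dz_sums == 0):
        empty = [dz_ids[i] for i in np.flatnonzero(dz_sums == 0)]
        raise ValueError(f"dark-zone sample(s) with zero total reads: {empty}")
    rel_dz = (dz_counts / dz_sums).mean(axis=1)

    dz_ids_by_loc = {
        loc: table.select_ids(location=loc, condition="dark_zone")
        for loc in locations
    }
    results = []
    for i, genus in enumerate(table.genera):
        row = presence.loc[genus]
        present_any_control = bool(row[control_ids].any())
        all_everywhere = bool(row.all())
        locs_all_dz = frozenset(
            loc for loc in locations if bool(row[dz_ids_by_loc[loc]].all())
        )
        if all_everywhere:
            category = "cosmopolitan"
        elif not present_any_control and locs_all_dz:
            category = (
                "dz_specific_all"
                if len(locs_all_dz) == len(locations)
                else "dz_specific_subset"
            )
        else:
            category = "unclassified"
        results.append(
            BiogeographyResult(
                genus=genus,
                domain=table.domain,
                category=category,
                locations_all_dz=locs_all_dz,
                present_any_control=present_any_control,
                mean_relabund_dz=float(rel_dz[i]),
            )
        )
    return results


def classify_genera(
    tables: Sequence[AbundanceTable], detection_threshold: int = 1
) -> list[BiogeographyResult]:
    """Classify every genus of the given tables (typically bacteria + fungi).

    Classification is per domain; a genus name appearing in more than one
    table is an error.  Every location must carry both conditions.
    """
    if detection_threshold < 1:
        raise ValueError(
            f"detection_threshold must be >= 1, got {detection_threshold}"
        )
    seen: dict[str, str] = {}
    for table in tables:
        for genus in table.genera:
            if genus in seen:
                raise ValueError(
                    f"genus {genus!r} appears in both the {seen[genus]} and "
                    f"{table.domain} tables"
                )
            seen[genus] = table.domain
    results: list[BiogeographyResult] = []
    for table in tables:
        results.extend(_classify_table(table, detection_threshold))
    return results


def biogeography_frame(results: Iterable[BiogeographyResult]) -> pd.DataFrame:
    """Tabular view of classification results for TSV export."""
    rows = [
        {
            "genus": r.genus,
            "domain": r.domain,
            "category": r.category,
            "locations_all_dz": ";".join(sorted(r.locations_all_dz)),
            "present_any_control": r.present_any_control,
            "mean_relabund_dz": r.mean_relabund_dz,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
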