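"""Reference criteria: Δlog changes at the reference location.

The similarity of each dark zone to the reference alteration is judged
against a set of criteria derived from the reference location:

* one criterion per genus whose read abundance shifts by more than a factor
  10 between control and dark zone (|Δlog10| > 1) in the bacterial and
  fungal tables,
* the Δlog of total archaeal reads (the archaeal table is too sparse for
  genus criteria),
* one Bray-Curtis distance criterion per rarefied domain (bacteria, fungi),
* one qPCR community-size criterion per domain (Δlog of copies/ng).

Sign convention: Δlog = log10(dark zone) - log10(control), so positive
values mean selection (enrichment) in the dark zone.  A pseudocount
(default 1 read, or 1 copy/ng) is added to both condition means before the
log so zero means are defined and equal means give exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import CONDITIONS, AbundanceTable, QPCRTable, SampleMeta

__all__ = [
    "DeltaLogRecord",
    "Criterion",
    "delta_log",
    "condition_mean_counts",
    "genus_delta_logs",
    "total_reads_delta_log",
    "qpcr_delta_log",
    "select_reference_taxa",
    "assemble_criteria",
]

KIND_GENUS = "genus"
KIND_ARCHAEAL_READS = "archaeal_reads"
KIND_BRAY_CURTIS = "bray_curtis"
KIND_QPCR = "qpcr"


@dataclass(frozen=True)
class DeltaLogRecord:
    """Per-criterion condition means and their log10 change at one location.

    ``mean_control`` / ``mean_dz`` are mean reads per replicate for genus
    criteria, mean total reads for the archaeal-reads criterion, or mean
    copies/ng for qPCR criteria.
    """

    criterion_id: str
    domain: str
    mean_control: float
    mean_dz: float
    delta_log: float


@dataclass(frozen=True)
class Criterion:
    """One reference criterion; ``delta_log_apse`` is None for Bray-Curtis
    criteria, whose reference quantity (the control-control distance α) is
    recomputed per comparison."""

    criterion_id: str
    kind: str
    domain: str
    delta_log_apse: float | None


def delta_log(
    mean_control: float, mean_dz: float, pseudocount: float = 1.0
) -> float:
    """log10(mean_dz + c) - log10(mean_control + c); positive = dark-zone
    selection.  Equal means give exactly 0.0."""
    if mean_control < 0 or mean_dz < 0:
        raise ValueError(
            f"means must be >= 0, got control={mean_control}, dz={mean_dz}"
        )
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if mean_dz == mean_control:
        return 0.0
    return math.log10(mean_dz + pseudocount) - math.log10(
        mean_control + pseudocount
    )


def condition_mean_counts(table: AbundanceTable, location: str) -> pd.DataFrame:
    """Per-genus arithmetic mean counts over the replicates of each condition.

    Returns a DataFrame indexed by genus with columns 'control' and
    'dark_zone'.  Averages over whatever replicates the table holds (e.g.
    after rarefaction dropped below-depth samples).
    """
    out = {}
    for cond in CONDITIONS:
        ids = table.select_ids(location=location, condition=cond)
        if not ids:
            raise ValueError(
                f"no {cond!r} samples at location {location!r} in the "
                f"{table.domain} table"
            )
        out[cond] = table.counts[ids].mean(axis=1)
    return pd.DataFrame(out)


def genus_delta_logs(
    table: AbundanceTable, location: str, pseudocount: float = 1.0
) -> list[DeltaLogRecord]:
    """One Δlog record per genus at a location (control vs dark zone means)."""
    means = condition_mean_counts(table, location)
    records = []
    for genus, row in means.iterrows():
        mc = float(row["control"])
        mdz = float(row["dark_zone"])
        records.append(
            DeltaLogRecord(
                criterion_id=str(genus),
                domain=table.domain,
                mean_control=mc,
                mean_dz=mdz,
                delta_log=delta_log(mc, mdz, pseudocount),
            )
        )
    return records


def total_reads_delta_log(
    table: AbundanceTable, location: str, pseudocount: float = 1.0
) -> DeltaLogRecord:
    """Δlog of mean total reads per replicate, control vs dark zone.

    Used for the archaeal-reads criterion, on the unnormalized archaeal table.
    """
    sums = table.column_sums()
    means = {}
    for cond in CONDITIONS:
        ids = table.select_ids(location=location, condition=cond)
        if not ids:
            raise ValueError(
                f"no {cond!r} samples at location {location!r} in the "
                f"{table.domain} table"
            )
        means[cond] = float(sums[ids].mean())
    return DeltaLogRecord(
        criterion_id="archaeal_reads" if table.domain == "archaea" else
        f"{table.domain}_reads",
        domain=table.domain,
        mean_control=means["control"],
        mean_dz=means["dark_zone"],
        delta_log=delta_log(means["control"], means["dark_zone"], pseudocount),
    )


def qpcr_delta_log(
    qpcr: QPCRTable,
    samples: Sequence[SampleMeta],
    domain: str,
    location: str,
    pseudocount: float = 1.0,
) -> DeltaLogRecord:
    """Δlog of mean marker-gene copies/ng, control vs dark zone, one domain."""
    means = {}
    for cond in CONDITIONS:
        ids = [
            s.sample_id
            for s in samples
            if s.location == location and s.condition == cond
        ]
        if not ids:
            raise ValueError(
                f"no {cond!r} samples at location {location!r} for qPCR"
            )
        means[cond] = float(qpcr.copies(domain, ids).mean())
    return DeltaLogRecord(
        criterion_id=f"qpcr_{domain}",
        domain=domain,
        mean_control=means["control"],
        mean_dz=means["dark_zone"],
        delta_log=delta_log(means["control"], means["dark_zone"], pseudocount),
    )


def select_reference_taxa(
    records: Iterable[DeltaLogRecord], threshold: float = 1.0
) -> list[Criterion]:
    """Keep genera with |Δlog| strictly above the threshold (default 1).

    The cutoff is strict: Δlog = 1.0 exactly is not selected.  Output is
    sorted by (domain, genus) so it does not depend on input order.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    selected = [
        Criterion(
            criterion_id=r.criterion_id,
            kind=KIND_GENUS,
            domain=r.domain,
            delta_log_apse=r.delta_log,
        )
        for r in records
        if abs(r.delta_log) > threshold
    ]
    return sorted(selected, key=lambda c: (c.domain, c.criterion_id))


def assemble_criteria(
    bacterial_criteria: Sequence[Criterion],
    fungal_criteria: Sequence[Criterion],
    archaeal_table: AbundanceTable,
    qpcr: QPCRTable,
    samples: Sequence[SampleMeta],
    reference_location: str,
    include_bray_curtis: bool = True,
    pseudocount: float = 1.0,
) -> list[Criterion]:
    """Full criterion set: genus criteria + archaeal reads + Bray-Curtis + qPCR.

    With Bray-Curtis included the count identity is
    ``len(output) == len(bacterial) + len(fungal) + 6`` (1 archaeal-reads
    criterion, 2 Bray-Curtis criteria, 3 qPCR criteria).
    """
    criteria: list[Criterion] = []
    criteria.extend(bacterial_criteria)
    criteria.extend(fungal_criteria)

    arch = total_reads_delta_log(archaeal_table, reference_location, pseudocount)
    criteria.append(
        Criterion(
            criterion_id="archaeal_reads",
            kind=KIND_ARCHAEAL_READS,
            domain="archaea",
            delta_log_apse=arch.delta_log,
        )
    )
    if include_bray_curtis:
        for domain in ("bacteria", "fungi"):
            criteria.append(
                Criterion(
                    criterion_id=f"bray_curtis_{domain}",
                    kind=KIND_BRAY_CURTIS,
                    domain=domain,
                    delta_log_apse=None,
                )
            )
    for domain in ("bacteria", "archaea", "fungi"):
        rec = qpcr_delta_log(qpcr, samples, domain, reference_location, pseudocount)
        criteria.append(
            Criterion(
                criterion_id=rec.criterion_id,
                kind=KIND_QPCR,
                domain=domain,
                delta_log_apse=rec.delta_log,
            )
        )
    return criteria
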