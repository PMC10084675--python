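"""Table conditioning: global low-abundance filtering and rarefaction.

Mirrors the processing applied to the study's amplicon tables: genera whose
total read count falls below a fixed fraction of all sequences (default
0.005%) are discarded, then each sample is randomly subsampled without
replacement down to a fixed depth so abundance comparisons are depth-fair.
The archaeal table is exempt from rarefaction (read numbers there are too
low and uneven); :func:`normalize_domain` enforces this by domain tag.
"""

from __future__ import annotations

import logging
import zlib
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable

__all__ = [
    "DEFAULT_FILTER_FRACTION",
    "DEFAULT_DEPTHS",
    "filter_low_abundance",
    "rarefy",
    "normalize_domain",
]

logger = logging.getLogger(__name__)

#: Low-abundance filter: genera below this fraction of all reads are removed.
DEFAULT_FILTER_FRACTION = 0.00005

#: Rarefaction depths per domain; archaea are never rarefied.
DEFAULT_DEPTHS: Mapping[str, int] = {"bacteria": 13467, "fungi": 12753}


def filter_low_abundance(
    table: AbundanceTable, fraction: float = DEFAULT_FILTER_FRACTION
) -> AbundanceTable:
    """Drop genera whose total count is strictly below ``fraction`` of all reads.

    A genus whose total exactly equals the threshold is kept (the filter
    removes strictly-below, the more conservative reading of "filtered at
    0.005%").  Retained counts are unchanged and the sample set is preserved;
    an empty result table is legal.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    totals = table.counts.sum(axis=1)
    threshold = fraction * float(table.counts.to_numpy().sum())
    keep = totals >= threshold
    return table.with_counts(table.counts.loc[keep].copy())


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-(sample, seed) substream: dropping/adding samples does not disturb
    # the draws of other samples
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a logged warning;
    if all samples fall below the depth a :class:`ValueError` is raised.  The
    draw is multivariate hypergeometric, seeded per (sample_id, seed), so the
    result is bit-identical across runs and stable under sample removal.
    """
    if int(depth) < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    depth = int(depth)
    sums = table.column_sums()
    dropped = [sid for sid in table.sample_ids if int(sums[sid]) < depth]
    if len(dropped) == len(table.sample_ids):
        raise ValueError(
            f"all samples are below rarefaction depth {depth} "
            f"(max total {int(sums.max()) if len(sums) else 0})"
        )
    if dropped:
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(dropped),
            depth,
            ", ".join(dropped),
        )
    kept = table.subset_samples(
        [sid for sid in table.sample_ids if sid not in set(dropped)]
    )
    new_cols = {}
    for sid in kept.sample_ids:
        col = kept.counts[sid].to_numpy()
        total = int(col.sum())
        if total == depth:
            new_cols[sid] = col
        else:
            rng = _sample_rng(seed, sid)
            new_cols[sid] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(new_cols, index=kept.counts.index, dtype=np.int64)
    return kept.with_counts(counts)


def normalize_domain(
    table: AbundanceTable,
    seed: int,
    fraction: float = DEFAULT_FILTER_FRACTION,
    depth: int | None = None,
) -> AbundanceTable:
    """Filter low-abundance genera, then rarefy -- except for archaea.

    The archaeal table is never rarefied (domain-tag enforced); bacteria and
    fungi default to the study depths in :data:`DEFAULT_DEPTHS`.
    """
    filtered = filter_low_abundance(table, fraction)
    if table.domain == "archaea":
        return filtered
    if depth is None:
        depth = DEFAULT_DEPTHS[table.domain]
    return rarefy(filtered, depth, seed)
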