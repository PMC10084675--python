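"""Dissimilarity, alpha-diversity and rank-correlation statistics.

Conventions follow the PAST software the study's indices were computed with:
Shannon H' uses the natural logarithm, evenness is exp(H')/S (not Pielou's
H/ln S), Chao-1 is the bias-corrected form S + F1(F1-1)/(2(F2+1)) so it is
defined when no doubletons are observed, and Simpson is reported as 1 - D.
Kendall's correlation is the tie-corrected tau-b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import kendalltau as _kendalltau
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import shannon as _shannon
from skbio.diversity.alpha import simpson as _simpson

from .tables_io import AbundanceTable

__all__ = [
    "DiversityReport",
    "CorrelationResult",
    "bray_curtis",
    "condition_profile",
    "diversity",
    "diversity_table",
    "kendall_tau",
]


@dataclass(frozen=True)
class DiversityReport:
    """Alpha-diversity indices for one sample (genus-level)."""

    sample_id: str
    S_obs: int
    F1: int
    F2: int
    chao1: float
    shannon_H: float
    simpson_1D: float
    evenness: float


@dataclass(frozen=True)
class CorrelationResult:
    tau: float
    p_value: float


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between matched vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(
            f"vectors must be 1-D of equal length, got {x.shape} and {y.shape}"
        )
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative vectors")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def condition_profile(
    table: AbundanceTable, location: str, condition: str
) -> np.ndarray:
    """Mean relative-abundance profile over the replicates of one condition.

    Each replicate's counts are divided by its column sum, then the relative
    abundances are averaged over replicates; the result sums to 1 and is the
    condition centroid used for between-condition Bray-Curtis distances.
    """
    ids = table.select_ids(location=location, condition=condition)
    if not ids:
        raise ValueError(
            f"no samples at location {location!r}, condition {condition!r}"
        )
    cols = table.counts[ids].to_numpy(dtype=float)
    sums = cols.sum(axis=0)
    if np.any(sums == 0):
        empty = [ids[i] for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"sample(s) with zero total reads: {empty}")
    return (cols / sums).mean(axis=1)


def diversity(counts, sample_id: str = "") -> DiversityReport:
    """Alpha-diversity report for one sample's genus count vector."""
    n = np.asarray(counts)
    if n.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(n < 0) or np.any(n != np.floor(n)):
        raise ValueError("counts must be non-negative integers")
    n = n.astype(np.int64)
    if n.sum() < 1:
        raise ValueError("diversity undefined for an all-zero sample")
    s_obs = int(np.count_nonzero(n))
    f1 = int(np.count_nonzero(n == 1))
    f2 = int(np.count_nonzero(n == 2))
    chao = float(_chao1(n, bias_corrected=True))
    h = float(_shannon(n, base=np.e))
    simpson_1d = float(_simpson(n))
    evenness = float(np.exp(h) / s_obs)
    return DiversityReport(
        sample_id=sample_id,
        S_obs=s_obs,
        F1=f1,
        F2=f2,
        chao1=chao,
        shannon_H=h,
        simpson_1D=simpson_1d,
        evenness=evenness,
    )


def diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample diversity indices for a whole table, with sample metadata."""
    rows = []
    for s in table.samples:
        rep = diversity(table.counts[s.sample_id].to_numpy(), s.sample_id)
        rows.append(
            {
                "sample_id": s.sample_id,
                "location": s.location,
                "condition": s.condition,
                "replicate": s.replicate,
                "S_obs": rep.S_obs,
                "F1": rep.F1,
                "F2": rep.F2,
                "chao1": rep.chao1,
                "shannon_H": rep.shannon_H,
                "simpson_1D": rep.simpson_1D,
                "evenness": rep.evenness,
            }
        )
    return pd.DataFrame(rows)


def kendall_tau(x, y) -> CorrelationResult:
    """Tie-corrected Kendall tau-b with an exact permutation p for small n.

    The p-value is exact for n <= 8 when neither vector has ties, and uses
    the normal approximation (with tie correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall tau undefined for a constant vector")
    has_ties = len(set(x)) < n or len(set(y)) < n
    method = "exact" if (n <= 8 and not has_ties) else "asymptotic"
    res = _kendalltau(x, y, method=method, variant="b")
    return CorrelationResult(tau=float(res.statistic), p_value=float(res.pvalue))
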