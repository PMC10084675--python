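"""Decisional matrix: banded similarity scoring of dark zones vs the reference.

Each criterion compares a location's Δlog variation with the reference
location's.  The relative deviation r = |Δlog_local - Δlog_ref| / |Δlog_ref|
is mapped to a score in 0.1-wide bands, closed on the lower edge:

    r in [k/10, (k+1)/10)  ->  score 1 - k/10   (k = 0 .. 9)
    r >= 1                 ->  score 0

so r < 0.1 scores 1, r = 0.1 exactly scores 0.9, and a location with no
change at all (Δlog_local = 0, r = 1) scores 0.  A variation of opposite
sign to the reference is flagged and scores 0 regardless of magnitude.

The Bray-Curtis criteria use the differential d = (β - α)/α, where α is the
control-control distance between the two locations and β the distance
between their dark zones; d is banded identically, and a negative d (the
dark zones more mutually similar than the controls) is flagged opposite.

Per-location scores are summed (opposite cells contribute 0), expressed as a
percent of the criterion count, and ranked by descending percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .community_stats import bray_curtis, condition_profile
from .reference_criteria import (
    KIND_ARCHAEAL_READS,
    KIND_BRAY_CURTIS,
    KIND_GENUS,
    KIND_QPCR,
    Criterion,
    condition_mean_counts,
    delta_log,
    qpcr_delta_log,
    total_reads_delta_log,
)
from .tables_io import AbundanceTable, QPCRTable, SampleMeta

__all__ = [
    "BandResult",
    "CriterionScore",
    "BCComparison",
    "DecisionMatrix",
    "band_score",
    "bc_score",
    "bray_curtis_comparison",
    "score_location",
    "build_matrix",
    "round_half_up",
]

_BAND_EDGES = np.arange(1, 11) / 10.0  # 0.1, 0.2, ..., 1.0


class BandResult(NamedTuple):
    rel_deviation: float
    score: float
    opposite: bool


@dataclass(frozen=True)
class CriterionScore:
    """One cell of the decisional matrix.

    ``rel_deviation`` is the banded quantity r (for Bray-Curtis, |d| with the
    sign carried by the opposite flag); ``delta_log_local`` is None for
    Bray-Curtis criteria.
    """

    criterion_id: str
    location: str
    delta_log_local: float | None
    rel_deviation: float
    score: float
    opposite: bool


@dataclass(frozen=True)
class BCComparison:
    """Bray-Curtis differential between a location and the reference."""

    alpha: float
    beta: float
    differential: float


@dataclass(eq=False)
class DecisionMatrix:
    criteria: tuple[Criterion, ...]
    locations: tuple[str, ...]
    scores: dict[str, tuple[CriterionScore, ...]]
    totals: dict[str, float]
    percent: dict[str, float]
    rank: dict[str, int]

    def scores_frame(self, mark_opposite: bool = False) -> pd.DataFrame:
        """Criteria x locations grid; opposite cells become "OPP" if asked."""
        data = {}
        for loc in self.locations:
            col = []
            for s in self.scores[loc]:
                col.append("OPP" if (mark_opposite and s.opposite) else s.score)
            data[loc] = col
        return pd.DataFrame(
            data, index=[c.criterion_id for c in self.criteria]
        ).rename_axis("criterion_id")

    def summary_frame(self) -> pd.DataFrame:
        # totals are sums of exact-decimal scores; display at score precision
        # (percent is always computed from the unrounded totals)
        return pd.DataFrame(
            {
                "location": list(self.locations),
                "total_score": [
                    round_half_up(self.totals[l], 1) for l in self.locations
                ],
                "percent_similarity": [self.percent[l] for l in self.locations],
                "rank": [self.rank[l] for l in self.locations],
            }
        )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (4.25 -> 4.3, -4.25 -> -4.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _band(r: float) -> float:
    """Score for a non-negative relative deviation r (11 levels, 1.0 .. 0.0)."""
    if r < 0:
        raise ValueError(f"relative deviation must be >= 0, got {r}")
    k = int(np.searchsorted(_BAND_EDGES, r, side="right"))
    return (10 - k) / 10.0 if k < 10 else 0.0


def band_score(delta_log_local: float, delta_log_apse: float) -> BandResult:
    """Score a location's Δlog against the reference Δlog.

    Opposite-signed variation scores 0 with the flag set; Δlog_local = 0 is
    not opposite, it lands at r = 1 and scores 0.
    """
    if delta_log_apse == 0:
        raise ValueError(
            "criterion ill-defined: reference delta_log is exactly 0"
        )
    opposite = delta_log_local != 0 and (
        (delta_log_local > 0) != (delta_log_apse > 0)
    )
    r = abs(delta_log_local - delta_log_apse) / abs(delta_log_apse)
    score = 0.0 if opposite else _band(r)
    return BandResult(rel_deviation=r, score=score, opposite=opposite)


def bc_score(alpha: float, beta: float) -> BandResult:
    """Score a Bray-Curtis differential d = (β - α)/α.

    d < 0 is flagged opposite (score 0).  α = 0 with β = 0 is the trivially
    identical comparison and scores 1; α = 0 with β > 0 leaves the
    differential undefined and is a hard error.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("Bray-Curtis distances must be >= 0")
    if alpha == 0:
        if beta == 0:
            return BandResult(rel_deviation=0.0, score=1.0, opposite=False)
        raise ValueError(
            "Bray-Curtis differential undefined: alpha = 0 with beta > 0"
        )
    d = (beta - alpha) / alpha
    if d < 0:
        return BandResult(rel_deviation=abs(d), score=0.0, opposite=True)
    return BandResult(rel_deviation=d, score=_band(d), opposite=False)


def bray_curtis_comparison(
    table: AbundanceTable, location: str, reference_location: str
) -> BCComparison:
    """α and β Bray-Curtis distances between a location and the reference.

    α compares the two control centroids, β the two dark-zone centroids;
    centroids are mean relative-abundance profiles over replicates.
    """
    ref_c = condition_profile(table, reference_location, "control")
    loc_c = condition_profile(table, location, "control")
    ref_d = condition_profile(table, reference_location, "dark_zone")
    loc_d = condition_profile(table, location, "dark_zone")
    alpha = bray_curtis(ref_c, loc_c)
    beta = bray_curtis(ref_d, loc_d)
    diff = float("nan") if alpha == 0 else (beta - alpha) / alpha
    return BCComparison(alpha=alpha, beta=beta, differential=diff)


def _genus_condition_means(
    table: AbundanceTable, genus: str, location: str
) -> tuple[float, float]:
    means = condition_mean_counts(table, location)
    if genus in means.index:
        return float(means.loc[genus, "control"]), float(
            means.loc[genus, "dark_zone"]
        )
    return 0.0, 0.0  # genus absent from the table: zero counts everywhere


def score_location(
    criteria: Sequence[Criterion],
    tables: Mapping[str, AbundanceTable],
    qpcr: QPCRTable,
    samples: Sequence[SampleMeta],
    location: str,
    reference_location: str,
    pseudocount: float = 1.0,
) -> list[CriterionScore]:
    """Score every criterion at one location against the reference.

    ``tables`` maps domain tags to (normalized) abundance tables holding both
    the target and the reference location's samples.
    """
    # cache per-domain condition means at this location
    means_cache: dict[str, pd.DataFrame] = {}

    def _means(domain: str) -> pd.DataFrame:
        if domain not in means_cache:
            if domain not in tables:
                raise ValueError(f"missing {domain!r} table")
            means_cache[domain] = condition_mean_counts(
                tables[domain], location
            )
        return means_cache[domain]

    out: list[CriterionScore] = []
    for c in criteria:
        if c.kind == KIND_GENUS:
            means = _means(c.domain)
            if c.criterion_id in means.index:
                mc = float(means.loc[c.criterion_id, "control"])
                mdz = float(means.loc[c.criterion_id, "dark_zone"])
            else:
                mc, mdz = 0.0, 0.0
            local = delta_log(mc, mdz, pseudocount)
            band = band_score(local, c.delta_log_apse)
        elif c.kind == KIND_ARCHAEAL_READS:
            if c.domain not in tables:
                raise ValueError(
                    f"missing {c.domain!r} table for criterion "
                    f"{c.criterion_id!r}"
                )
            rec = total_reads_delta_log(tables[c.domain], location, pseudocount)
            local = rec.delta_log
            band = band_score(local, c.delta_log_apse)
        elif c.kind == KIND_QPCR:
            rec = qpcr_delta_log(qpcr, samples, c.domain, location, pseudocount)
            local = rec.delta_log
            band = band_score(local, c.delta_log_apse)
        elif c.kind == KIND_BRAY_CURTIS:
            if c.domain not in tables:
                raise ValueError(
                    f"missing {c.domain!r} table for criterion "
                    f"{c.criterion_id!r}"
                )
            comp = bray_curtis_comparison(
                tables[c.domain], location, reference_location
            )
            local = None
            band = bc_score(comp.alpha, comp.beta)
        else:  # pragma: no cover - guarded by Criterion construction
            raise ValueError(f"unknown criterion kind {c.kind!r}")
        out.append(
            CriterionScore(
                criterion_id=c.criterion_id,
                location=location,
                delta_log_local=local,
                rel_deviation=band.rel_deviation,
                score=band.score,
                opposite=band.opposite,
            )
        )
    return out


def build_matrix(
    criteria: Sequence[Criterion],
    scores_by_location: Mapping[str, Sequence[CriterionScore]],
) -> DecisionMatrix:
    """Assemble the score grid with totals, percent similarities and ranks.

    Totals sum positive scores (opposite-flagged cells contribute 0), percent
    is 100 * total / |criteria| rounded half-away-from-zero to one decimal
    (from the unrounded total), and ranks order locations by descending
    percent with alphabetical tie-break.
    """
    n = len(criteria)
    if n == 0:
        raise ValueError("criterion set is empty")
    ids = [c.criterion_id for c in criteria]
    scores: dict[str, tuple[CriterionScore, ...]] = {}
    for loc, loc_scores in scores_by_location.items():
        got = [s.criterion_id for s in loc_scores]
        if got != ids:
            raise ValueError(
                f"ragged score grid at location {loc!r}: expected criteria "
                f"{ids}, got {got}"
            )
        scores[loc] = tuple(loc_scores)
    locations = tuple(scores)
    totals = {
        loc: float(sum(s.score for s in scores[loc])) for loc in locations
    }
    percent = {
        loc: round_half_up(100.0 * totals[loc] / n, 1) for loc in locations
    }
    order = sorted(locations, key=lambda l: (-percent[l], l))
    rank = {loc: i + 1 for i, loc in enumerate(order)}
    return DecisionMatrix(
        criteria=tuple(criteria),
        locations=locations,
        scores=scores,
        totals=totals,
        percent=percent,
        rank=rank,
    )
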