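"""Data model and TSV I/O for genus count tables, sample metadata and qPCR tables.

The whole pipeline runs on three in-memory containers:

* :class:`AbundanceTable` -- a genus x sample matrix of non-negative integer
  read counts for one marker domain (bacterial 16S, archaeal 16S or fungal
  ITS2), carrying per-sample metadata (location, condition, replicate).
* :class:`SampleMeta` -- one sample's identity within the paired design
  (control surface vs dark-zone alteration, several replicates per location).
* :class:`QPCRTable` -- marker-gene copy numbers per ng of total DNA, one row
  per (sample, domain), used as a community-size proxy.

The canonical interchange format is tab-separated UTF-8 text with Unix
newlines: small genus tables are meant to be inspectable with standard shell
tools.  Genus names are opaque keys; no taxonomy normalisation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "CONDITIONS",
    "DEFAULT_LOCATIONS",
    "SampleMeta",
    "AbundanceTable",
    "QPCRTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_qpcr_table",
    "write_qpcr_table",
]

DOMAINS = ("bacteria", "archaea", "fungi")
CONDITIONS = ("control", "dark_zone")

#: The nine cave locations of the default sampling design.
DEFAULT_LOCATIONS = (
    "Apse",
    "Nave high",
    "Nave low",
    "Passage vertical",
    "Passage horizontal",
    "Bulls left",
    "Bulls center",
    "Bulls wall",
    "Airlock-2 wall",
)


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one swab sample within the paired sampling design."""

    sample_id: str
    location: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be a non-empty string")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition for sample {self.sample_id!r} must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if not isinstance(self.replicate, (int, np.integer)) or isinstance(
            self.replicate, bool
        ):
            raise ValueError(
                f"replicate for sample {self.sample_id!r} must be an integer"
            )
        if self.replicate < 1:
            raise ValueError(
                f"replicate for sample {self.sample_id!r} must be >= 1, "
                f"got {self.replicate}"
            )


def _validate_samples(samples: Sequence[SampleMeta]) -> None:
    seen_ids: set[str] = set()
    seen_keys: set[tuple[str, str, int]] = set()
    for s in samples:
        if s.sample_id in seen_ids:
            raise ValueError(f"duplicate sample_id {s.sample_id!r}")
        key = (s.location, s.condition, int(s.replicate))
        if key in seen_keys:
            raise ValueError(
                f"duplicate (location, condition, replicate) = {key!r}"
            )
        seen_ids.add(s.sample_id)
        seen_keys.add(key)


@dataclass(eq=False)
class AbundanceTable:
    """Genus x sample count matrix for one marker domain.

    ``counts`` is a DataFrame indexed by genus name with one column per
    sample id, in the same order as ``samples``.  All counts are
    non-negative integers.
    """

    domain: str
    counts: pd.DataFrame
    samples: tuple[SampleMeta, ...]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"domain must be one of {DOMAINS}, got {self.domain!r}"
            )
        self.samples = tuple(self.samples)
        _validate_samples(self.samples)
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError(
                "counts columns must match sample metadata ids in order; "
                f"columns={list(self.counts.columns)!r} ids={ids!r}"
            )
        genera = list(self.counts.index)
        if len(set(genera)) != len(genera):
            dups = sorted({g for g in genera if genera.count(g) > 1})
            raise ValueError(f"duplicate genus name(s): {dups}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                # tolerate float storage only if integral
                if not np.all(np.isfinite(values)) or np.any(
                    values != np.floor(values)
                ):
                    bad = np.argwhere(values != np.floor(values))
                    r, c = bad[0]
                    raise ValueError(
                        f"non-integer count at genus {genera[r]!r}, "
                        f"sample {ids[c]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count at genus {genera[r]!r}, sample {ids[c]!r}"
                )
        else:
            self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "genus"
        self._meta = {s.sample_id: s for s in self.samples}

    # -- convenience accessors -------------------------------------------------

    @property
    def genera(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.location, None)
        return list(seen)

    def meta(self, sample_id: str) -> SampleMeta:
        return self._meta[sample_id]

    def select_ids(
        self, location: str | None = None, condition: str | None = None
    ) -> list[str]:
        """Sample ids matching a (location, condition) filter, in table order."""
        out = []
        for s in self.samples:
            if location is not None and s.location != location:
                continue
            if condition is not None and s.condition != condition:
                continue
            out.append(s.sample_id)
        return out

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        keep = set(sample_ids)
        samples = tuple(s for s in self.samples if s.sample_id in keep)
        missing = keep - {s.sample_id for s in samples}
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        return AbundanceTable(
            domain=self.domain,
            counts=self.counts[[s.sample_id for s in samples]].copy(),
            samples=samples,
        )

    def with_counts(self, counts: pd.DataFrame) -> "AbundanceTable":
        """Same samples, new count matrix (used by filtering/rarefaction)."""
        return AbundanceTable(domain=self.domain, counts=counts, samples=self.samples)

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(eq=False)
class QPCRTable:
    """Marker-gene copies per ng total DNA, one row per (sample, domain)."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "domain", "copies_per_ng")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"qPCR table missing column(s): {missing}")
        self.data = self.data.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        for _, row in self.data.iterrows():
            if row["domain"] not in DOMAINS:
                raise ValueError(
                    f"unknown domain {row['domain']!r} for sample "
                    f"{row['sample_id']!r}"
                )
            v = float(row["copies_per_ng"])
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"copies_per_ng must be > 0; got {row['copies_per_ng']!r} "
                    f"for sample {row['sample_id']!r}, domain {row['domain']!r}"
                )
        pairs = list(zip(self.data["sample_id"], self.data["domain"]))
        if len(set(pairs)) != len(pairs):
            dup = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValueError(f"duplicate (sample_id, domain) row(s): {dup}")
        self.data["copies_per_ng"] = self.data["copies_per_ng"].astype(float)

    def copies(self, domain: str, sample_ids: Sequence[str]) -> pd.Series:
        """Copies/ng for the given samples in one domain, indexed by sample id."""
        sub = self.data[self.data["domain"] == domain].set_index("sample_id")
        missing = [s for s in sample_ids if s not in sub.index]
        if missing:
            raise KeyError(
                f"no qPCR rows for domain {domain!r}, sample(s) {missing}"
            )
        return sub.loc[list(sample_ids), "copies_per_ng"]


# -- TSV I/O -------------------------------------------------------------------


def read_metadata(metadata_path: str | Path) -> tuple[SampleMeta, ...]:
    """Read a sample metadata TSV (sample_id, location, condition, replicate)."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = ["sample_id", "location", "condition", "replicate"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file missing column(s): {missing}")
    samples = []
    for _, row in meta.iterrows():
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise ValueError(
                f"non-integer replicate {row['replicate']!r} for sample "
                f"{row['sample_id']!r}"
            ) from None
        samples.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                location=str(row["location"]),
                condition=str(row["condition"]),
                replicate=rep,
            )
        )
    _validate_samples(samples)
    return tuple(samples)


def write_metadata(samples: Sequence[SampleMeta], metadata_path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "location": [s.location for s in samples],
            "condition": [s.condition for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    df.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")


def read_abundance_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    domain: str,
) -> AbundanceTable:
    """Read a counts TSV (header ``genus<TAB>sample...``) plus its metadata TSV.

    Every counts column must have a metadata row; metadata rows for samples
    not present in the counts file are ignored.  Sample order follows the
    counts header.
    """
    counts = pd.read_csv(counts_path, sep="\t", dtype=str)
    if counts.columns[0] != "genus":
        raise ValueError(
            f"counts file {counts_path} must start with a 'genus' column, "
            f"got {counts.columns[0]!r}"
        )
    counts = counts.set_index("genus")
    # integer parse with row/column naming on failure
    parsed = {}
    for col in counts.columns:
        try:
            parsed[col] = pd.to_numeric(counts[col])
        except (TypeError, ValueError):
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric count {bad.iloc[0]!r} at genus "
                f"{bad.index[0]!r}, sample {col!r}"
            ) from None
    counts = pd.DataFrame(parsed, index=counts.index)

    all_meta = {s.sample_id: s for s in read_metadata(metadata_path)}
    samples = []
    for col in counts.columns:
        if col not in all_meta:
            raise ValueError(
                f"sample {col!r} in counts file has no metadata row"
            )
        samples.append(all_meta[col])
    return AbundanceTable(domain=domain, counts=counts, samples=tuple(samples))


def write_abundance_table(
    table: AbundanceTable,
    counts_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write counts + metadata TSVs such that reading them back is the identity."""
    table.counts.to_csv(counts_path, sep="\t", index=True, lineterminator="\n")
    write_metadata(table.samples, metadata_path)


def read_qpcr_table(path: str | Path) -> QPCRTable:
    """Read a qPCR TSV with columns sample_id, domain, copies_per_ng."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "domain": str})
    return QPCRTable(data=df)


def write_qpcr_table(table: QPCRTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, lineterminator="\n")
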