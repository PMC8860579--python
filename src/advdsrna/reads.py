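"""Containers for UMI-tagged spliced alignments and junction count tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

Interval = tuple[int, int]

JUNCTION_COLUMNS = [
    "library_id",
    "reference",
    "strand",
    "donor",
    "acceptor",
    "unique_read_count",
]


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One strand-resolved, UMI-tagged alignment as a list of genomic blocks.

    ``blocks`` are half-open genomic intervals, sorted and non-overlapping; a
    gap between consecutive blocks is a splice junction (CIGAR ``N``).
    """

    read_id: str
    umi: str
    reference: str
    strand: str
    blocks: tuple[Interval, ...]
    library_id: str | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.read_id}: read needs at least one block")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 and e1 <= s2):
                raise ValueError(f"{self.read_id}: blocks unsorted or overlapping")
        if self.blocks[-1][0] >= self.blocks[-1][1]:
            raise ValueError(f"{self.read_id}: empty block")

    @property
    def mapped_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class ReadLibrary:
    """All reads of one sequencing library (condition x fraction x replicate)."""

    library_id: str
    condition: str
    fraction: str  # input | ip
    replicate: int
    reads: list[AlignedRead] = field(default_factory=list)
    deduplicated: bool = False

    def __post_init__(self) -> None:
        if self.fraction not in ("input", "ip"):
            raise ValueError(f"fraction must be 'input' or 'ip', got {self.fraction!r}")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True, slots=True)
class Junction:
    """A splice junction: donor = end of the upstream block, acceptor = start
    of the downstream block (top-strand genomic coordinates, half-open)."""

    reference: str
    strand: str
    donor: int
    acceptor: int

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"junction gap empty: donor {self.donor} >= acceptor {self.acceptor}")


@dataclass
class JunctionTable:
    """Per-library unique-read counts per junction plus library totals.

    ``counts`` has columns ``library_id, reference, strand, donor, acceptor,
    unique_read_count``; ``totals`` maps library_id to the total number of
    unique mapped deduplicated reads (the normalization denominator).
    """

    counts: pd.DataFrame
    totals: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(JUNCTION_COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValueError(f"junction table missing columns {sorted(missing)}")
        if (self.counts["unique_read_count"] < 0).any():
            raise ValueError("negative junction counts")

    @property
    def library_ids(self) -> list[str]:
        return sorted(self.totals)

    def normalized(self, scale: float = 1e6) -> pd.DataFrame:
        """Counts with a reads-per-million ``norm_abundance`` column added."""
        df = self.counts.copy()
        denom = df["library_id"].map(self.totals).astype(float)
        df["norm_abundance"] = df["unique_read_count"] / denom * scale
        return df

    def junctions(self) -> list[Junction]:
        """Distinct junctions present in any library, sorted."""
        cols = ["reference", "strand", "donor", "acceptor"]
        uniq = self.counts[cols].drop_duplicates().sort_values(cols)
        return [Junction(*row) for row in uniq.itertuples(index=False)]

    @classmethod
    def concat(cls, tables: Iterable["JunctionTable"]) -> "JunctionTable":
        tables = list(tables)
        totals: dict[str, int] = {}
        for t in tables:
            dup = set(totals) & set(t.totals)
            if dup:
                raise ValueError(f"duplicate library ids: {sorted(dup)}")
            totals.update(t.totals)
        counts = pd.concat([t.counts for t in tables], ignore_index=True)
        return cls(counts=counts, totals=totals)


def junction_key(j: Junction) -> tuple:
    return (j.reference, j.strand, j.donor, j.acceptor)


def read_junctions(read: AlignedRead) -> list[Junction]:
    """Junctions implied by the gaps of one spliced read."""
    return [
        Junction(read.reference, read.strand, e1, s2)
        for (s1, e1), (s2, e2) in zip(read.blocks, read.blocks[1:])
    ]
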