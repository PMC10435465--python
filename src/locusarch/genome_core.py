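"""Core genomic domain types and interval algebra.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted at the I/O boundary (:mod:`locusarch.io`). Interval algebra is
strand-agnostic; strand is retained on :class:`GeneModel` only to derive
the transcriptional start site.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "CoverageTrack",
    "ContactDomainSet",
    "ContactDomainBorder",
    "merge_intervals",
    "intersect_any",
    "OverlapReport",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: touching intervals (end == start) do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def strictly_contains_position(self, pos: int) -> bool:
        """True if ``pos`` lies in the open interval (start, end)."""
        return self.start < pos < self.end

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a derived TSS.

    The TSS equals ``start`` on the plus strand and ``end - 1`` on the minus
    strand, so it always lies within the gene body.
    """

    interval: GenomicInterval
    gene_id: str
    name: str
    biotype: str = "protein_coding"
    specificity: str = "other"

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.name} requires a stranded interval")

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class CoverageTrack:
    """Binned read coverage along a single chromosome.

    ``values[i]`` is the read count (or normalized value) in bin
    ``[i * bin_size, (i + 1) * bin_size)``.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    total_mapped_reads: int
    read_length: int = 50

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.bin_size

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, i * self.bin_size, (i + 1) * self.bin_size)


@dataclass(frozen=True)
class ContactDomainBorder:
    """One boundary coordinate of a contact domain (TAD)."""

    chrom: str
    position: int
    side: str  # {"start", "end"}


@dataclass
class ContactDomainSet:
    """Ordered, non-overlapping contact domains; their edges are borders."""

    domains: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        doms = sorted(self.domains, key=lambda d: (d.chrom, d.start))
        for a, b in zip(doms, doms[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping contact domains: {a} / {b}")
        self.domains = doms

    def borders(self) -> list[ContactDomainBorder]:
        out = []
        for d in self.domains:
            out.append(ContactDomainBorder(d.chrom, d.start, "start"))
            out.append(ContactDomainBorder(d.chrom, d.end, "end"))
        return out

    def border_positions(self, chrom: str) -> list[int]:
        """Sorted unique border coordinates on ``chrom``."""
        pos = {d.start for d in self.domains if d.chrom == chrom}
        pos |= {d.end for d in self.domains if d.chrom == chrom}
        return sorted(pos)

    def borders_inside(self, interval: GenomicInterval) -> list[int]:
        """Border positions strictly inside ``interval`` (start < p < end)."""
        pos = self.border_positions(interval.chrom)
        lo = bisect.bisect_right(pos, interval.start)
        hi = bisect.bisect_left(pos, interval.end)
        return pos[lo:hi]


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose separation is <= ``gap``.

    Output is sorted and pairwise separated by more than ``gap``. Strand is
    dropped (interval algebra is strand-agnostic).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            last = merged[-1]
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end)
            )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class OverlapReport:
    any: bool
    hits: list[GenomicInterval]


def intersect_any(
    query: GenomicInterval, subjects: Sequence[GenomicInterval]
) -> OverlapReport:
    """Report which ``subjects`` overlap ``query`` (half-open semantics)."""
    hits = [s for s in subjects if query.overlaps(s)]
    return OverlapReport(any=bool(hits), hits=hits)
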