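"""STAT5 regulatory-element definition from ChIP coverage.

The stage covers four steps:

1. coverage normalization (RPKM or 1x-depth RPGC),
2. enrichment peak calling on binned coverage — a transparent bin-wise
   Poisson caller with a local-background lambda and Benjamini–Hochberg
   control, in the spirit of MACS2 but simple enough to verify against a
   closed-form oracle,
3. the replicate-consistency filter: an element must be supported by a
   peak in both replicates and overlap an H3K27ac broad peak,
4. GAS (interferon-Gamma Activated Sequence) motif scanning and
   promoter CpG-methylation summarization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .genome_core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    merge_intervals,
)

__all__ = [
    "Peak",
    "RegulatoryElement",
    "MotifHit",
    "normalize_coverage",
    "call_peaks",
    "consistent_elements",
    "scan_gas_motifs",
    "promoter_methylation",
    "CANONICAL_GAS",
    "NONCANONICAL_GAS",
]

# GAS: TTC-N3-GAA (canonical, 9 bp) and TTC-N4-GAA (non-canonical, 10 bp).
# Both are reverse-complement symmetric up to the spacer, so a forward-strand
# scan finds every site.
CANONICAL_GAS = re.compile(r"(?=(TTC[ACGT]{3}GAA))")
NONCANONICAL_GAS = re.compile(r"(?=(TTC[ACGT]{4}GAA))")

LOCAL_LAMBDA_WINDOW = 10_000  # bp, local background window


@dataclass(frozen=True)
class Peak:
    """A contiguous enriched region from one replicate."""

    interval: GenomicInterval
    summit: int
    score: float  # -log10(p) of the best bin
    signal: float  # background-subtracted mean enrichment
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains_position(self.summit):
            raise ValueError("summit must lie within the peak interval")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    kind: str  # {"canonical", "non_canonical"}
    sequence: str


@dataclass
class RegulatoryElement:
    """A replicate-consistent STAT5-bound element with H3K27ac support."""

    interval: GenomicInterval
    supporting_peaks: dict[str, list[Peak]] = field(default_factory=dict)
    h3k27ac_supported: bool = True
    gas_motifs: list[MotifHit] = field(default_factory=list)
    name: str = ""
    signal_value: float | None = None  # explicit signal, e.g. from a BED score

    @property
    def signal(self) -> float:
        """Mean across replicates of summed supporting-peak signal (or the
        explicit ``signal_value`` for elements loaded from disk)."""
        if self.signal_value is not None:
            return float(self.signal_value)
        if not self.supporting_peaks:
            return 0.0
        per_rep = [sum(p.signal for p in peaks) for peaks in self.supporting_peaks.values()]
        return float(np.mean(per_rep))


def normalize_coverage(
    track: CoverageTrack, mode: str, genome_size: int | None = None
) -> CoverageTrack:
    """Normalize binned counts by RPKM or 1x genome coverage (RPGC).

    RPKM: count / (bin length in kb x millions of mapped reads).
    RPGC: count x genome_size / (total reads x read length), i.e. coverage
    relative to uniform 1x depth.
    """
    if track.total_mapped_reads <= 0:
        raise ValueError("normalization requires total_mapped_reads > 0")
    if mode == "RPKM":
        factor = 1.0 / ((track.bin_size / 1_000) * (track.total_mapped_reads / 1e6))
    elif mode == "RPGC":
        gsize = genome_size if genome_size is not None else track.chrom_length
        factor = gsize / (track.total_mapped_reads * track.read_length)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return CoverageTrack(
        chrom=track.chrom,
        bin_size=track.bin_size,
        values=track.values * factor,
        total_mapped_reads=track.total_mapped_reads,
        read_length=track.read_length,
    )


def call_peaks(
    treatment: CoverageTrack,
    mode: str = "narrow",
    alpha: float = 0.05,
    replicate_id: str = "",
) -> list[Peak]:
    """Call enriched regions on a binned track with a Poisson model.

    Per-bin p-values are the upper Poisson tail against
    ``lambda = max(global mean, local 10 kb mean)``; BH controls the FDR
    across bins. Significant bins are merged (narrow: gap of 1 bin; broad:
    gap of 10 bins at a 10x relaxed alpha, for dispersed histone marks).
    Peaks shorter than 2 bins are dropped; the summit is the midpoint of
    the maximum-signal bin.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if mode not in {"narrow", "broad"}:
        raise ValueError(f"unknown peak mode {mode!r}")

    counts = treatment.values
    n = len(counts)
    if n == 0:
        return []
    global_lam = float(counts.mean())
    window_bins = max(1, LOCAL_LAMBDA_WINDOW // treatment.bin_size)
    if n >= window_bins:
        local_lam = uniform_filter1d(counts, size=window_bins, mode="nearest")
        lam = np.maximum(global_lam, local_lam)
    else:
        lam = np.full(n, global_lam)
    lam = np.maximum(lam, 1e-9)

    # P(X >= observed) under Poisson(lam); sf(k-1) gives the inclusive tail.
    pvals = poisson.sf(np.ceil(counts) - 1, lam)
    level = alpha * 10 if mode == "broad" else alpha
    level = min(level, 0.999)
    reject, _, _, _ = multipletests(pvals, alpha=level, method="fdr_bh")

    sig = np.flatnonzero(reject)
    if sig.size == 0:
        return []
    gap_bins = 10 if mode == "broad" else 1
    bin_size = treatment.bin_size
    bin_ivs = [
        GenomicInterval(treatment.chrom, int(i) * bin_size, (int(i) + 1) * bin_size)
        for i in sig
    ]
    merged = merge_intervals(bin_ivs, gap=gap_bins * bin_size)

    peaks: list[Peak] = []
    for iv in merged:
        if iv.length < 2 * bin_size:
            continue
        lo, hi = iv.start // bin_size, iv.end // bin_size
        seg = counts[lo:hi]
        best = lo + int(np.argmax(seg))
        summit = best * bin_size + bin_size // 2
        best_p = float(pvals[lo:hi].min())
        score = float(-np.log10(max(best_p, 1e-300)))
        signal = float(max(seg.mean() - global_lam, 0.0))
        peaks.append(
            Peak(
                interval=iv,
                summit=summit,
                score=score,
                signal=signal,
                replicate_id=replicate_id,
            )
        )
    return peaks


def consistent_elements(
    peaks_rep1: list[Peak],
    peaks_rep2: list[Peak],
    h3k27ac_broad_peaks: list[GenomicInterval],
) -> list[RegulatoryElement]:
    """Replicate-consistency + H3K27ac filter.

    For every rep1 peak overlapping a rep2 peak (>= 1 bp), the union span of
    the pair is emitted; spans are merged and only elements overlapping at
    least one H3K27ac broad peak are kept. A peak present in a single
    replicate never yields an element.
    """
    spans: list[GenomicInterval] = []
    for p1 in peaks_rep1:
        for p2 in peaks_rep2:
            if p1.interval.overlaps(p2.interval):
                spans.append(p1.interval.union_span(p2.interval))
    merged = merge_intervals(spans, gap=0)

    elements: list[RegulatoryElement] = []
    idx = 1
    for iv in merged:
        if not any(iv.overlaps(k) for k in h3k27ac_broad_peaks):
            continue
        support = {
            "rep1": [p for p in peaks_rep1 if p.interval.overlaps(iv)],
            "rep2": [p for p in peaks_rep2 if p.interval.overlaps(iv)],
        }
        elements.append(
            RegulatoryElement(
                interval=iv,
                supporting_peaks=support,
                h3k27ac_supported=True,
                name=f"element_{idx}",
            )
        )
        idx += 1
    return elements


def scan_gas_motifs(
    sequence: str, offset: int = 0, chrom: str = "chr5"
) -> list[MotifHit]:
    """Find all canonical (TTC-N3-GAA) and non-canonical (TTC-N4-GAA) GAS
    motifs on the forward strand; overlapping hits are reported.

    ``N`` bases never match. Both motif forms are reverse-complement
    symmetric, so the forward scan is exhaustive.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for kind, pattern in (("canonical", CANONICAL_GAS), ("non_canonical", NONCANONICAL_GAS)):
        for m in pattern.finditer(seq):
            matched = m.group(1)
            start = offset + m.start()
            hits.append(
                MotifHit(
                    interval=GenomicInterval(chrom, start, start + len(matched)),
                    kind=kind,
                    sequence=matched,
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.kind))
    return hits


def promoter_methylation(
    cpg_table: pd.DataFrame, gene: GeneModel, window: int = 400
) -> float | None:
    """Mean CpG beta in the ``window`` bp promoter centred on the TSS.

    The window is ``[tss - window/2, tss + window/2)``. Returns ``None``
    when no CpG falls inside it.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be even and positive")
    half = window // 2
    lo, hi = gene.tss - half, gene.tss + half
    mask = (
        (cpg_table["chrom"] == gene.chrom)
        & (cpg_table["pos"] >= lo)
        & (cpg_table["pos"] < hi)
    )
    sub = cpg_table.loc[mask, "beta"]
    if sub.empty:
        return None
    return float(sub.mean())
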