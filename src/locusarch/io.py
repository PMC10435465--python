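"""Readers and writers for the standard text formats the pipeline touches.

Conventions
-----------
* BED / bedGraph are 0-based half-open, matching the internal convention.
* GFF3 is 1-based closed on disk and converted at this boundary.
* All writers emit LF line endings and coordinate-sorted records.
* TSV files are tab-delimited with a header row; lines starting with ``#``
  are comments.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_core import CoverageTrack, GeneModel, GenomicInterval

__all__ = [
    "ParseError",
    "BedRecord",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
]


class ParseError(ValueError):
    """Malformed line in a standard-format file."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


def read_bed(path) -> list[BedRecord]:
    """Read a BED6 (or BED3/4/5) file into records."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "BED line has fewer than 3 fields")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                records.append(
                    BedRecord(GenomicInterval(chrom, start, end, strand), name, score)
                )
            except (ValueError, IndexError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(path, lineno, f"malformed BED line: {exc}") from exc
    return records


def _fmt_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return f"{score:g}"


def write_bed(path, records: Sequence[BedRecord]) -> None:
    recs = sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    with open(path, "w", newline="\n") as fh:
        for r in recs:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t"
                f"{_fmt_score(r.score)}\t{iv.strand}\n"
            )


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for item in raw.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Only ``gene`` features are consumed. 1-based closed coordinates are
    converted to 0-based half-open.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, "GFF3 line does not have 9 fields")
            chrom, _source, ftype, start, end, _score, strand, _phase, attr = fields
            if ftype != "gene":
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinates: {exc}") from exc
            if strand not in {"+", "-"}:
                raise ParseError(path, lineno, f"gene with invalid strand {strand!r}")
            attrs = _parse_gff_attributes(attr)
            gene_id = attrs.get("ID", attrs.get("gene_id", f"gene{lineno}"))
            genes.append(
                GeneModel(
                    interval=GenomicInterval(chrom, start0, end0, strand),
                    gene_id=gene_id,
                    name=attrs.get("Name", gene_id),
                    biotype=attrs.get("biotype", "protein_coding"),
                    specificity=attrs.get("specificity", "other"),
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def write_gff3_genes(path, genes: Sequence[GeneModel]) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};Name={g.name};biotype={g.biotype};"
                f"specificity={g.specificity}"
            )
            fh.write(
                f"{g.chrom}\tlocusarch\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.interval.strand}\t.\t{attrs}\n"
            )


def read_bedgraph(path) -> CoverageTrack:
    """Read a fixed-bin single-chromosome bedGraph into a coverage track.

    Track metadata (bin size, library size, read length) is carried in a
    leading ``# locusarch`` comment written by :func:`write_bedgraph`; when
    absent it is inferred from the records.
    """
    meta: dict[str, int] = {}
    chrom = None
    entries: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# locusarch"):
                    for item in line.split()[2:]:
                        key, value = item.split("=", 1)
                        meta[key] = int(value)
                continue
            if line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, "bedGraph line does not have 4 fields")
            try:
                c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(path, lineno, f"malformed bedGraph line: {exc}") from exc
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ParseError(path, lineno, "multi-chromosome bedGraph not supported")
            entries.append((s, e, v))
    if chrom is None:
        raise ParseError(path, 0, "empty bedGraph")
    entries.sort()
    bin_size = meta.get("bin_size", entries[0][1] - entries[0][0])
    n_bins = entries[-1][1] // bin_size
    import numpy as np

    values = np.zeros(n_bins, dtype=float)
    for s, e, v in entries:
        values[s // bin_size : e // bin_size] = v
    total = meta.get("total_reads", int(round(values.sum())))
    read_length = meta.get("read_length", 50)
    return CoverageTrack(
        chrom=chrom,
        bin_size=bin_size,
        values=values,
        total_mapped_reads=total,
        read_length=read_length,
    )


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Write a coverage track, run-length compressing equal adjacent bins."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"# locusarch bin_size={track.bin_size} "
            f"total_reads={track.total_mapped_reads} "
            f"read_length={track.read_length}\n"
        )
        vals = track.values
        i = 0
        n = len(vals)
        while i < n:
            j = i
            while j + 1 < n and vals[j + 1] == vals[i]:
                j += 1
            start = i * track.bin_size
            end = (j + 1) * track.bin_size
            v = vals[i]
            fh.write(f"{track.chrom}\t{start}\t{end}\t{_fmt_score(v)}\n")
            i = j + 1


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
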