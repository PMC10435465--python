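"""Contact-domain-aware assembly of multigene "complex loci".

Starting from genes induced during the pregnancy-to-lactation transition,
maximal runs of consecutive induced protein-coding genes are stitched into
candidate loci; loci are then validated against Hi-C contact-domain
borders (a locus may not contain a border in its interior), split and
shrunk where they do, extended to incorporate STAT5A-bound elements in the
flanking intergenic regions, re-checked against borders, and finally
filtered to loci with at least three member genes.

Rules applied to a locus whose span contains a domain border:

1. a two-gene locus is discarded outright;
2. larger loci are partitioned at each interior border (a gene whose own
   body straddles a border is dropped), keeping fragments with more than
   two genes;
3. kept fragments are shrunk to the span of their member genes;
4. after the STAT5A-site extension, the final list keeps loci with >= 3
   member genes.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .element_calling import RegulatoryElement
from .genome_core import ContactDomainSet, GeneModel, GenomicInterval

__all__ = [
    "ComplexLocus",
    "select_induced_genes",
    "stitch_genes",
    "apply_domain_constraints",
    "extend_with_tf_sites",
    "finalize_loci",
    "identify_complex_loci",
]

REQUIRED_CONTRASTS = ("p6_vs_L1", "p6_vs_L10")


@dataclass
class ComplexLocus:
    interval: GenomicInterval
    member_genes: list[GeneModel] = field(default_factory=list)
    incorporated_sites: list[RegulatoryElement] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)

    @property
    def member_names(self) -> list[str]:
        return [g.name for g in self.member_genes]

    def log(self, rule: str, **detail) -> None:
        self.history.append({"rule": rule, **detail})


def select_induced_genes(
    de_tables: dict[str, pd.DataFrame], genes: list[GeneModel]
) -> set[str]:
    """Flag protein-coding genes induced more than two-fold (strict) with
    adjusted p < 0.05 in at least one of the p6->L1 / p6->L10 contrasts.
    """
    for contrast in REQUIRED_CONTRASTS:
        if contrast not in de_tables:
            raise ValueError(f"missing required contrast {contrast!r}")
    coding = {g.name for g in genes if g.is_coding}
    flagged: set[str] = set()
    for contrast in REQUIRED_CONTRASTS:
        de = de_tables[contrast]
        fold = np.power(2.0, de["log2_fc"].to_numpy(dtype=float))
        padj = de["padj"].to_numpy(dtype=float)
        ok = (fold > 2.0) & (padj < 0.05)
        flagged |= set(de.loc[ok, "gene"])
    return flagged & coding


def stitch_genes(genes: list[GeneModel], flags: set[str]) -> list[ComplexLocus]:
    """Maximal runs of consecutive flagged protein-coding genes.

    Non-coding genes are invisible: they neither join nor break a run.
    Runs of any length (including singletons) are emitted; short loci are
    pruned later by the domain rules and the final >= 3 gene filter.
    """
    coding = sorted(
        (g for g in genes if g.is_coding),
        key=lambda g: (g.chrom, g.start, g.end),
    )
    loci: list[ComplexLocus] = []
    run: list[GeneModel] = []

    def close_run() -> None:
        if not run:
            return
        iv = GenomicInterval(
            run[0].chrom, min(g.start for g in run), max(g.end for g in run)
        )
        locus = ComplexLocus(interval=iv, member_genes=list(run))
        locus.log("stitch", members=[g.name for g in run])
        loci.append(locus)
        run.clear()

    for g in coding:
        if g.name in flags:
            if run and run[-1].chrom != g.chrom:
                close_run()
            run.append(g)
        else:
            close_run()
    close_run()
    return loci


def _span_of(genes: list[GeneModel]) -> GenomicInterval:
    return GenomicInterval(
        genes[0].chrom, min(g.start for g in genes), max(g.end for g in genes)
    )


def apply_domain_constraints(
    loci: list[ComplexLocus], domains: ContactDomainSet
) -> list[ComplexLocus]:
    """Validate loci against contact-domain borders (rules 1-3)."""
    out: list[ComplexLocus] = []
    for locus in loci:
        borders = domains.borders_inside(locus.interval)
        if not borders:
            locus.log("domain_check", borders_inside=0, action="pass")
            out.append(locus)
            continue
        if len(locus.member_genes) <= 2:
            locus.log(
                "domain_check", borders_inside=len(borders), action="discard_small"
            )
            continue
        # partition genes at each interior border; a gene straddling a
        # border belongs to neither side and is dropped
        segments: dict[int, list[GeneModel]] = {}
        dropped: list[str] = []
        for g in locus.member_genes:
            if any(g.start < b < g.end for b in borders):
                dropped.append(g.name)
                continue
            seg = bisect.bisect_right(borders, g.start)
            segments.setdefault(seg, []).append(g)
        for seg in sorted(segments):
            members = segments[seg]
            if len(members) <= 2:
                continue
            frag = ComplexLocus(
                interval=_span_of(members),
                member_genes=members,
                history=list(locus.history),
            )
            frag.log(
                "domain_split",
                borders=[int(b) for b in borders],
                kept=[g.name for g in members],
                dropped_straddling=dropped,
            )
            out.append(frag)
    return out


def extend_with_tf_sites(
    loci: list[ComplexLocus],
    stat5_elements: list[RegulatoryElement],
    genes: list[GeneModel],
    domains: ContactDomainSet,
) -> list[ComplexLocus]:
    """Expand each locus over STAT5A sites in the adjacent intergenic regions.

    For each flank, elements lying wholly between the terminal member gene
    and the nearest protein-coding gene outside the locus are incorporated
    and the span extended to cover them. If the extension places a contact
    domain border inside the span, the flank retracts to the outermost
    incorporated element (or the gene edge) on the locus side of the border.
    """
    coding = sorted(
        (g for g in genes if g.is_coding),
        key=lambda g: (g.chrom, g.start, g.end),
    )
    out: list[ComplexLocus] = []
    for locus in loci:
        chrom = locus.interval.chrom
        first, last = locus.member_genes[0], locus.member_genes[-1]
        member_ids = {g.gene_id for g in locus.member_genes}
        same_chrom = [g for g in coding if g.chrom == chrom and g.gene_id not in member_ids]

        left_neighbors = [g for g in same_chrom if g.end <= first.start]
        left_bound = max((g.end for g in left_neighbors), default=0)
        right_neighbors = [g for g in same_chrom if g.start >= last.end]
        right_bound = min((g.start for g in right_neighbors), default=None)

        left_sites = sorted(
            (
                e
                for e in stat5_elements
                if e.interval.chrom == chrom
                and e.interval.start >= left_bound
                and e.interval.end <= first.start
            ),
            key=lambda e: e.interval.start,
        )
        right_sites = sorted(
            (
                e
                for e in stat5_elements
                if e.interval.chrom == chrom
                and e.interval.start >= last.end
                and (right_bound is None or e.interval.end <= right_bound)
            ),
            key=lambda e: e.interval.start,
        )

        new_start = min(
            [locus.interval.start] + [e.interval.start for e in left_sites]
        )
        new_end = max([locus.interval.end] + [e.interval.end for e in right_sites])

        # re-check borders introduced by the extension and retract flank-wise
        border_pos = domains.border_positions(chrom)
        left_borders = [
            b for b in border_pos if new_start < b <= locus.interval.start
        ]
        if left_borders:
            b = max(left_borders)
            left_sites = [e for e in left_sites if e.interval.start >= b]
            new_start = min(
                [locus.interval.start] + [e.interval.start for e in left_sites]
            )
        right_borders = [
            b for b in border_pos if locus.interval.end <= b < new_end
        ]
        if right_borders:
            b = min(right_borders)
            right_sites = [e for e in right_sites if e.interval.end <= b]
            new_end = max(
                [locus.interval.end] + [e.interval.end for e in right_sites]
            )

        extended = ComplexLocus(
            interval=GenomicInterval(chrom, new_start, new_end),
            member_genes=list(locus.member_genes),
            incorporated_sites=left_sites + right_sites,
            history=list(locus.history),
        )
        extended.log(
            "tf_extension",
            incorporated=[e.name for e in left_sites + right_sites],
            span=[int(new_start), int(new_end)],
            retracted=bool(left_borders or right_borders),
        )
        out.append(extended)
    return out


def finalize_loci(loci: list[ComplexLocus]) -> list[ComplexLocus]:
    """Rule 4: keep loci with at least three member genes; sort output."""
    kept = []
    for locus in loci:
        if len(locus.member_genes) >= 3:
            locus.log("finalize", n_genes=len(locus.member_genes), action="keep")
            kept.append(locus)
    kept.sort(key=lambda l: (l.interval.chrom, l.interval.start, l.interval.end))
    return kept


def identify_complex_loci(
    genes: list[GeneModel],
    de_tables: dict[str, pd.DataFrame],
    stat5_elements: list[RegulatoryElement],
    domains: ContactDomainSet,
) -> list[ComplexLocus]:
    """Full pipeline: induce -> stitch -> domain rules -> extend -> finalize."""
    flags = select_induced_genes(de_tables, genes)
    loci = stitch_genes(genes, flags)
    loci = apply_domain_constraints(loci, domains)
    loci = extend_with_tf_sites(loci, stat5_elements, genes, domains)
    return finalize_loci(loci)
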