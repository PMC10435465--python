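"""End-to-end orchestration: simulate -> call elements -> super-enhancers ->
complex loci -> expression readouts, with a machine-readable report.

Every stage is also available as a library function; ``run_all`` wires them
together on a synthetic scenario bundle and writes text artifacts plus a
JSON report and checksum manifest, so that a fixed seed reproduces the run
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .complex_loci import identify_complex_loci
from .element_calling import (
    call_peaks,
    consistent_elements,
    promoter_methylation,
    scan_gas_motifs,
)
from .expression import (
    differential_expression,
    fold_change,
    mrna_fraction,
    percent_reduction,
)
from .genome_core import GenomicInterval
from .superenhancer import classify_superenhancers, stitch_elements
from .synthetic_data import (
    CASEIN_GENES,
    CHROM,
    SCENARIOS,
    ScenarioConfig,
    TruthSet,
    build_locus_layout,
    simulate_chip_coverage,
    simulate_counts,
    simulate_methylation,
)

__all__ = ["run_all", "compare_to_truth", "match_intervals"]

LOCUS_GENES = (
    "Csn1s1", "Csn2", "Csn1s2a", "Csn1s2b", "Odam", "Fdcsp", "Prr27", "Csn3",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _truth_to_json(truth: TruthSet) -> dict:
    return {
        "elements": [
            {
                "name": e.name,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "class": e.klass,
            }
            for e in truth.elements
        ],
        "se": None
        if truth.se_interval is None
        else {
            "chrom": truth.se_interval.chrom,
            "start": truth.se_interval.start,
            "end": truth.se_interval.end,
        },
        "loci": truth.loci,
        "effects": truth.effects,
        "induced_genes": sorted(truth.induced_genes),
        "motifs": [
            {"start": m.interval.start, "kind": m.kind, "sequence": m.sequence}
            for m in truth.motifs
        ],
    }


def run_all(
    outdir,
    seed: int,
    config: ScenarioConfig | None = None,
    scenario_names: list[str] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Run the full pipeline on the synthetic locus; return the report dict.

    Writes the scenario bundle, called elements, super-enhancer table,
    complex loci, per-genotype expression readouts, methylation summary,
    ``report.json`` and ``manifest.json`` under ``outdir``.
    """
    config = config or ScenarioConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(SCENARIOS) if scenario_names is None else list(scenario_names)

    genes, truth, domains, sequence = build_locus_layout(config)
    lio.write_fasta(outdir / "genome.fa", {CHROM: sequence})
    lio.write_gff3_genes(outdir / "genes.gff3", genes)
    lio.write_bed(
        outdir / "domains.bed",
        [lio.BedRecord(d, f"domain_{i + 1}") for i, d in enumerate(domains.domains)],
    )
    lio.write_bed(
        outdir / "truth_elements.bed",
        [lio.BedRecord(e.interval, e.name) for e in truth.elements],
    )
    (outdir / "truth.json").write_text(
        json.dumps(_truth_to_json(truth), indent=1, sort_keys=True) + "\n"
    )

    # --- element calling ---------------------------------------------------
    tracks = {}
    for mark in ("stat5", "h3k27ac"):
        for rep in (1, 2):
            track = simulate_chip_coverage(config, mark, rep, seed)
            tracks[(mark, rep)] = track
            lio.write_bedgraph(outdir / f"{mark}_rep{rep}.bedgraph", track)
    stat5_peaks = {
        rep: call_peaks(tracks[("stat5", rep)], "narrow", alpha, f"rep{rep}")
        for rep in (1, 2)
    }
    k27_peaks = [
        p.interval
        for rep in (1, 2)
        for p in call_peaks(tracks[("h3k27ac", rep)], "broad", alpha, f"rep{rep}")
    ]
    elements = consistent_elements(stat5_peaks[1], stat5_peaks[2], k27_peaks)
    for e in elements:
        e.gas_motifs = scan_gas_motifs(
            sequence[e.interval.start : e.interval.end],
            offset=e.interval.start,
            chrom=CHROM,
        )
    lio.write_bed(
        outdir / "elements.bed",
        [lio.BedRecord(e.interval, e.name, round(e.signal, 3)) for e in elements],
    )
    motif_rows = [
        {"element": e.name, "start": m.interval.start, "end": m.interval.end,
         "kind": m.kind, "sequence": m.sequence}
        for e in elements
        for m in e.gas_motifs
    ]
    lio.write_tsv(
        outdir / "motifs.tsv",
        pd.DataFrame(motif_rows, columns=["element", "start", "end", "kind", "sequence"]),
    )

    # --- super-enhancers ---------------------------------------------------
    tss_list = [g.tss for g in genes]
    regions = stitch_elements(elements, tss_list=tss_list)
    ses, se_table = classify_superenhancers(regions)
    lio.write_tsv(outdir / "superenhancers.tsv", se_table)

    # --- complex loci ------------------------------------------------------
    counts_def, meta_def = simulate_counts(config, None, seed)
    lio.write_tsv(outdir / "counts_default.tsv", counts_def, index=True)
    lio.write_tsv(outdir / "meta_default.tsv", meta_def)
    by_stage = {
        st: meta_def.loc[meta_def["stage"] == st, "sample"].tolist()
        for st in ("p6", "L1", "L10")
    }
    de_tables = {
        "p6_vs_L1": differential_expression(counts_def, by_stage["p6"], by_stage["L1"]),
        "p6_vs_L10": differential_expression(counts_def, by_stage["p6"], by_stage["L10"]),
    }
    loci = identify_complex_loci(genes, de_tables, elements, domains)
    lio.write_bed(
        outdir / "complex_loci.bed",
        [lio.BedRecord(l.interval, f"locus_{i + 1}") for i, l in enumerate(loci)],
    )
    membership = pd.DataFrame(
        [
            {"locus": f"locus_{i + 1}", "gene": g.name,
             "start": l.interval.start, "end": l.interval.end}
            for i, l in enumerate(loci)
            for g in l.member_genes
        ],
        columns=["locus", "gene", "start", "end"],
    )
    lio.write_tsv(outdir / "complex_loci_members.tsv", membership)
    (outdir / "complex_loci_history.json").write_text(
        json.dumps([l.history for l in loci], indent=1, sort_keys=True) + "\n"
    )

    # --- expression readouts per deletion scenario -------------------------
    reduction_rows = []
    for name in names:
        scen = SCENARIOS[name]
        counts, meta = simulate_counts(config, scen, seed)
        wt = meta.loc[meta["genotype"] == "WT", "sample"].tolist()
        mut = meta.loc[meta["genotype"] != "WT", "sample"].tolist()
        de = differential_expression(counts, wt, mut)
        for gene in LOCUS_GENES:
            red = percent_reduction(de, gene)
            fc = fold_change(de, gene)
            reduction_rows.append(
                {
                    "scenario": name,
                    "genotype": scen.genotype,
                    "tissue": scen.tissue,
                    "stage": scen.stage,
                    "gene": gene,
                    "percent_reduction": np.nan if red is None else round(red, 4),
                    "fold_change": np.nan if fc is None else round(fc, 6),
                    "true_effect": scen.effects.get(gene, 1.0),
                }
            )
    reductions = pd.DataFrame(reduction_rows)
    lio.write_tsv(outdir / "reductions.tsv", reductions)

    # --- casein mRNA fraction + methylation --------------------------------
    l1_samples = meta_def.loc[meta_def["stage"] == "L1", "sample"].tolist()
    _frac, frac_mean = mrna_fraction(counts_def, CASEIN_GENES, l1_samples)

    meth = simulate_methylation(config, seed)
    lio.write_tsv(outdir / "methylation.tsv", meth)
    meth_rows = []
    for tissue in sorted(meth["tissue"].unique()):
        sub = meth[meth["tissue"] == tissue]
        for g in genes:
            beta = promoter_methylation(sub, g)
            if beta is not None:
                meth_rows.append(
                    {"tissue": tissue, "gene": g.name, "promoter_beta": round(beta, 4)}
                )
    meth_summary = pd.DataFrame(meth_rows, columns=["tissue", "gene", "promoter_beta"])
    lio.write_tsv(outdir / "promoter_methylation.tsv", meth_summary)

    report = {
        "seed": int(seed),
        "n_elements_called": len(elements),
        "n_truth_elements": len(truth.elements),
        "n_stitched_regions": len(regions),
        "superenhancers": [
            {"chrom": s.interval.chrom, "start": s.interval.start,
             "end": s.interval.end, "total_signal": round(s.total_signal, 4)}
            for s in ses
        ],
        "complex_loci": [l.member_names for l in loci],
        "casein_mrna_fraction_L1": round(frac_mean, 6),
        "percent_reductions": {
            name: {
                row["gene"]: row["percent_reduction"]
                for _, row in reductions[reductions["scenario"] == name].iterrows()
                if not pd.isna(row["percent_reduction"])
            }
            for name in names
        },
        "promoter_methylation": meth_rows,
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )

    manifest = {
        "seed": int(seed),
        "config": repr(config),
        "config_sha256": hashlib.sha256(repr(config).encode()).hexdigest(),
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return report


def match_intervals(
    predicted: list[GenomicInterval],
    truth: list[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy 1:1 matching by reciprocal overlap; returns (TP, FP, FN)."""
    used = [False] * len(truth)
    tp = 0
    for p in predicted:
        best, best_frac = None, 0.0
        for i, t in enumerate(truth):
            if used[i] or p.chrom != t.chrom:
                continue
            ov = min(p.end, t.end) - max(p.start, t.start)
            if ov <= 0:
                continue
            frac = min(ov / p.length, ov / t.length)
            if frac > best_frac:
                best, best_frac = i, frac
        if best is not None and best_frac >= min_reciprocal:
            used[best] = True
            tp += 1
    return tp, len(predicted) - tp, len(truth) - tp


def compare_to_truth(outdir, min_reciprocal: float = 1e-9) -> dict:
    """Score a ``run_all`` output directory against its truth manifest."""
    outdir = Path(outdir)
    truth_path = outdir / "truth.json"
    if not truth_path.exists():
        raise ValueError(f"missing truth manifest in {outdir}")
    truth = json.loads(truth_path.read_text())

    called = [r.interval for r in lio.read_bed(outdir / "elements.bed")]
    truth_ivs = [
        GenomicInterval(e["chrom"], e["start"], e["end"]) for e in truth["elements"]
    ]
    tp, fp, fn = match_intervals(called, truth_ivs, min_reciprocal)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else (None if truth_ivs else 1.0)

    se_table = lio.read_tsv(outdir / "superenhancers.tsv")
    se_recovered = False
    se_rows = se_table[se_table["is_se"]] if len(se_table) else se_table
    if truth["se"] is not None and len(se_rows):
        t = GenomicInterval(truth["se"]["chrom"], truth["se"]["start"], truth["se"]["end"])
        for _, row in se_rows.iterrows():
            p = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            ov = min(p.end, t.end) - max(p.start, t.start)
            # the SE span itself is held to >= 50% reciprocal overlap
            if ov > 0 and min(ov / p.length, ov / t.length) >= 0.5:
                se_recovered = True

    members = lio.read_tsv(outdir / "complex_loci_members.tsv")
    called_loci = [
        sorted(g["gene"].tolist()) for _, g in members.groupby("locus")
    ] if len(members) else []
    truth_loci = [sorted(l) for l in truth["loci"]]
    loci_match = sorted(called_loci) == sorted(truth_loci)

    reductions = lio.read_tsv(outdir / "reductions.tsv")
    effect_errors = []
    for _, row in reductions.iterrows():
        if row["true_effect"] == 1.0 or pd.isna(row["percent_reduction"]):
            continue
        true_red = 100.0 * (1.0 - row["true_effect"])
        effect_errors.append(
            {
                "scenario": row["scenario"],
                "gene": row["gene"],
                "true_reduction": true_red,
                "estimated_reduction": row["percent_reduction"],
                "abs_error": abs(row["percent_reduction"] - true_red),
            }
        )
    return {
        "element_tp": tp,
        "element_fp": fp,
        "element_fn": fn,
        "element_precision": precision,
        "element_recall": recall,
        "se_recovered": se_recovered,
        "loci_match": loci_match,
        "called_loci": called_loci,
        "effect_errors": effect_errors,
    }
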