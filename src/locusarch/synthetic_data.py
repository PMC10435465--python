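"""Self-contained emulation of the extended casein locus study.

The generator lays out a ~330 kbp core locus (inside a 400 kbp window)
hosting the eight named genes of three tissue specificities, twenty
STAT5-bound candidate regulatory elements — including a four-module,
10 kbp super-enhancer between Csn1s2b and Odam — embedded GAS motifs,
contact domains, negative-binomial RNA-seq counts across developmental
stages and deletion genotypes, promoter CpG methylation and qPCR Ct
tables. Every downstream stage of the pipeline is testable against the
returned :class:`TruthSet` without any external download.

Effect sizes of the packaged deletion scenarios follow the study's
printed readouts (e.g. the full super-enhancer deletion leaves Csn1s2b at
7%, Csn3 at 2% and Odam at 0.2% of wild-type mammary expression).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .element_calling import MotifHit, scan_gas_motifs
from .genome_core import (
    ContactDomainSet,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "TruthSet",
    "TruthElement",
    "SCENARIOS",
    "CASEIN_GENES",
    "build_locus_layout",
    "simulate_chip_coverage",
    "simulate_counts",
    "simulate_methylation",
    "simulate_qpcr",
]

CHROM = "chr5"
CASEIN_GENES = ("Csn1s1", "Csn2", "Csn1s2a", "Csn1s2b", "Csn3")

# ---------------------------------------------------------------------------
# default locus layout: (name, start, end, strand, biotype, specificity)
# ---------------------------------------------------------------------------

DEFAULT_GENES: tuple[tuple, ...] = (
    ("FillerL1", 2_000, 8_000, "+", "protein_coding", "filler"),
    ("FillerL2", 12_000, 18_000, "+", "protein_coding", "filler"),
    ("Csn1s1", 40_000, 55_000, "+", "protein_coding", "mammary"),
    ("Csn2", 90_000, 98_000, "-", "protein_coding", "mammary"),
    ("Csn1s2a", 173_000, 188_000, "+", "protein_coding", "mammary"),
    ("Csn1s2b", 210_000, 222_000, "+", "protein_coding", "mammary"),
    ("Odam", 255_000, 265_000, "+", "protein_coding", "dual"),
    ("Gm49906", 266_500, 268_500, "+", "lncRNA", "mammary"),
    ("Fdcsp", 270_000, 276_000, "-", "protein_coding", "salivary"),
    ("Prr27", 285_000, 291_000, "+", "protein_coding", "salivary"),
    ("Csn3", 330_000, 340_000, "+", "protein_coding", "mammary"),
    ("FillerR1", 370_000, 375_000, "+", "protein_coding", "filler"),
    ("FillerR2", 380_000, 386_000, "+", "protein_coding", "filler"),
)

# (name, start, end, class, motif kinds)
DEFAULT_ELEMENTS: tuple[tuple, ...] = (
    ("Csn1s1-E1", 28_500, 28_800, "local_enhancer", ()),
    ("CTCF-1", 34_000, 34_200, "CTCF", ()),
    ("Csn1s1-E2", 36_400, 36_700, "local_enhancer", ()),
    ("Csn1s1-P", 39_800, 40_000, "promoter_element", ("canonical",)),
    ("Csn2-P", 98_000, 98_200, "promoter_element", ("canonical", "non_canonical")),
    ("Csn2-E1", 104_000, 104_300, "local_enhancer", ("canonical",)),
    ("Csn2-E2", 123_000, 123_300, "local_enhancer", ("canonical",)),
    ("Csn2-E3", 133_000, 133_300, "local_enhancer", ()),
    ("Csn1s2a-P", 172_800, 173_000, "promoter_element", ("canonical",)),
    ("Csn1s2b-E1", 207_900, 208_200, "local_enhancer", ("canonical",)),
    ("Csn1s2b-P", 209_700, 209_900, "promoter_element", ("canonical",)),
    ("SE-E1", 240_000, 241_200, "SE_module", ("canonical",)),
    ("CTCF-2", 242_000, 242_200, "CTCF", ()),
    ("SE-E2", 243_000, 244_200, "SE_module", ("canonical",)),
    ("SE-E3", 246_000, 247_200, "SE_module", ("canonical",)),
    ("CTCF-3", 247_600, 247_800, "CTCF", ()),
    ("SE-E4", 248_800, 250_000, "SE_module", ("canonical",)),
    ("Csn3-E1", 323_000, 323_300, "local_enhancer", ()),
    ("Csn3-E2", 329_300, 329_600, "local_enhancer", ("canonical", "canonical")),
    ("CTCF-4", 361_000, 361_200, "CTCF", ()),
)

# expected L1 wild-type counts per gene (mammary) / adult counts (salivary)
MAMMARY_BASELINE = {
    "Csn1s1": 500_000.0,
    "Csn2": 1_200_000.0,
    "Csn1s2a": 450_000.0,
    "Csn1s2b": 250_000.0,
    "Csn3": 350_000.0,
    "Odam": 200.0,
    "Gm49906": 30.0,
    "Fdcsp": 0.2,
    "Prr27": 0.5,
    "FillerL1": 500.0,
    "FillerL2": 500.0,
    "FillerR1": 500.0,
    "FillerR2": 500.0,
}
SALIVARY_BASELINE = {
    "Csn1s1": 50.0,
    "Csn2": 60.0,
    "Csn1s2a": 40.0,
    "Csn1s2b": 30.0,
    "Csn3": 500.0,
    "Odam": 150_000.0,
    "Gm49906": 20.0,
    "Fdcsp": 300_000.0,
    "Prr27": 80_000.0,
    "FillerL1": 500.0,
    "FillerL2": 500.0,
    "FillerR1": 500.0,
    "FillerR2": 500.0,
}

# developmental multipliers on the L1 baseline (mammary only). Caseins are
# induced ~3,000-fold virgin -> L1 and another 10-fold to L10 (4-5 orders
# virgin -> L10); Odam turns on between p6 and L1.
_CASEIN_STAGES = {"virgin": 3e-4, "p6": 2e-3, "p18": 1.0, "L1": 1.0, "L10": 10.0}
_FLAT_STAGES = {"virgin": 1.0, "p6": 1.0, "p18": 1.0, "L1": 1.0, "L10": 1.0}
STAGE_FACTORS: dict[str, dict[str, float]] = {
    **{g: _CASEIN_STAGES for g in CASEIN_GENES},
    "Odam": {"virgin": 0.02, "p6": 0.5, "p18": 1.0, "L1": 1.0, "L10": 3.0},
    "Gm49906": {"virgin": 0.03, "p6": 0.03, "p18": 1.0, "L1": 1.0, "L10": 1.0},
}

N_BACKGROUND_GENES = 300
# STAT5 footprint peak heights (x background) per element class; H3K27ac is
# broad and shared across classes
CHIP_ENRICHMENT = {
    "SE_module": 50.0,
    "local_enhancer": 25.0,
    "promoter_element": 20.0,
    "CTCF": 25.0,
}
K27AC_ENRICHMENT = 35.0
STAT5_FOOTPRINT = 300  # bp, punctate TF binding width
K27AC_FLANK = 500  # bp, broad acetylation shoulder around an element
QPCR_TARGETS = ("Csn1s1", "Csn2", "Csn1s2a", "Csn1s2b", "Odam", "Csn3")


@dataclass(frozen=True)
class Scenario:
    """One figure-level deletion experiment: tissue, stage, group sizes and
    the per-gene multiplicative effects of the mutant genotype."""

    name: str
    genotype: str
    tissue: str = "mammary"
    stage: str = "L1"
    n_wt: int = 4
    n_mut: int = 4
    effects: dict[str, float] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.effects.values()):
            raise ValueError("effects must be >= 0")


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in (
        Scenario(
            "dSE-p18",
            "dSE",
            stage="p18",
            n_wt=4,
            n_mut=4,
            effects={
                "Csn1s1": 0.50,
                "Csn2": 0.70,
                "Csn1s2a": 0.60,
                "Csn1s2b": 0.07,
                "Csn3": 0.02,
                "Odam": 0.002,
            },
            description="full 10 kbp super-enhancer deletion, mammary p18",
        ),
        Scenario(
            "dSE-p6",
            "dSE",
            stage="p6",
            n_wt=3,
            n_mut=4,
            effects={g: 0.02 for g in (*CASEIN_GENES, "Odam")},
            description="super-enhancer deletion at early pregnancy",
        ),
        Scenario(
            "dSE-salivary",
            "dSE",
            tissue="salivary",
            stage="adult",
            n_wt=3,
            n_mut=3,
            effects={"Odam": 0.001, "Fdcsp": 0.01, "Csn3": 0.12},
            description="super-enhancer deletion, salivary gland",
        ),
        Scenario(
            "dOdam",
            "dOdam",
            stage="L1",
            n_wt=3,
            n_mut=3,
            effects={"Odam": 0.0, "Csn3": 2.0},
            description="Odam gene deletion: SE moves next to Fdcsp, "
            "Csn3 doubles, Fdcsp stays silent in mammary",
        ),
        Scenario(
            "csn3-dE1", "csn3-dE1", stage="p18", n_wt=3, n_mut=3,
            effects={"Csn3": 0.55},
            description="Csn3 distal enhancer deletion",
        ),
        Scenario(
            "csn3-dE2S", "csn3-dE2S", stage="p18", n_wt=3, n_mut=3,
            effects={"Csn3": 0.02},
            description="deletion of the two GAS motifs in Csn3-E2",
        ),
        Scenario(
            "csn3-dE2SN", "csn3-dE2SN", stage="p18", n_wt=3, n_mut=3,
            effects={"Csn3": 0.005},
            description="deletion of Csn3-E2 GAS motifs plus the NFIB site",
        ),
        Scenario(
            "csn1s1-dE1", "csn1s1-dE1", stage="L1", n_wt=5, n_mut=5,
            effects={},
            description="Csn1s1 distal enhancer GR-motif deletion (no effect)",
        ),
        Scenario(
            "csn1s1-dE2", "csn1s1-dE2", stage="L1", n_wt=5, n_mut=5,
            effects={"Csn1s1": 0.35},
            description="Csn1s1 proximal enhancer NFIB-site deletion",
        ),
        Scenario(
            "csn2-dE1", "csn2-dE1", stage="L1", n_wt=4, n_mut=3,
            effects={},
            description="Csn2 -6 kb enhancer deletion (no significant effect)",
        ),
        Scenario(
            "csn2-dE23", "csn2-dE23", stage="L1", n_wt=4, n_mut=4,
            effects={},
            description="combined Csn2 -25/-35 kb enhancer deletion",
        ),
        Scenario(
            "csn2-dE123", "csn2-dE123", stage="L1", n_wt=4, n_mut=4,
            effects={"Csn2": 0.5},
            description="triple Csn2 enhancer deletion",
        ),
        Scenario(
            "csn2-dP", "csn2-dP", stage="L1", n_wt=4, n_mut=3,
            effects={"Csn2": 0.2},
            description="disabling mutations in both Csn2 promoter GAS motifs",
        ),
        Scenario(
            "csn2-dP-E123", "csn2-dP-E123", stage="L1", n_wt=4, n_mut=4,
            effects={"Csn2": 1e-4},
            description="promoter GAS mutations plus triple enhancer deletion",
        ),
        Scenario(
            "csn2-dP-A", "csn2-dP-A", stage="L1", n_wt=4, n_mut=3,
            effects={},
            description="canonical promoter GAS motif mutation alone",
        ),
        Scenario(
            "csn2-dP-B", "csn2-dP-B", stage="L1", n_wt=4, n_mut=3,
            effects={"Csn2": 0.2},
            description="non-canonical promoter GAS motif mutation alone",
        ),
        Scenario(
            "csn2-dP-E123-A", "csn2-dP-E123-A", stage="L1", n_wt=4, n_mut=4,
            effects={"Csn2": 0.5},
            description="canonical GAS mutation plus triple enhancer deletion",
        ),
        Scenario(
            "csn2-dP-E123-B", "csn2-dP-E123-B", stage="L1", n_wt=4, n_mut=4,
            effects={"Csn2": 1e-4},
            description="non-canonical GAS mutation plus triple enhancer deletion",
        ),
    )
}


@dataclass
class ScenarioConfig:
    """Study-level constants of the emulated locus.

    Defaults are the study conditions; they are exposed for sensitivity
    analysis, not for routine adjustment.
    """

    seed: int = 7
    locus_span: int = 400_000
    bin_size: int = 25
    genes: tuple = DEFAULT_GENES
    elements: tuple = DEFAULT_ELEMENTS
    domain_split: bool = False
    nb_dispersion: float = 0.05
    chip_background: float = 1.0
    enrichment_scale: float = 1.0
    qpcr_noise_sd: float = 0.15
    casein_fraction_l1: float = 0.55
    n_background_genes: int = N_BACKGROUND_GENES

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 < self.casein_fraction_l1 < 1):
            raise ValueError("casein_fraction_l1 must be in (0, 1)")
        spans = sorted((g[1], g[2], g[0]) for g in self.genes)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping gene placements: {n1} / {n2}")
        for name, start, end, _klass, _motifs in self.elements:
            if not (0 <= start < end <= self.locus_span):
                raise ValueError(f"element {name} outside locus span")


@dataclass(frozen=True)
class TruthElement:
    name: str
    interval: GenomicInterval
    klass: str


@dataclass
class TruthSet:
    """Ground truth used to score recovery by the pipeline stages."""

    elements: list[TruthElement]
    se_interval: GenomicInterval | None
    loci: list[list[str]]
    effects: dict[str, dict[str, float]]
    motifs: list[MotifHit]
    induced_genes: set[str]

    @property
    def element_intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.elements]


def _rng(seed: int, *streams: str) -> np.random.Generator:
    codes = [zlib.crc32(s.encode()) & 0x7FFFFFFF for s in streams]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *codes])


def _gene_models(config: ScenarioConfig) -> list[GeneModel]:
    genes = []
    for name, start, end, strand, biotype, spec in config.genes:
        genes.append(
            GeneModel(
                interval=GenomicInterval(CHROM, start, end, strand),
                gene_id=name,
                name=name,
                biotype="protein_coding" if biotype == "protein_coding" else "other",
                specificity=spec,
            )
        )
    genes.sort(key=lambda g: g.start)
    return genes


def _domains(config: ScenarioConfig) -> ContactDomainSet:
    if config.domain_split:
        spans = [(0, 10_000), (10_000, 200_000), (200_000, 380_000), (380_000, 400_000)]
    else:
        spans = [(0, 10_000), (10_000, 380_000), (380_000, 400_000)]
    return ContactDomainSet([GenomicInterval(CHROM, s, e) for s, e in spans])


def _true_loci(genes: list[GeneModel], induced: set[str], domains: ContactDomainSet) -> list[list[str]]:
    """First-principles expectation: maximal induced coding runs, split at
    borders (straddling genes dropped), fragments/loci with >= 3 genes."""
    coding = [g for g in genes if g.is_coding]
    runs: list[list[GeneModel]] = []
    cur: list[GeneModel] = []
    for g in coding:
        if g.name in induced:
            cur.append(g)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        borders = [
            b
            for b in domains.border_positions(CHROM)
            if min(g.start for g in run) < b < max(g.end for g in run)
        ]
        fragments: dict[int, list[str]] = {}
        for g in run:
            if any(g.start < b < g.end for b in borders):
                continue
            key = sum(1 for b in borders if b <= g.start)
            fragments.setdefault(key, []).append(g.name)
        if not borders and len(run) >= 3:
            out.append([g.name for g in run])
        elif borders:
            if len(run) <= 2:
                continue
            out.extend(names for _k, names in sorted(fragments.items()) if len(names) >= 3)
    return out


def _embed_motifs(
    seq: bytearray, config: ScenarioConfig, rng: np.random.Generator
) -> list[MotifHit]:
    """Write configured GAS motifs into the sequence and scrub spurious ones
    so that the truth motif list equals an exhaustive scan exactly."""
    truth: list[tuple[int, str, str]] = []  # (start, kind, seq)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _name, start, _end, _klass, kinds in config.elements:
        pos = start + 30
        for kind in kinds:
            n_spacer = 3 if kind == "canonical" else 4
            spacer = alphabet[rng.integers(0, 4, n_spacer)].tobytes()
            motif = b"TTC" + spacer + b"GAA"
            seq[pos : pos + len(motif)] = motif
            truth.append((pos, kind, motif.decode()))
            pos += 25
    protected = [(p, p + len(s)) for p, _k, s in truth]
    truth_keys = {(p, k) for p, k, _s in truth}

    for _round in range(12):
        text = seq.decode()
        spurious = [
            h
            for h in scan_gas_motifs(text, chrom=CHROM)
            if (h.interval.start, h.kind) not in truth_keys
        ]
        if not spurious:
            break
        for hit in spurious:
            for p in range(hit.interval.start, hit.interval.end):
                if not any(lo <= p < hi for lo, hi in protected):
                    seq[p] = ord("C") if seq[p] != ord("C") else ord("A")
                    break
    else:  # pragma: no cover - scrubbing always converges on random sequence
        raise RuntimeError("GAS motif scrubbing did not converge")

    hits = [
        MotifHit(
            interval=GenomicInterval(CHROM, p, p + len(s)),
            kind=k,
            sequence=s,
        )
        for p, k, s in truth
    ]
    hits.sort(key=lambda h: (h.interval.start, h.kind))
    return hits


_LAYOUT_CACHE: dict[str, tuple] = {}


def build_locus_layout(
    config: ScenarioConfig | None = None,
) -> tuple[list[GeneModel], TruthSet, ContactDomainSet, str]:
    """Deterministically construct genes, truth, contact domains and genome
    sequence for the configured locus.

    Results are cached per configuration (the layout depends only on the
    config, never on a run seed); callers must treat them as read-only.
    """
    config = config or ScenarioConfig()
    key = repr(config)
    if key in _LAYOUT_CACHE:
        return _LAYOUT_CACHE[key]
    genes = _gene_models(config)
    domains = _domains(config)

    rng = _rng(config.seed, "layout")
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(alphabet[rng.integers(0, 4, config.locus_span)].tobytes())
    motifs = _embed_motifs(seq, config, rng)

    elements = [
        TruthElement(name, GenomicInterval(CHROM, start, end), klass)
        for name, start, end, klass, _kinds in config.elements
    ]
    se_modules = [e for e in elements if e.klass == "SE_module"]
    se_interval = None
    if se_modules:
        se_interval = GenomicInterval(
            CHROM,
            min(e.interval.start for e in se_modules),
            max(e.interval.end for e in se_modules),
        )

    induced = {
        g.name
        for g in genes
        if g.is_coding
        and g.name in STAGE_FACTORS
        and max(STAGE_FACTORS[g.name]["L1"], STAGE_FACTORS[g.name]["L10"])
        / STAGE_FACTORS[g.name]["p6"]
        > 2
    }
    truth = TruthSet(
        elements=elements,
        se_interval=se_interval,
        loci=_true_loci(genes, induced, domains),
        effects={s.genotype: dict(s.effects) for s in SCENARIOS.values()},
        motifs=motifs,
        induced_genes=induced,
    )
    result = (genes, truth, domains, seq.decode())
    _LAYOUT_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------


def simulate_chip_coverage(
    config: ScenarioConfig,
    mark: str,
    replicate: int,
    seed: int,
) -> CoverageTrack:
    """Poisson-binned ChIP coverage for ``mark`` ("stat5" or "h3k27ac").

    Background bins are Poisson(lambda_bg); element bins are enriched with a
    triangular profile for the punctate TF and a broad flat profile
    (element +/- 500 bp) for H3K27ac. Replicates share the truth layout and
    differ only in counting noise.
    """
    if mark not in {"stat5", "h3k27ac"}:
        raise ValueError(f"unknown mark {mark!r}")
    n_bins = config.locus_span // config.bin_size
    lam = np.full(n_bins, config.chip_background, dtype=float)
    centers = (np.arange(n_bins) + 0.5) * config.bin_size

    for _name, start, end, klass, _kinds in config.elements:
        if mark == "stat5":
            # punctate TF footprint centred on the element
            height = CHIP_ENRICHMENT[klass]
            mid = (start + end) / 2.0
            half = min(end - start, STAT5_FOOTPRINT) / 2.0
            lo, hi = mid - half, mid + half
        else:
            # broad acetylation across the element and its shoulders
            height = K27AC_ENRICHMENT
            lo, hi = start - K27AC_FLANK, end + K27AC_FLANK
            mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        boost = (height - 1.0) * config.enrichment_scale
        mask = (centers >= lo) & (centers < hi)
        shape = 1.0 - np.abs(centers[mask] - mid) / half
        lam[mask] += config.chip_background * boost * shape

    rng = _rng(seed, "chip", mark, f"rep{replicate}")
    values = rng.poisson(lam).astype(float)
    return CoverageTrack(
        chrom=CHROM,
        bin_size=config.bin_size,
        values=values,
        total_mapped_reads=int(values.sum()),
        read_length=50,
    )


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def _background_baselines(config: ScenarioConfig) -> pd.Series:
    """Deterministic log-spaced background transcriptome scaled so the five
    caseins take the configured share of the wild-type L1 mammary library."""
    raw = np.geomspace(100.0, 30_000.0, config.n_background_genes)
    casein_total = sum(MAMMARY_BASELINE[g] for g in CASEIN_GENES)
    other_known = sum(v for g, v in MAMMARY_BASELINE.items() if g not in CASEIN_GENES)
    f = config.casein_fraction_l1
    target = casein_total * (1.0 / f - 1.0) - other_known
    if target <= 0:
        raise ValueError("casein_fraction_l1 incompatible with locus baselines")
    raw = raw * (target / raw.sum())
    names = [f"bg{i + 1:04d}" for i in range(config.n_background_genes)]
    return pd.Series(raw, index=names)


def _expected_means(config: ScenarioConfig, tissue: str, stage: str) -> pd.Series:
    if tissue == "mammary":
        base = pd.Series(MAMMARY_BASELINE)
        factors = pd.Series(
            {g: STAGE_FACTORS.get(g, _FLAT_STAGES)[stage] for g in base.index}
        )
        locus = base * factors
    elif tissue == "salivary":
        locus = pd.Series(SALIVARY_BASELINE)
    else:
        raise ValueError(f"unknown tissue {tissue!r}")
    return pd.concat([locus, _background_baselines(config)])


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion <= 1e-6:
        out[pos] = rng.poisson(mu[pos])
    else:
        n = 1.0 / dispersion
        p = n / (n + mu[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    config: ScenarioConfig,
    scenario: Scenario | str | None,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a count matrix and sample metadata.

    ``scenario=None`` (or ``"default"``) produces the wild-type mammary
    developmental panel (virgin/p6 n=3, L1/L10 n=4); a deletion scenario
    produces wild-type and mutant groups at the scenario's tissue/stage.
    Counts are NB(mean = baseline x stage factor x genotype effect,
    shared dispersion).
    """
    if isinstance(scenario, str) and scenario not in {"default", ""}:
        scenario = SCENARIOS[scenario]
    is_default = scenario in (None, "default", "")
    if is_default:
        groups = [("WT", st, n, {}) for st, n in
                  (("virgin", 3), ("p6", 3), ("L1", 4), ("L10", 4))]
        tissue = "mammary"
        rng = _rng(seed, "counts", "default")
    else:
        groups = [
            ("WT", scenario.stage, scenario.n_wt, {}),
            (scenario.genotype, scenario.stage, scenario.n_mut, scenario.effects),
        ]
        tissue = scenario.tissue
        rng = _rng(seed, "counts", scenario.name)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    gene_index = None
    for genotype, stage, n_rep, effects in groups:
        means = _expected_means(config, tissue, stage if tissue == "mammary" else "L1")
        if effects:
            eff = pd.Series(1.0, index=means.index)
            for g, v in effects.items():
                if g in eff.index:
                    eff[g] = v
            means = means * eff
        gene_index = means.index
        for r in range(1, n_rep + 1):
            sample = f"{genotype}_{stage}_{r}" if is_default else f"{genotype}_{r}"
            cols[sample] = _nb_draw(rng, means.to_numpy(), config.nb_dispersion)
            meta_rows.append(
                {
                    "sample": sample,
                    "tissue": tissue,
                    "stage": stage,
                    "genotype": genotype,
                    "replicate": r,
                }
            )
    counts = pd.DataFrame(cols, index=gene_index)
    counts.index.name = "gene"
    meta = pd.DataFrame(meta_rows)
    return counts, meta


# ---------------------------------------------------------------------------
# methylation and qPCR
# ---------------------------------------------------------------------------

_METHYLATION_TARGETS = {
    # (tissue, specificity) -> expected promoter beta
    ("mammary", "mammary"): 0.05,
    ("mammary", "dual"): 0.08,
    ("mammary", "salivary"): 0.95,
    ("mammary", "filler"): 0.10,
    ("liver", "mammary"): 0.90,
    ("liver", "dual"): 0.90,
    ("liver", "salivary"): 0.90,
    ("liver", "filler"): 0.10,
}


def simulate_methylation(
    config: ScenarioConfig,
    seed: int,
    tissues: tuple[str, ...] = ("mammary", "liver"),
) -> pd.DataFrame:
    """CpG beta values around every gene TSS (+/- 1 kb) per tissue.

    Active mammary promoters are hypomethylated; the Fdcsp promoter is
    essentially fully methylated in mammary tissue; casein promoters are
    highly methylated in liver.
    """
    genes, _truth, _domains, seq = build_locus_layout(config)
    rng = _rng(seed, "methylation")
    rows = []
    for tissue in tissues:
        for g in genes:
            lo, hi = max(g.tss - 1_000, 0), min(g.tss + 1_000, len(seq) - 1)
            window = seq[lo:hi]
            cpgs = [lo + i for i in range(len(window) - 1) if window[i : i + 2] == "CG"]
            mean_beta = _METHYLATION_TARGETS.get((tissue, g.specificity), 0.5)
            conc = 60.0
            betas = rng.beta(mean_beta * conc, (1.0 - mean_beta) * conc, len(cpgs))
            for pos, beta in zip(cpgs, betas):
                rows.append(
                    {
                        "chrom": CHROM,
                        "pos": pos,
                        "beta": float(beta),
                        "tissue": tissue,
                        "gene": g.name,
                    }
                )
    return pd.DataFrame(rows)


def simulate_qpcr(
    config: ScenarioConfig,
    scenario: Scenario | str,
    seed: int,
) -> pd.DataFrame:
    """Ct table for the TaqMan panel, normalized-to-Gapdh design.

    Ct = gene base Ct - log2(genotype effect) + Gaussian noise; Gapdh is
    constant across genotypes in expectation. A silent target (effect 0)
    reports the non-detect ceiling Ct = 40.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    rng = _rng(seed, "qpcr", scenario.name)
    means = _expected_means(config, scenario.tissue,
                            scenario.stage if scenario.tissue == "mammary" else "L1")
    rows = []
    for genotype, n_rep, effects in (
        ("WT", scenario.n_wt, {}),
        (scenario.genotype, scenario.n_mut, scenario.effects),
    ):
        for r in range(1, n_rep + 1):
            sample = f"{genotype}_{r}"
            for gene in QPCR_TARGETS:
                base_ct = 34.0 - np.log2(max(means[gene], 1.0))
                effect = effects.get(gene, 1.0)
                if effect <= 0:
                    ct = 40.0
                else:
                    ct = base_ct - np.log2(effect)
                    if config.qpcr_noise_sd > 0:
                        ct += rng.normal(0.0, config.qpcr_noise_sd)
                rows.append(
                    {"sample": sample, "group": genotype, "gene": gene,
                     "ct": float(min(ct, 40.0))}
                )
            gapdh = 18.0
            if config.qpcr_noise_sd > 0:
                gapdh += rng.normal(0.0, config.qpcr_noise_sd)
            rows.append(
                {"sample": sample, "group": genotype, "gene": "Gapdh",
                 "ct": float(gapdh)}
            )
    return pd.DataFrame(rows)
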