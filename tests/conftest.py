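import pytest

from locusarch.element_calling import RegulatoryElement, call_peaks, consistent_elements
from locusarch.genome_core import GenomicInterval
from locusarch.synthetic_data import ScenarioConfig, build_locus_layout, simulate_chip_coverage


@pytest.fixture(scope="session")
def config():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def layout(config):
    """(genes, truth, domains, sequence) for the default locus."""
    return build_locus_layout(config)


@pytest.fixture(scope="session")
def called_elements(config):
    """Replicate-consistent elements called on seed-1 simulated coverage."""
    tracks = {
        (m, r): simulate_chip_coverage(config, m, r, seed=1)
        for m in ("stat5", "h3k27ac")
        for r in (1, 2)
    }
    s1 = call_peaks(tracks[("stat5", 1)], "narrow", 0.05, "rep1")
    s2 = call_peaks(tracks[("stat5", 2)], "narrow", 0.05, "rep2")
    k27 = [
        p.interval
        for r in (1, 2)
        for p in call_peaks(tracks[("h3k27ac", r)], "broad", 0.05)
    ]
    return consistent_elements(s1, s2, k27)


@pytest.fixture
def make_element():
    """Factory for bare regulatory elements with an explicit signal."""

    def _make(start, end, signal=1.0, chrom="chr5", name=""):
        return RegulatoryElement(
            interval=GenomicInterval(chrom, start, end),
            name=name or f"e{start}",
            signal_value=signal,
        )

    return _make
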