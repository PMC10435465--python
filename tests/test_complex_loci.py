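"""The contact-domain-aware complex-locus assembly rules."""

import numpy as np
import pandas as pd
import pytest

from locusarch.complex_loci import (
    apply_domain_constraints,
    extend_with_tf_sites,
    finalize_loci,
    identify_complex_loci,
    select_induced_genes,
    stitch_genes,
)
from locusarch.element_calling import RegulatoryElement
from locusarch.genome_core import ContactDomainSet, GeneModel, GenomicInterval
from oracles import random_genome, reference_complex_loci


def gene(name, start, end, coding=True, strand="+"):
    return GeneModel(
        GenomicInterval("c", start, end, strand),
        name,
        name,
        "protein_coding" if coding else "other",
    )


def element(name, start, end):
    return RegulatoryElement(
        interval=GenomicInterval("c", start, end), name=name, signal_value=1.0
    )


def domains(*spans):
    return ContactDomainSet([GenomicInterval("c", s, e) for s, e in spans])


def de_table(rows):
    """rows: (gene, log2_fc, padj)"""
    return pd.DataFrame(
        [{"gene": g, "log2_fc": f, "padj": p} for g, f, p in rows],
        columns=["gene", "log2_fc", "padj"],
    )


class TestSelectInducedGenes:
    GENES = [gene("A", 0, 100), gene("B", 200, 300), gene("N", 400, 500, coding=False)]

    def run(self, l1_rows, l10_rows=()):
        return select_induced_genes(
            {"p6_vs_L1": de_table(l1_rows), "p6_vs_L10": de_table(l10_rows)},
            self.GENES,
        )

    def test_fold_and_padj_thresholds(self):
        assert self.run([("A", 2.0, 0.01)]) == {"A"}  # fold 4

    def test_exactly_twofold_is_not_induced(self):
        assert self.run([("A", 1.0, 0.001)]) == set()  # fold exactly 2

    def test_padj_at_threshold_not_induced(self):
        assert self.run([("A", 3.32, 0.06), ("A", 3.32, 0.05)]) == set()

    def test_either_contrast_suffices(self):
        assert self.run([("A", 0.5, 0.9)], [("A", 3.0, 0.001)]) == {"A"}

    def test_noncoding_never_flagged(self):
        assert self.run([("N", 5.0, 1e-9)]) == set()

    def test_missing_contrast_is_an_error(self):
        with pytest.raises(ValueError):
            select_induced_genes({"p6_vs_L1": de_table([])}, self.GENES)


class TestStitchGenes:
    def test_consecutive_flagged_run(self):
        genes = [gene("A", 0, 100), gene("B", 200, 300), gene("C", 400, 500)]
        (locus,) = stitch_genes(genes, {"A", "B", "C"})
        assert locus.member_names == ["A", "B", "C"]
        assert (locus.interval.start, locus.interval.end) == (0, 500)

    def test_unflagged_coding_gene_breaks_run(self):
        genes = [gene("A", 0, 100), gene("X", 200, 300), gene("B", 400, 500)]
        loci = stitch_genes(genes, {"A", "B"})
        assert [l.member_names for l in loci] == [["A"], ["B"]]

    def test_noncoding_gene_is_invisible(self):
        genes = [gene("A", 0, 100), gene("N", 200, 300, coding=False),
                 gene("B", 400, 500)]
        (locus,) = stitch_genes(genes, {"A", "B"})
        assert locus.member_names == ["A", "B"]


class TestDomainConstraints:
    def test_locus_without_interior_border_passes(self):
        genes = [gene("A", 100, 200), gene("B", 300, 400), gene("C", 500, 600)]
        (locus,) = stitch_genes(genes, {"A", "B", "C"})
        (out,) = apply_domain_constraints([locus], domains((0, 100), (100, 700)))
        assert out.member_names == ["A", "B", "C"]

    def test_two_gene_locus_on_border_discarded(self):
        genes = [gene("A", 100, 200), gene("B", 300, 400)]
        (locus,) = stitch_genes(genes, {"A", "B"})
        assert apply_domain_constraints([locus], domains((0, 250), (250, 500))) == []

    def test_split_keeps_and_shrinks_large_fragment(self):
        genes = [gene(f"G{i}", i * 1000, i * 1000 + 500) for i in range(1, 6)]
        (locus,) = stitch_genes(genes, {g.name for g in genes})
        # border between gene 3 and gene 4
        (frag,) = apply_domain_constraints(
            [locus], domains((0, 3_800), (3_800, 10_000))
        )
        assert frag.member_names == ["G1", "G2", "G3"]
        assert (frag.interval.start, frag.interval.end) == (1_000, 3_500)

    def test_gene_straddling_border_is_dropped(self):
        genes = [gene(f"G{i}", i * 1000, i * 1000 + 500) for i in range(1, 6)]
        (locus,) = stitch_genes(genes, {g.name for g in genes})
        # border inside gene 4's body: G4 dropped, G1-3 fragment survives
        (frag,) = apply_domain_constraints(
            [locus], domains((0, 4_200), (4_200, 10_000))
        )
        assert frag.member_names == ["G1", "G2", "G3"]


class TestTfSiteExtension:
    GENES = [gene("Out", 0, 500), gene("A", 10_000, 11_000),
             gene("B", 12_000, 13_000), gene("C", 14_000, 15_000),
             gene("Next", 30_000, 31_000)]

    def locus(self):
        (l,) = stitch_genes(self.GENES, {"A", "B", "C"})
        return l

    def test_intergenic_element_incorporated(self):
        els = [element("up", 5_000, 5_200)]
        (out,) = extend_with_tf_sites(
            [self.locus()], els, self.GENES, domains((0, 50_000))
        )
        assert out.interval.start == 5_000
        assert [e.name for e in out.incorporated_sites] == ["up"]

    def test_element_beyond_neighbor_gene_not_incorporated(self):
        els = [element("far", 31_500, 31_700)]  # past gene Next
        (out,) = extend_with_tf_sites(
            [self.locus()], els, self.GENES, domains((0, 50_000))
        )
        assert out.interval.end == 15_000
        assert out.incorporated_sites == []

    def test_extension_retracts_at_border(self):
        # two upstream elements; a border lies between them, so the
        # extension keeps only the element on the locus side
        els = [element("far", 3_000, 3_200), element("near", 6_000, 6_200)]
        (out,) = extend_with_tf_sites(
            [self.locus()], els, self.GENES, domains((0, 5_000), (5_000, 50_000))
        )
        assert out.interval.start == 6_000
        assert [e.name for e in out.incorporated_sites] == ["near"]


class TestFinalize:
    def test_minimum_three_genes(self):
        two = stitch_genes([gene("A", 0, 100), gene("B", 200, 300)], {"A", "B"})
        three = stitch_genes(
            [gene("A", 0, 100), gene("B", 200, 300), gene("C", 400, 500)],
            {"A", "B", "C"},
        )
        assert finalize_loci(two) == []
        assert len(finalize_loci(three)) == 1


class TestPipelineProperties:
    def run_pipeline(self, genes, flags, elements, doms):
        loci = stitch_genes(genes, flags)
        loci = apply_domain_constraints(loci, doms)
        loci = extend_with_tf_sites(loci, elements, genes, doms)
        return finalize_loci(loci)

    def convert(self, raw_genes, raw_elements, raw_domains):
        genes = [gene(n, s, e, coding=c) for n, s, e, c in raw_genes]
        elements = [element(n, s, e) for n, s, e in raw_elements]
        doms = domains(*raw_domains)
        return genes, elements, doms

    def test_equivalence_with_bruteforce_reference(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            raw_genes, flags, raw_els, raw_doms = random_genome(rng)
            genes, elements, doms = self.convert(raw_genes, raw_els, raw_doms)
            got = self.run_pipeline(genes, flags, elements, doms)
            expected = reference_complex_loci(raw_genes, flags, raw_els, raw_doms)
            assert [
                {
                    "members": l.member_names,
                    "span": (l.interval.start, l.interval.end),
                    "sites": sorted(e.name for e in l.incorporated_sites),
                }
                for l in got
            ] == expected

    def test_no_output_locus_contains_a_border(self):
        rng = np.random.default_rng(321)
        for _ in range(100):
            raw_genes, flags, raw_els, raw_doms = random_genome(rng)
            genes, elements, doms = self.convert(raw_genes, raw_els, raw_doms)
            for locus in self.run_pipeline(genes, flags, elements, doms):
                assert doms.borders_inside(locus.interval) == []

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(555)
        for _ in range(50):
            raw_genes, flags, raw_els, raw_doms = random_genome(rng)
            genes, elements, doms = self.convert(raw_genes, raw_els, raw_doms)
            once = self.run_pipeline(genes, flags, elements, doms)
            again = finalize_loci(
                extend_with_tf_sites(
                    apply_domain_constraints(once, doms), elements, genes, doms
                )
            )
            assert [(l.member_names, l.interval) for l in again] == [
                (l.member_names, l.interval) for l in once
            ]

    def test_removing_a_border_never_loses_member_genes(self):
        # splitting can turn one long run into two surviving fragments, so
        # the locus count itself is not monotone; the genes covered by
        # surviving loci are: without the border the whole run survives
        rng = np.random.default_rng(777)
        for _ in range(100):
            raw_genes, flags, raw_els, raw_doms = random_genome(rng)
            if len(raw_doms) < 2:
                continue
            genes, elements, doms = self.convert(raw_genes, raw_els, raw_doms)
            before = self.run_pipeline(genes, flags, elements, doms)
            # merge the first two domains, removing one interior border
            merged = [(raw_doms[0][0], raw_doms[1][1])] + list(raw_doms[2:])
            _g, _e, doms2 = self.convert(raw_genes, raw_els, merged)
            after = self.run_pipeline(genes, flags, elements, doms2)
            genes_before = {g for l in before for g in l.member_names}
            genes_after = {g for l in after for g in l.member_names}
            assert genes_before <= genes_after

    def test_default_scenario_recovers_casein_locus(self, config, layout,
                                                    called_elements):
        genes, truth, doms, _seq = layout
        from locusarch.expression import differential_expression
        from locusarch.synthetic_data import simulate_counts

        counts, meta = simulate_counts(config, None, seed=1)
        stage = lambda s: meta.loc[meta["stage"] == s, "sample"].tolist()
        de = {
            "p6_vs_L1": differential_expression(counts, stage("p6"), stage("L1")),
            "p6_vs_L10": differential_expression(counts, stage("p6"), stage("L10")),
        }
        loci = identify_complex_loci(genes, de, called_elements, doms)
        assert [l.member_names for l in loci] == truth.loci
        members = loci[0].member_names
        assert {"Csn1s1", "Csn2", "Csn1s2a", "Csn1s2b"} <= set(members)
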