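"""Consequence calling: fixture regression, named examples, oracle properties."""

import numpy as np
import pytest

from conftest import random_exonic_variants
from helpers_oracle import oracle_category
from melpanel.consequence import (
    Category,
    CdsEdit,
    NoOverlapError,
    ReferenceMismatchError,
    VariantRecord,
    annotate_variant,
    combined_impact,
    protein_change,
    render_variant_string,
)
from melpanel.simulate import ToyGeneConfig, generate_toy_gene
from melpanel.transcript import GenomicPosition


def annotate_pos(model, pos, ref, alt):
    v = VariantRecord(model.symbol, GenomicPosition(model.chrom, pos), ref, alt)
    return annotate_variant(model, v)


def by_isoform(consequences):
    return {c.isoform: c for c in consequences}


class TestNamedExamples:
    """Worked examples with published expected strings."""

    def test_shared_base_missense_in_p16_silent_in_p14(self, cdkn2a):
        cons = by_isoform(annotate_pos(cdkn2a, 21971146, "A", "G"))
        p16, p14 = cons["p16"], cons["p14"]
        assert (p16.category, p16.hgvs_c, p16.hgvs_p) == (
            Category.MISSENSE, "c.212A>G", "p.N71S")
        assert (p14.category, p14.hgvs_c, p14.hgvs_p) == (
            Category.SILENT, "c.255A>G", "p.Q85Q")

    def test_canonical_donor_splicing_no_protein_call(self, cdkn2a):
        cons = annotate_pos(cdkn2a, 21994137, "G", "A")
        assert len(cons) == 1 and cons[0].isoform == "p14"
        assert cons[0].category is Category.SPLICING
        assert cons[0].hgvs_c == "c.193+1G>A" and cons[0].hgvs_p == ""

    def test_nonsense_rendered_in_x_style(self, cdkn2a):
        p16 = by_isoform(annotate_pos(cdkn2a, 21974748, "G", "T"))["p16"]
        assert p16.category is Category.TRUNCATING
        assert (p16.hgvs_c, p16.hgvs_p) == ("c.79G>T", "p.E27X")

    def test_nonsense_ter_style_option(self, cdkn2a):
        v = VariantRecord("CDKN2A", GenomicPosition("chr9", 21974748), "G", "T")
        p16 = by_isoform(annotate_variant(cdkn2a, v, nonsense_style="Ter"))["p16"]
        assert p16.hgvs_p == "p.E27Ter"

    def test_duplication_frameshift_in_two_frames(self, cdkn2a):
        cons = by_isoform(annotate_pos(cdkn2a, 21971164, "", "TGCT"))
        assert cons["p16"].hgvs_c == "c.191_194dupTGCT"
        assert cons["p16"].hgvs_p == "p.H66Afs*55"
        assert cons["p14"].hgvs_c == "c.234_237dupTGCT"
        assert cons["p14"].hgvs_p == "p.P80Cfs*82"

    def test_single_base_deletion_frameshifts_differ_by_frame(self, cdkn2a):
        cons = by_isoform(annotate_pos(cdkn2a, 21971157, "C", ""))
        assert cons["p16"].hgvs_p == "p.A68Rfs*78"
        assert cons["p14"].hgvs_p == "p.R82Afs*90"

    def test_frameshift_deletion_derived_by_retranslation(self, cdkn2a):
        """c.201delC re-derived through protein_change on a CDS edit."""
        p16 = cdkn2a.isoform("p16")
        got = protein_change(p16, CdsEdit(201, "C", ""), cdkn2a.reference)
        assert got == "p.A68Rfs*78"

    def test_in_frame_deletion_naming(self, cdkn2a):
        p16 = by_isoform(annotate_pos(cdkn2a, 21974775, "ACGGCC", ""))["p16"]
        assert p16.category is Category.INFRAME_DELETION
        assert (p16.hgvs_c, p16.hgvs_p) == ("c.52_57delACGGCC", "p.T18_A19del")

    def test_deletion_frameshift_immediate_stop_uses_x_style(self, cdkn2a):
        p16 = by_isoform(annotate_pos(cdkn2a, 21974695, "C", ""))["p16"]
        assert (p16.hgvs_c, p16.hgvs_p) == ("c.132delC", "p.Y44X")
        assert p16.category is Category.TRUNCATING

    def test_single_base_insertion_rendered_ins_not_dup(self, cdkn2a):
        p16 = by_isoform(annotate_pos(cdkn2a, 21970922, "", "G"))["p16"]
        assert (p16.hgvs_c, p16.hgvs_p) == ("c.436_437insG", "p.D146Gfs*19")

    def test_utr_and_intronic_variants(self, cdkn2a):
        five = by_isoform(annotate_pos(cdkn2a, 21974857, "G", "C"))["p16"]
        assert five.category is Category.FIVE_UTR and five.hgvs_c == "c.-31G>C"
        three = by_isoform(annotate_pos(cdkn2a, 21968197, "G", "A"))["p16"]
        assert three.category is Category.THREE_UTR and three.hgvs_c == "c.*31G>A"
        deep = by_isoform(annotate_pos(cdkn2a, 21968346, "A", "G"))["p16"]
        assert deep.category is Category.INTRONIC
        assert deep.hgvs_c == "c.458-105A>G"

    def test_extended_splice_window_needs_exonic_sibling(self, cdkn2a):
        """+5/+37/+49 are splicing because p12 reads them as coding."""
        for pos, p12_c in [(21974672, "c.155G>T"), (21974640, None),
                           (21974628, None)]:
            ref = "A" if pos == 21974628 else "G"
            alt = {21974672: "T", 21974640: "C", 21974628: "T"}[pos]
            cons = by_isoform(annotate_pos(cdkn2a, pos, ref, alt))
            assert cons["p16"].category is Category.SPLICING
            assert cons["p12"].category is Category.MISSENSE
        # same offsets without an exonic sibling stay intronic (p16 only
        # position): deep intron 2 has no other exon
        deep = by_isoform(annotate_pos(cdkn2a, 21970890, *_ref_alt(cdkn2a, 21970890)))
        assert deep["p16"].category in (Category.SPLICING, Category.INTRONIC)

    def test_cdk4_codon48_in_frame_deletion(self, models):
        cdk4 = models["CDK4"]
        c = annotate_pos(cdk4, 58145309, "AGG", "")[0]
        assert (c.hgvs_c, c.hgvs_p) == ("c.132_134delAGG", "p.G48del")
        assert c.category is Category.INFRAME_DELETION

    def test_mitf_e318k(self, models):
        c = annotate_pos(models["MITF"], 69789001, "G", "A")[0]
        assert (c.hgvs_c, c.hgvs_p) == ("c.952G>A", "p.E318K")

    def test_reference_mismatch_names_position(self, cdkn2a):
        with pytest.raises(ReferenceMismatchError, match="21974756"):
            annotate_pos(cdkn2a, 21974756, "T", "C")  # locus has coding G

    def test_no_overlap_error(self, cdkn2a):
        with pytest.raises(NoOverlapError):
            annotate_pos(cdkn2a, 21960000, "A", "C")


def _ref_alt(model, pos):
    from melpanel.transcript import reverse_complement

    ref = reverse_complement(model.reference.base(pos))
    alt = "A" if ref != "A" else "C"
    return ref, alt


class TestCombinedImpact:
    def test_priority_and_silent_suppression(self, cdkn2a):
        assert combined_impact(
            annotate_pos(cdkn2a, 21974672, "G", "T")
        ).label == "splicing/missense"
        assert combined_impact(
            annotate_pos(cdkn2a, 21971146, "A", "G")
        ).label == "missense"  # p14 silent call suppressed
        assert combined_impact(
            annotate_pos(cdkn2a, 21974857, "G", "C")
        ).label == "5′UTR"
        assert combined_impact(
            annotate_pos(cdkn2a, 21974776, "C", "T")
        ).label == "silent"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            combined_impact([])


class TestFixtureRegression:
    def test_all_unambiguous_rows_reproduce_printed_strings(self, cdkn2a, bundle):
        """Variant strings and impacts of the curated table, byte-exact."""
        n_checked = 0
        for _, row in bundle.table3.iterrows():
            if "excluded" in row["flags"]:
                continue
            v = VariantRecord(
                "CDKN2A", GenomicPosition("chr9", row["pos"]),
                row["ref"], row["alt"],
            )
            cons = annotate_variant(cdkn2a, v)
            assert render_variant_string(cons) == row["variant"]
            assert combined_impact(cons).label.lower() == row["impact"].lower()
            n_checked += 1
        assert n_checked == 31

    def test_excluded_rows_annotate_without_error(self, cdkn2a, bundle):
        """The two internally inconsistent rows still pass through cleanly."""
        rows = bundle.table3[bundle.table3["flags"].str.contains("excluded")]
        assert len(rows) == 2
        for _, row in rows.iterrows():
            v = VariantRecord(
                "CDKN2A", GenomicPosition("chr9", row["pos"]),
                row["ref"], row["alt"],
            )
            cons = annotate_variant(cdkn2a, v)
            assert cons  # annotation succeeds; strings intentionally untested


class TestOracleEquivalence:
    """Engine vs brute-force mutate-splice-translate oracle."""

    N_PER_GENE = 60

    @pytest.mark.parametrize("seed", range(10))
    def test_random_variants_match_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        cfg = ToyGeneConfig(
            seed=seed,
            dual_isoform=(seed % 2 == 0),
            strand="-" if seed % 3 == 0 else "+",
        )
        gene = generate_toy_gene(cfg)
        n = 0
        for iso in gene.isoforms:
            for v in random_exonic_variants(gene, iso, rng, self.N_PER_GENE):
                mine = by_isoform(annotate_variant(gene, v))[iso.name]
                assert mine.category == oracle_category(gene, v, iso), v
                n += 1
        assert n >= self.N_PER_GENE  # enough variants were generated

    def test_silent_iff_protein_unchanged_and_frameshift_iff_len(self, cdkn2a):
        """Spot-check the two biconditionals on the real locus."""
        rng = np.random.default_rng(7)
        p16 = cdkn2a.isoform("p16")
        for v in random_exonic_variants(cdkn2a, p16, rng, 120):
            c = by_isoform(annotate_variant(cdkn2a, v))["p16"]
            want = oracle_category(cdkn2a, v, p16)
            assert (c.category is Category.SILENT) == (want is Category.SILENT)
            if v.kind in ("del", "ins") and c.hgvs_p.startswith("p.") and "fs" in c.hgvs_p:
                assert (len(v.ref) + len(v.alt)) % 3 != 0
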