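"""Gene models and genomic<->CDS coordinate projection."""

import numpy as np
import pytest

from melpanel.transcript import (
    AlphabetError,
    CdsCoordinate,
    GeneModelError,
    GenomicPosition,
    OutOfTranscriptError,
    load_gene_model,
    project_cds_to_genomic,
    project_genomic_to_cds,
    translate_cds,
)

TOY_PLUS = {
    "symbol": "TOYP",
    "chrom": "chrT",
    "strand": "+",
    "isoforms": [
        {"name": "t1", "exons": [[101, 130], [161, 220]], "cds_start": 11,
         "cds_end": 70},
    ],
}


def project(iso, chrom, pos):
    return str(project_genomic_to_cds(iso, GenomicPosition(chrom, pos)))


class TestLoadGeneModel:
    def test_minimal_single_exon_plus_gene(self):
        m = load_gene_model(
            {
                "symbol": "ONE", "chrom": "chr1", "strand": "+",
                "isoforms": [
                    {"name": "a", "exons": [[11, 22]], "cds_start": 1,
                     "cds_end": 12}
                ],
            }
        )
        assert m.isoform("a").cds_length == 12

    def test_overlapping_exons_rejected_naming_isoform(self):
        bad = {
            "symbol": "BAD", "chrom": "chr1", "strand": "+",
            "isoforms": [
                {"name": "p16", "exons": [[1, 100], [90, 150]],
                 "cds_start": 1, "cds_end": 99}
            ],
        }
        with pytest.raises(GeneModelError, match="p16"):
            load_gene_model(bad)

    def test_unknown_strand_and_cds_outside_transcript(self):
        with pytest.raises(GeneModelError, match="strand"):
            load_gene_model(
                {"symbol": "X", "chrom": "c", "strand": "^", "isoforms": []}
            )
        with pytest.raises(GeneModelError, match="CDS"):
            load_gene_model(
                {
                    "symbol": "X", "chrom": "c", "strand": "+",
                    "isoforms": [
                        {"name": "a", "exons": [[1, 30]], "cds_start": 5,
                         "cds_end": 60}
                    ],
                }
            )

    def test_cds_frame_exception_flag(self):
        doc = {
            "symbol": "X", "chrom": "c", "strand": "+",
            "isoforms": [
                {"name": "a", "exons": [[1, 30]], "cds_start": 1, "cds_end": 20}
            ],
        }
        with pytest.raises(GeneModelError, match="multiple of 3"):
            load_gene_model(doc)
        doc["isoforms"][0]["frame_exception"] = True
        assert load_gene_model(doc).isoform("a").cds_length == 20

    def test_cdkn2a_has_four_isoforms_on_minus_strand(self, cdkn2a):
        assert cdkn2a.strand == "-"
        assert {i.name for i in cdkn2a.isoforms} == {"p16", "p14", "p12", "p16γ"}
        assert cdkn2a.isoform("p16g").name == "p16γ"  # ASCII alias


class TestProjection:
    def test_plus_strand_cds_boundaries(self):
        iso = load_gene_model(TOY_PLUS).isoform("t1")
        assert project(iso, "chrT", 111) == "1"  # CDS start
        assert project(iso, "chrT", 101) == "-10"
        assert project(iso, "chrT", 130) == "20"
        assert project(iso, "chrT", 161) == "21"  # across the intron
        assert project(iso, "chrT", 135) == "20+5"
        assert project(iso, "chrT", 156) == "21-5"
        assert project(iso, "chrT", 201) == "*1"
        assert project(iso, "chrT", 211) == "*11"

    @pytest.mark.parametrize(
        "iso_name,pos,expected",
        [
            ("p16", 21974756, "71"),
            ("p16", 21974672, "150+5"),
            ("p12", 21974672, "155"),
            ("p14", 21971146, "255"),
            ("p16", 21971146, "212"),
            ("p16", 21971057, "301"),
            ("p16", 21974857, "-31"),
            ("p16", 21968197, "*31"),
            ("p16", 21968346, "458-105"),
            ("p14", 21994170, "161"),
            ("p16γ", 21968732, "496"),
        ],
    )
    def test_published_anchor_pairs(self, cdkn2a, iso_name, pos, expected):
        assert project(cdkn2a.isoform(iso_name), "chr9", pos) == expected

    def test_all_curated_positions_project_to_printed_coordinates(
        self, cdkn2a, bundle
    ):
        """Every curated genomic position reproduces the c. string of its row."""
        import re

        for _, row in bundle.table3.iterrows():
            if "dup" in row["variant"]:
                # the anchor of a duplication is the last duplicated base
                c_str = re.search(r"_(\d+)dup", row["variant"]).group(1)
            else:
                m = re.search(r"c\.([-*0-9+]+?)(?=[ACGT_d])", row["variant"])
                c_str = m.group(1)
            iso = cdkn2a.isoform(row["variant"].split(":")[0].split(",")[0])
            got = str(
                project_genomic_to_cds(iso, GenomicPosition("chr9", row["pos"]))
            )
            assert got == c_str, (row["variant"], got)

    def test_inverse_projection_published_examples(self, cdkn2a):
        p16 = cdkn2a.isoform("p16")
        assert project_cds_to_genomic(p16, CdsCoordinate(71), "chr9").pos == 21974756
        assert project_cds_to_genomic(p16, CdsCoordinate(301), "chr9").pos == 21971057

    def test_round_trip_identity_all_exonic_positions(self, cdkn2a):
        for iso in cdkn2a.isoforms:
            for exon in iso.exons:
                for pos in range(exon.start, exon.end + 1):
                    c = project_genomic_to_cds(iso, GenomicPosition("chr9", pos))
                    assert c.offset == 0
                    back = project_cds_to_genomic(iso, c, "chr9")
                    assert back.pos == pos

    def test_minus_strand_monotonicity_within_exon(self, cdkn2a):
        p16 = cdkn2a.isoform("p16")
        exon2 = p16.exons[1]
        bases = [
            project_genomic_to_cds(p16, GenomicPosition("chr9", g)).base
            for g in range(exon2.start, exon2.end + 1)
        ]
        assert all(b1 > b2 for b1, b2 in zip(bases, bases[1:]))

    def test_p14_p16_frame_offset_is_43_on_anchor_pairs(self, cdkn2a):
        """Shared exon-2 positions differ by exactly 43 CDS bases (p14 - p16)."""
        p16, p14 = cdkn2a.isoform("p16"), cdkn2a.isoform("p14")
        pairs = [(212, 255), (249, 292), (301, 344), (340, 383),
                 (167, 210), (176, 219), (199, 242)]
        for c16, c14 in pairs:
            g = project_cds_to_genomic(p16, CdsCoordinate(c16), "chr9")
            got = project_genomic_to_cds(p14, g)
            assert got.base == c14 and c14 - c16 == 43

    def test_out_of_span_errors(self, cdkn2a):
        p16 = cdkn2a.isoform("p16")
        with pytest.raises(OutOfTranscriptError):
            project_genomic_to_cds(p16, GenomicPosition("chr9", 21994170))
        with pytest.raises(OutOfTranscriptError):
            project_cds_to_genomic(p16, CdsCoordinate(5000))


class TestTranslate:
    def test_standard_code_and_stop(self):
        assert translate_cds("ATGGCC") == "MA"
        assert translate_cds("TAA") == "*"
        assert translate_cds("ATGTAAGGG", to_stop=True) == "M"

    def test_p16_codon_24_is_arginine(self, cdkn2a):
        cds = cdkn2a.isoform("p16").cds_sequence(cdkn2a.reference)
        prot = translate_cds(cds, to_stop=True)
        assert prot[23] == "R" and len(prot) == 156

    def test_alphabet_error_reports_position(self):
        with pytest.raises(AlphabetError, match="position 4"):
            translate_cds("ATGN")


class TestCdsCoordinate:
    @pytest.mark.parametrize("text", ["71", "-31", "*31", "150+5", "458-105"])
    def test_parse_render_round_trip(self, text):
        assert str(CdsCoordinate.parse(text)) == text

    def test_invalid_base_zero(self):
        with pytest.raises(ValueError):
            CdsCoordinate(0)
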