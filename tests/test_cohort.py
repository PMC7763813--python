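"""Triage rules, panel masking, cohort summarization, surveillance plans."""

import itertools

import pandas as pd
import pytest

from melpanel.cohort import (
    MELANOMA,
    NGS_TEST,
    PANCREATIC,
    SANGER_TEST,
    IneligibleError,
    NotReferableError,
    ObservedVariant,
    PatientRecord,
    Relative,
    StageError,
    apply_panel,
    destabilization_tally,
    hotspots,
    round_pct,
    summarize_cohort,
    surveillance_plan,
    triage,
)


def patient(n_mel, n_rel, degrees=None, **kw):
    degrees = degrees or [1] * n_rel
    return PatientRecord(
        id="t1",
        sex="F",
        age_first_melanoma=45.0,
        n_melanomas=n_mel,
        relatives=[Relative(d, MELANOMA) for d in degrees[:n_rel]],
        **kw,
    )


class TestTriage:
    @pytest.mark.parametrize(
        "n_mel,n_rel,want",
        [
            (3, 0, "high"),   # three melanomas alone suffice
            (5, 2, "high"),
            (2, 1, "high"),   # two melanomas + one affected relative
            (1, 2, "high"),   # one melanoma + two affected relatives
            (2, 0, "low"),
            (1, 1, "low"),
        ],
    )
    def test_rule_branches(self, n_mel, n_rel, want):
        assert triage(patient(n_mel, n_rel)).label == want

    def test_second_degree_relatives_count(self):
        assert triage(patient(2, 1, degrees=[2])).label == "high"

    def test_non_melanoma_relatives_do_not_count(self):
        p = patient(2, 0)
        p.relatives.append(Relative(1, PANCREATIC))
        assert triage(p).label == "low"

    def test_ineligible_and_not_referable(self):
        with pytest.raises(IneligibleError):
            triage(patient(0, 0))
        with pytest.raises(NotReferableError):
            triage(patient(1, 0))

    def test_rules_total_and_deterministic(self):
        """Every eligible (n_mel, n_rel) combination maps to exactly one tier."""
        for n_mel, n_rel in itertools.product(range(1, 7), range(0, 5)):
            if n_mel == 1 and n_rel == 0:
                continue
            a = triage(patient(n_mel, n_rel)).label
            b = triage(patient(n_mel, n_rel)).label
            assert a == b and a in {"low", "high"}


class TestApplyPanel:
    def test_mitf_masked_by_sanger_visible_on_ngs(self):
        p = patient(3, 0, test_year=2018)
        p.observed_variants = [ObservedVariant("MITF", "P", 318, "MITF:c.952G>A")]
        assert apply_panel(p, SANGER_TEST)[0] is False
        assert apply_panel(p, NGS_TEST)[0] is True

    def test_cdk4_codon_restriction(self):
        p = patient(3, 0)
        p.observed_variants = [ObservedVariant("CDK4", "VUS", 48, "CDK4:G48del")]
        assert apply_panel(p, SANGER_TEST)[0] is False  # codon 48 masked
        assert apply_panel(p, NGS_TEST)[0] is True
        p.observed_variants = [ObservedVariant("CDK4", "P", 24, "CDK4:R24H")]
        assert apply_panel(p, SANGER_TEST)[0] is True

    def test_benign_side_never_positive(self):
        p = patient(3, 0)
        p.observed_variants = [ObservedVariant("CDKN2A", "LB", 24, "x")]
        assert apply_panel(p, SANGER_TEST)[0] is False
        assert apply_panel(p, NGS_TEST)[0] is False

    def test_era_assignment(self):
        early, late = patient(3, 0, test_year=2017), patient(3, 0, test_year=2018)
        apply_panel(early), apply_panel(late)
        assert early.panel == "Sanger-Test" and late.panel == "NGS-Test"

    def test_panel_monotonicity_ngs_superset(self, reference_cohort):
        """NGS positivity >= Sanger positivity on the same patients."""
        for p in reference_cohort[:300]:
            s = apply_panel(p, SANGER_TEST)[0]
            n = apply_panel(p, NGS_TEST)[0]
            assert n >= s
        # restore era panels mutated by this test
        for p in reference_cohort[:300]:
            apply_panel(p)

    def test_unknown_gene_raises(self):
        from melpanel.cohort import PanelScopeError

        p = patient(3, 0)
        p.observed_variants = [ObservedVariant("BRCA2", "P", 1, "x")]
        with pytest.raises(PanelScopeError):
            apply_panel(p, NGS_TEST)


class TestSummarize:
    def test_reference_cohort_reproduces_published_counts(self, reference_cohort):
        s = summarize_cohort(reference_cohort)
        assert s.n_patients == 888
        assert s.category_counts == {"low": 538, "high": 350}
        assert s.strata[("low", "Sanger-Test")] == {"tested": 418, "positive": 13}
        assert s.strata[("low", "NGS-Test")] == {"tested": 120, "positive": 23}
        assert s.strata[("high", "Sanger-Test")] == {"tested": 268, "positive": 67}
        assert s.strata[("high", "NGS-Test")] == {"tested": 82, "positive": 25}
        assert s.n_positive == 128
        assert s.gene_positive == {
            "CDKN2A": 98, "MITF": 10, "CDK4": 9, "BAP1": 9, "POT1": 2,
        }

    def test_conservation_invariants(self, reference_cohort):
        s = summarize_cohort(reference_cohort)
        assert sum(v["tested"] for v in s.strata.values()) == s.n_patients
        assert sum(s.gene_positive.values()) == s.n_positive
        # positive implies tested within each stratum
        assert all(v["positive"] <= v["tested"] for v in s.strata.values())

    def test_carrier_counts_match_fixture(self, reference_cohort, bundle):
        """98 CDKN2A patients carry 100 observations; per-variant counts hold."""
        s = summarize_cohort(reference_cohort)
        got = dict(zip(s.variant_carriers["variant"], s.variant_carriers["carriers"]))
        for _, row in bundle.table3.iterrows():
            assert got.get(row["variant"], 0) == row["carriers"]

    def test_empty_cohort_all_zero(self):
        s = summarize_cohort([])
        assert s.n_patients == 0 and s.n_positive == 0 and not s.strata

    def test_untriaged_patient_rejected(self):
        with pytest.raises(StageError):
            summarize_cohort([patient(3, 0)])

    def test_degenerate_all_positive_high_cohort(self):
        pats = []
        for i in range(10):
            p = patient(3, 0, test_year=2018)
            p.id = f"h{i}"
            p.observed_variants = [ObservedVariant("CDKN2A", "P", 24, "v")]
            triage(p)
            apply_panel(p)
            pats.append(p)
        s = summarize_cohort(pats)
        assert s.n_positive == 10
        assert round_pct(s.category_counts["high"], s.n_patients) == 100


class TestRounding:
    @pytest.mark.parametrize(
        "n,d,want",
        [(92, 128, 72), (13, 418, 3), (23, 120, 19), (67, 268, 25),
         (25, 82, 30), (128, 888, 14), (1, 2, 50), (1, 200, 1), (0, 5, 0)],
    )
    def test_round_half_away_from_zero(self, n, d, want):
        assert round_pct(n, d) == want

    def test_exact_halves_round_away(self):
        assert round_pct(1, 8) == 13  # 12.5 -> 13
        assert round_pct(25, 1000) == 3  # 2.5 -> 3


class TestDestabilization:
    def test_fixture_tally_17_of_20(self, bundle):
        assert destabilization_tally(bundle.table3) == (17, 20)

    def test_empty_and_toy_tables(self):
        empty = pd.DataFrame(columns=["impact", "mm_p16"])
        assert destabilization_tally(empty) == (0, 0)
        toy = pd.DataFrame(
            [
                {"impact": "missense", "mm_p16": "Ss", "mm_p14": "N"},
                {"impact": "missense", "mm_p16": "Hd", "mm_p14": "-"},
                {"impact": "truncating", "mm_p16": "", "mm_p14": ""},
            ]
        )
        assert destabilization_tally(toy) == (1, 2)

    def test_unknown_label_rejected(self):
        bad = pd.DataFrame([{"impact": "missense", "mm_p16": "XX"}])
        with pytest.raises(ValueError, match="XX"):
            destabilization_tally(bad)


class TestHotspots:
    def test_three_hotspots_above_ten_carriers(self, bundle):
        hs = hotspots(bundle.table3, 10)
        assert len(hs) == 3
        assert list(hs["carriers"]) == [17, 16, 11]
        joined = " ".join(hs["variant"])
        for marker in ("p.R24P", "p.G101W", "p.N71S"):
            assert marker in joined

    def test_threshold_edge_cases(self, bundle):
        assert len(hotspots(bundle.table3, 0)) == 33
        assert hotspots(bundle.table3, 100).empty
        with pytest.raises(ValueError):
            hotspots(bundle.table3, -1)


class TestSurveillance:
    def _positive(self, gene, cls="P", codon=None, relatives=()):
        p = patient(3, 0, test_year=2018)
        p.relatives.extend(relatives)
        p.observed_variants = [ObservedVariant(gene, cls, codon, f"{gene}:v")]
        triage(p)
        apply_panel(p)
        return p

    def test_cdkn2a_with_pancreatic_history_gets_imaging(self):
        p = self._positive("CDKN2A", relatives=[Relative(1, PANCREATIC)])
        plan = surveillance_plan(p)
        codes = {a.code for a in plan}
        assert "pancreas-imaging" in codes and "gastro-eval" in codes
        skin = next(a for a in plan if a.code == "skin-surveillance")
        assert skin.interval_months == (3, 3)

    def test_cdkn2a_without_pancreatic_history_no_imaging(self):
        codes = {a.code for a in surveillance_plan(self._positive("CDKN2A"))}
        assert "pancreas-imaging" not in codes

    def test_mitf_includes_urinary_cytology(self):
        plan = surveillance_plan(self._positive("MITF"))
        cyto = next(a for a in plan if a.code == "urinary-cytology")
        assert cyto.interval_months == (6, 6)

    def test_bap1_age_gated_actions(self):
        plan = {a.code: a for a in surveillance_plan(self._positive("BAP1", "LP"))}
        assert plan["skin-surveillance"].start_age == 18
        assert plan["eye-exam"].start_age == 16

    def test_pot1_li_fraumeni_flag(self):
        codes = {a.code for a in surveillance_plan(self._positive("POT1", "VUS-3B"))}
        assert "li-fraumeni-protocol" in codes

    def test_vus_only_schedule(self):
        plan = surveillance_plan(self._positive("BAP1", "VUS"))
        codes = {a.code for a in plan}
        assert "vus-review" in codes
        skin = next(a for a in plan if a.code == "skin-surveillance")
        assert skin.interval_months == (6, 6)

    def test_negative_schedule(self):
        p = patient(3, 0)
        triage(p)
        apply_panel(p)
        plan = surveillance_plan(p)
        skin = next(a for a in plan if a.code == "skin-surveillance")
        assert skin.interval_months == (8, 10)
        assert any(a.code == "re-counselling" for a in plan)

    def test_requires_panel_stage(self):
        with pytest.raises(StageError):
            surveillance_plan(patient(3, 0))
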