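"""Clinical cohort logic: triage, test panels, positivity and surveillance.

Patients referred for melanoma genetic counselling (multiple primary
melanomas, MPM, and/or familial melanoma, FM) are triaged into two clinical
categories from the personal melanoma count and the number of first/second-
degree relatives with melanoma:

* **high significance** — at least three melanomas; or two melanomas plus at
  least one affected relative; or one melanoma plus at least two affected
  relatives;
* **low significance** — exactly two melanomas with no affected relative; or
  one melanoma with exactly one affected relative.

Two historical test panels are modelled: the *Sanger-Test* (full CDKN2A
coding region plus CDK4 codon 24 only) used through 2017, and the five-gene
*NGS-Test* (CDKN2A, CDK4, BAP1, MITF, POT1) from 2018.  A patient is
*positive* when at least one panel-visible variant is classified P, LP,
VUS-3B or VUS.  Gene-specific surveillance plans follow the published
management flow (3-month skin checks and conditional pancreatic imaging for
CDKN2A carriers, urinary cytology for MITF, ophthalmologic surveillance for
BAP1, Li-Fraumeni-style follow-up for POT1, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acmg import is_reportable

__all__ = [
    "Relative",
    "ObservedVariant",
    "PatientRecord",
    "ClinicalCategory",
    "PanelDefinition",
    "SANGER_TEST",
    "NGS_TEST",
    "PlanAction",
    "CohortSummary",
    "triage",
    "assign_panel",
    "apply_panel",
    "summarize_cohort",
    "destabilization_tally",
    "hotspots",
    "surveillance_plan",
    "round_pct",
    "IneligibleError",
    "NotReferableError",
    "PanelScopeError",
    "StageError",
    "IncompleteRecordError",
]

log = logging.getLogger(__name__)

MELANOMA = "melanoma"
PANCREATIC = "pancreatic cancer"

#: precedence for attributing a multi-gene positive patient to one gene
GENE_PRECEDENCE = ["CDKN2A", "CDK4", "BAP1", "MITF", "POT1"]

DESTABILIZING_LABELS = {"Hd", "D", "Sd"}
MODELLING_LABELS = DESTABILIZING_LABELS | {"Ss", "N", "-", "n.a.", ""}


class IneligibleError(ValueError):
    """Patient does not meet the referral criteria at all (no melanoma)."""


class NotReferableError(ValueError):
    """Single melanoma without an affected relative: not MPM, not FM."""


class PanelScopeError(ValueError):
    """An observed variant names a gene outside every panel."""


class StageError(RuntimeError):
    """Pipeline stages run out of order (e.g. summary before triage)."""


class IncompleteRecordError(ValueError):
    """A positive result lacks the gene attribution a plan needs."""


@dataclass(frozen=True)
class Relative:
    degree: int  # 1 or 2
    cancer: str

    def __post_init__(self):
        if self.degree not in (1, 2):
            raise ValueError(f"relative degree must be 1 or 2, got {self.degree}")


@dataclass(frozen=True)
class ObservedVariant:
    gene: str
    class_label: str  # one of the seven ACMG classes
    codon: int | None = None  # protein position, when known
    variant_id: str = ""


@dataclass
class PatientRecord:
    id: str
    sex: str
    age_first_melanoma: float
    n_melanomas: int
    relatives: list[Relative] = field(default_factory=list)
    other_cancers: list[str] = field(default_factory=list)
    test_year: int = 2010
    observed_variants: list[ObservedVariant] = field(default_factory=list)
    panel_override: str | None = None
    # pipeline outputs
    category: str | None = None
    panel: str | None = None
    positive: bool | None = None
    visible_variants: list[ObservedVariant] = field(default_factory=list)

    @property
    def n_affected_relatives(self) -> int:
        return sum(1 for r in self.relatives if r.cancer == MELANOMA)

    @property
    def has_pancreatic_family_history(self) -> bool:
        return any(r.cancer == PANCREATIC for r in self.relatives)


@dataclass(frozen=True)
class ClinicalCategory:
    label: str  # "low" | "high"

    def __post_init__(self):
        if self.label not in ("low", "high"):
            raise ValueError(f"unknown clinical category {self.label!r}")


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    #: gene -> set of allowed protein positions, or None for the whole gene
    scope: dict

    def covers(self, ov: ObservedVariant) -> bool:
        if ov.gene not in set(self.scope) | set(GENE_PRECEDENCE):
            raise PanelScopeError(
                f"gene {ov.gene!r} unknown to panel {self.name}"
            )
        if ov.gene not in self.scope:
            return False
        restriction = self.scope[ov.gene]
        if restriction is None:
            return True
        return ov.codon is not None and ov.codon in restriction


SANGER_TEST = PanelDefinition("Sanger-Test", {"CDKN2A": None, "CDK4": {24}})
NGS_TEST = PanelDefinition(
    "NGS-Test", {g: None for g in ("CDKN2A", "CDK4", "BAP1", "MITF", "POT1")}
)
PANELS = {p.name: p for p in (SANGER_TEST, NGS_TEST)}


def triage(p: PatientRecord) -> ClinicalCategory:
    """Assign the two-tier clinical category from melanoma and family counts.

    The five rule branches are mutually exclusive and exhaustive over
    eligible patients (n_melanomas >= 1 and MPM and/or FM referral criteria).
    """
    if p.n_melanomas < 1:
        raise IneligibleError(f"{p.id}: no melanoma recorded")
    k = p.n_affected_relatives
    if p.n_melanomas >= 3:
        label = "high"
    elif p.n_melanomas == 2:
        label = "high" if k >= 1 else "low"
    else:  # exactly 1 melanoma
        if k >= 2:
            label = "high"
        elif k == 1:
            label = "low"
        else:
            raise NotReferableError(
                f"{p.id}: one melanoma and no affected relative"
            )
    p.category = label
    return ClinicalCategory(label)


def assign_panel(p: PatientRecord) -> PanelDefinition:
    """Test assignment by era: through 2017 Sanger-Test, from 2018 NGS-Test."""
    if p.panel_override:
        return PANELS[p.panel_override]
    return SANGER_TEST if p.test_year <= 2017 else NGS_TEST


def apply_panel(
    p: PatientRecord, panel: PanelDefinition | None = None
) -> tuple[bool, list[ObservedVariant]]:
    """Mask variants outside the panel scope and decide positivity.

    Positive iff at least one visible variant has a reportable class
    (P, LP, VUS-3B or VUS).  Masked variants are logged.
    """
    panel = panel or assign_panel(p)
    visible, masked = [], []
    for ov in p.observed_variants:
        (visible if panel.covers(ov) else masked).append(ov)
    for ov in masked:
        log.debug("%s: %s masked by %s", p.id, ov.variant_id or ov.gene, panel.name)
    positive = any(is_reportable(ov.class_label) for ov in visible)
    p.panel = panel.name
    p.positive = positive
    p.visible_variants = visible
    return positive, visible


def round_pct(numerator: float, denominator: float) -> int:
    """Percentage rounded half away from zero, as printed in reports."""
    if denominator == 0:
        return 0
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def attribute_gene(visible: list[ObservedVariant]) -> str | None:
    """Single causal gene for spectrum accounting (fixed precedence)."""
    genes = {ov.gene for ov in visible if is_reportable(ov.class_label)}
    if not genes:
        return None
    if len(genes) > 1:
        log.warning("multi-gene positive patient attributed by precedence: %s",
                    sorted(genes))
    for g in GENE_PRECEDENCE:
        if g in genes:
            return g
    return sorted(genes)[0]


@dataclass
class CohortSummary:
    n_patients: int
    category_counts: dict
    sex_counts: dict            # category -> {"M": n, "F": n}
    onset_age: dict             # category -> (mean, sd)
    other_cancer_counts: dict   # category -> n
    strata: dict                # (category, panel) -> {"tested": n, "positive": k}
    gene_positive: dict         # gene -> positive patients
    gene_class_counts: dict     # gene -> {class -> patients}
    variant_carriers: pd.DataFrame  # variant_id x carriers (visible variants)

    @property
    def n_positive(self) -> int:
        return sum(s["positive"] for s in self.strata.values())

    def positivity_pct(self, category: str, panel: str) -> int:
        s = self.strata[(category, panel)]
        return round_pct(s["positive"], s["tested"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cat, panel), s in sorted(self.strata.items()):
            rows.append(
                {
                    "category": cat,
                    "panel": panel,
                    "tested": s["tested"],
                    "positive": s["positive"],
                    "positivity_pct": round_pct(s["positive"], s["tested"]),
                }
            )
        return pd.DataFrame(rows)


def summarize_cohort(patients: list[PatientRecord]) -> CohortSummary:
    """Stratified counts, per-gene spectrum and carrier table for a cohort.

    Every patient must already be triaged and panel-applied.  Conservation
    invariants hold by construction: stratum tested counts sum to the cohort
    size and per-gene positives sum to the total positives (one causal gene
    per positive patient, fixed precedence for the rare multi-gene carrier).
    """
    for p in patients:
        if p.category is None or p.positive is None:
            raise StageError(f"{p.id}: triage/panel stage missing before summary")

    categories = ("low", "high")
    category_counts = {c: 0 for c in categories}
    sex_counts = {c: {"M": 0, "F": 0} for c in categories}
    ages: dict[str, list[float]] = {c: [] for c in categories}
    other = {c: 0 for c in categories}
    strata: dict = {}
    gene_positive: dict[str, int] = {}
    gene_class: dict[str, dict[str, int]] = {}
    carrier_counts: dict[str, int] = {}

    for p in patients:
        c = p.category
        category_counts[c] += 1
        sex_counts[c][p.sex] += 1
        ages[c].append(p.age_first_melanoma)
        other[c] += bool(p.other_cancers)
        key = (c, p.panel)
        s = strata.setdefault(key, {"tested": 0, "positive": 0})
        s["tested"] += 1
        if p.positive:
            s["positive"] += 1
            gene = attribute_gene(p.visible_variants)
            gene_positive[gene] = gene_positive.get(gene, 0) + 1
            for ov in p.visible_variants:
                if is_reportable(ov.class_label):
                    gc = gene_class.setdefault(ov.gene, {})
                    gc[ov.class_label] = gc.get(ov.class_label, 0) + 1
                    if ov.variant_id:
                        key = (ov.gene, ov.variant_id)
                        carrier_counts[key] = carrier_counts.get(key, 0) + 1

    onset = {
        c: (float(np.mean(a)), float(np.std(a, ddof=1)) if len(a) > 1 else 0.0)
        if a
        else (float("nan"), float("nan"))
        for c, a in ages.items()
    }
    carriers = (
        pd.DataFrame(
            [
                {"gene": g, "variant": vid, "carriers": n}
                for (g, vid), n in sorted(
                    carrier_counts.items(), key=lambda kv: (-kv[1], kv[0])
                )
            ]
        )
        if carrier_counts
        else pd.DataFrame(columns=["gene", "variant", "carriers"])
    )
    return CohortSummary(
        n_patients=len(patients),
        category_counts=category_counts,
        sex_counts=sex_counts,
        onset_age=onset,
        other_cancer_counts=other,
        strata=strata,
        gene_positive=gene_positive,
        gene_class_counts=gene_class,
        variant_carriers=carriers,
    )


def destabilization_tally(variant_table: pd.DataFrame) -> tuple[int, int]:
    """(n_destabilizing, n_missense) under the {Hd, D, Sd} membership rule.

    A variant counts as missense when its coding impact includes "missense"
    (case-insensitive); it counts as destabilizing when the protein-stability
    modelling label of at least one isoform is highly destabilizing (Hd),
    destabilizing (D) or slightly destabilizing (Sd).
    """
    if variant_table.empty:
        return (0, 0)
    mm_cols = [c for c in variant_table.columns if c.startswith("mm_")]
    n_missense = 0
    n_destab = 0
    for _, row in variant_table.iterrows():
        labels = {str(row[c]) if pd.notna(row[c]) else "" for c in mm_cols}
        unknown = labels - MODELLING_LABELS
        if unknown:
            raise ValueError(f"unknown modelling label(s): {sorted(unknown)}")
        if "missense" not in str(row["impact"]).lower():
            continue
        n_missense += 1
        if labels & DESTABILIZING_LABELS:
            n_destab += 1
    return (n_destab, n_missense)


def hotspots(variant_table: pd.DataFrame, min_carriers: int) -> pd.DataFrame:
    """Variants carried by strictly more than ``min_carriers`` patients."""
    if min_carriers < 0:
        raise ValueError(f"negative carrier threshold: {min_carriers}")
    col = "carriers"
    out = variant_table[variant_table[col] > min_carriers]
    return out.sort_values(col, ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# surveillance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanAction:
    code: str
    description: str
    interval_months: tuple[int, int] | None = None
    start_age: int | None = None


def _skin(months_lo: int, months_hi: int | None = None) -> PlanAction:
    hi = months_hi or months_lo
    return PlanAction(
        "skin-surveillance",
        f"clinical and instrumental skin follow-up every "
        f"{months_lo if hi == months_lo else f'{months_lo}–{hi}'} months",
        (months_lo, hi),
    )


def surveillance_plan(p: PatientRecord) -> list[PlanAction]:
    """Gene-specific follow-up schedule from the final test result.

    Requires :func:`apply_panel` to have run.  Positive here means a P, LP or
    VUS-3B variant; a patient whose only reportable finding is a plain VUS
    follows the VUS re-review schedule.
    """
    if p.positive is None:
        raise StageError(f"{p.id}: panel stage missing before surveillance")
    strong = [
        ov for ov in p.visible_variants if ov.class_label in {"P", "LP", "VUS-3B"}
    ]
    vus_only = not strong and any(
        ov.class_label == "VUS" for ov in p.visible_variants
    )

    if strong:
        gene = attribute_gene(strong)
        if gene is None:
            raise IncompleteRecordError(f"{p.id}: positive without gene")
        if gene == "CDKN2A":
            plan = [_skin(3)]
            if p.has_pancreatic_family_history:
                plan += [
                    PlanAction(
                        "gastro-eval",
                        "gastroenterological evaluation (familial pancreatic cancer)",
                    ),
                    PlanAction(
                        "pancreas-imaging",
                        "pancreas MRI and/or endoscopic ultrasound",
                    ),
                ]
            plan.append(
                PlanAction("family-counselling", "familial surveillance via genetic counselling")
            )
            return plan
        if gene == "CDK4":
            return [_skin(3)]
        if gene == "BAP1":
            return [
                PlanAction(
                    "skin-surveillance",
                    "biannual clinical and instrumental skin check-ups",
                    (6, 6),
                    start_age=18,
                ),
                PlanAction(
                    "eye-exam",
                    "annual ophthalmologic examination (uveal melanoma surveillance)",
                    (12, 12),
                    start_age=16,
                ),
                PlanAction(
                    "visceral-imaging",
                    "periodic renal/abdomen/chest imaging (mesothelioma and "
                    "renal-cell carcinoma surveillance)",
                ),
            ]
        if gene == "MITF":
            return [
                _skin(6),
                PlanAction(
                    "abdomen-ultrasound", "abdominal ultrasound evaluation", (6, 6)
                ),
                PlanAction(
                    "urinary-cytology", "urinary cytology every 6 months", (6, 6)
                ),
            ]
        if gene == "POT1":
            return [
                PlanAction(
                    "li-fraumeni-protocol",
                    "follow-up comparable to Li-Fraumeni syndrome surveillance",
                )
            ]
        raise IncompleteRecordError(f"{p.id}: unknown positive gene {gene!r}")

    if vus_only:
        return [
            _skin(6),
            PlanAction(
                "vus-review", "re-interpretation of the VUS at least every 6 months",
                (6, 6),
            ),
        ]

    return [
        _skin(8, 10),
        PlanAction(
            "re-counselling",
            "new genetic counselling after about 12 months for overall "
            "reassessment",
            (12, 12),
        ),
    ]
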