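"""Packaged fixtures: panel gene models, curated variant table, cohort counts.

The packaged CDKN2A/CDK4/MITF/BAP1/POT1 loci are synthetic anchor-consistent
reconstructions (see ``data/README.md``): transcript structure and every
curated variant anchor behave like the real hg19 locus, but intervening
sequence is designed, not downloaded.  The curated variant table transcribes
the published 33-variant CDKN2A spectrum (carrier counts, ACMG classes and
per-isoform protein-stability modelling labels); cohort fixtures carry the
published stratified tested/positive counts.

``build_reference_cohort`` materializes a deterministic patient-level cohort
that realizes those counts exactly, so the cohort summarizer can be checked
against the published percentages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd
from Bio import SeqIO

from .acmg import SEVEN_CLASSES
from .cohort import ObservedVariant, PatientRecord, Relative
from .transcript import GeneModel, LocusSequence, load_gene_model

__all__ = [
    "FixtureBundle",
    "IntegrityError",
    "load_fixtures",
    "load_panel_models",
    "build_reference_cohort",
]

PANEL_GENES = ["CDKN2A", "CDK4", "MITF", "BAP1", "POT1"]


class IntegrityError(RuntimeError):
    """A packaged data file is missing or does not match its checksum."""


@dataclass
class FixtureBundle:
    table3: pd.DataFrame       # curated CDKN2A variant table (33 rows)
    table2: pd.DataFrame       # cohort description counts
    strata: pd.DataFrame       # tested/positive per category x panel
    gene_counts: pd.DataFrame  # positive patients per gene
    primers: pd.DataFrame      # PCR primer sequences (data only)


def _data_dir():
    return files("melpanel") / "data"


def _read_bytes(name: str) -> bytes:
    res = _data_dir() / name
    try:
        return res.read_bytes()
    except FileNotFoundError as exc:
        raise IntegrityError(f"packaged fixture {name!r} is missing") from exc


def verify_checksums() -> None:
    sums = json.loads(_read_bytes("checksums.json"))
    for name, want in sums.items():
        got = hashlib.sha256(_read_bytes(name)).hexdigest()
        if got != want:
            raise IntegrityError(
                f"packaged fixture {name!r} fails its checksum "
                f"(expected {want[:12]}…, got {got[:12]}…)"
            )


def _read_tsv(name: str) -> pd.DataFrame:
    import io

    return pd.read_csv(io.BytesIO(_read_bytes(name)), sep="\t", dtype=str)


def load_fixtures(verify: bool = True) -> FixtureBundle:
    """Load and validate the packaged fixture bundle (checksummed)."""
    if verify:
        verify_checksums()
    table3 = _read_tsv("table3_variants.tsv")
    table3["pos"] = table3["pos"].astype(int)
    table3["carriers"] = table3["carriers"].astype(int)
    table3 = table3.fillna({"ref": "", "alt": "", "flags": ""})
    table3[["ref", "alt", "flags"]] = table3[["ref", "alt", "flags"]].fillna("")
    strata = _read_tsv("strata_counts.tsv")
    strata[["tested", "positive"]] = strata[["tested", "positive"]].astype(int)
    gene_counts = _read_tsv("gene_positive_counts.tsv")
    gene_counts["positive_patients"] = gene_counts["positive_patients"].astype(int)
    table2 = _read_tsv("table2_cohort.tsv")
    table2[["low", "high"]] = table2[["low", "high"]].astype(int)
    primers = _read_tsv("primers.tsv")

    if len(table3) != 33:
        raise IntegrityError(f"variant table has {len(table3)} rows, expected 33")
    if len(strata) != 4 or set(strata["category"]) != {"low", "high"}:
        raise IntegrityError("strata fixture malformed")
    bad = set(table3["acmg_class"]) - set(SEVEN_CLASSES)
    if bad:
        raise IntegrityError(f"unknown ACMG classes in variant table: {bad}")
    return FixtureBundle(
        table3=table3,
        table2=table2,
        strata=strata,
        gene_counts=gene_counts,
        primers=primers,
    )


def load_panel_models(verify: bool = True) -> dict[str, GeneModel]:
    """Gene models for the five panel genes, with locus sequences attached."""
    if verify:
        verify_checksums()
    import io

    loci = {}
    fasta = io.StringIO(_read_bytes("panel_loci.fasta").decode())
    for rec in SeqIO.parse(fasta, "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        loci[rec.id] = LocusSequence(
            str(rec.seq), int(fields["offset"]), fields.get("chrom", "")
        )
    models = {}
    for symbol in PANEL_GENES:
        doc = (_data_dir() / f"{symbol.lower()}_model.yaml").read_text()
        models[symbol] = load_gene_model(doc, locus=loci[symbol])
    return models


# ---------------------------------------------------------------------------
# deterministic reference cohort
# ---------------------------------------------------------------------------

#: protein position restrictions used when materializing panel-era positives
_CDK4_SANGER_VARIANTS = [("CDK4:c.71G>A", "P", 24), ("CDK4:c.71G>T", "P", 24)]
_CDK4_NGS_EXTRA = ("CDK4:c.132_134delAGG", "VUS", 48)


def _variant_codon(hgvs: str) -> int | None:
    """Approximate protein position of the first CDKN2A (p16) coding base."""
    import re

    m = re.search(r"c\.(\d+)", hgvs)
    return (int(m.group(1)) - 1) // 3 + 1 if m else None


def build_reference_cohort(seed: int = 0) -> list[PatientRecord]:
    """A deterministic 888-patient cohort realizing the fixture counts.

    Each stratum (clinical category x test era) gets exactly its recorded
    number of tested and positive patients; positives carry variants such
    that per-gene positive counts and the CDKN2A per-variant carrier counts
    are realized exactly.  The CDKN2A carrier counts sum to two more than the
    number of CDKN2A-positive patients, so two patients carry two variants
    each.  Ages and sexes are drawn to match the published marginals; the
    seed only affects those nuisance draws, never any count.
    """
    rng = np.random.default_rng(seed)
    fx = load_fixtures()

    # expand the variant table into 100 carrier observations
    obs_queue: list[ObservedVariant] = []
    for _, row in fx.table3.iterrows():
        ov = ObservedVariant(
            gene="CDKN2A",
            class_label=row["acmg_class"],
            codon=_variant_codon(row["variant"]),
            variant_id=row["variant"],
        )
        obs_queue.extend([ov] * row["carriers"])
    n_carriers = len(obs_queue)  # 100 observations for 98 patients

    # per-era gene queues (Sanger-era positives must be Sanger-visible)
    sanger_genes = ["CDKN2A"] * 72 + ["CDK4"] * 8
    ngs_genes = (
        ["CDKN2A"] * 26 + ["CDK4"] + ["MITF"] * 10 + ["BAP1"] * 9 + ["POT1"] * 2
    )

    strata = [
        (r["category"], r["panel"], r["tested"], r["positive"])
        for _, r in fx.strata.iterrows()
    ]
    sex_targets = {"low": 254, "high": 180}  # males among referred
    other_cancer_targets = {"low": 50, "high": 48}
    cat_sizes = {"low": 538, "high": 350}

    patients: list[PatientRecord] = []
    obs_i = 0
    cdkn2a_patients: list[PatientRecord] = []
    mitf_i = 0
    cdk4_sanger_i = 0
    per_cat_index: dict[str, int] = {"low": 0, "high": 0}

    for category, panel, tested, positive in strata:
        era_year = 2010 if panel == "Sanger-Test" else 2018
        genes = sanger_genes if panel == "Sanger-Test" else ngs_genes
        for j in range(tested):
            idx = per_cat_index[category]
            per_cat_index[category] += 1
            is_male = idx < sex_targets[category]
            has_other = idx < other_cancer_targets[category]
            age = float(np.clip(rng.normal(47, 14), 10, 90))
            if category == "high":
                n_mel, relatives = 3, []
            else:
                n_mel, relatives = 2, []
            p = PatientRecord(
                id=f"R{len(patients) + 1:04d}",
                sex="M" if is_male else "F",
                age_first_melanoma=age,
                n_melanomas=n_mel,
                relatives=list(relatives),
                other_cancers=["other cancer"] if has_other else [],
                test_year=era_year,
            )
            if j < positive:
                gene = genes.pop(0)
                if gene == "CDKN2A":
                    p.observed_variants.append(obs_queue[obs_i])
                    obs_i += 1
                    cdkn2a_patients.append(p)
                elif gene == "CDK4" and panel == "Sanger-Test":
                    vid, cls, codon = _CDK4_SANGER_VARIANTS[
                        cdk4_sanger_i % len(_CDK4_SANGER_VARIANTS)
                    ]
                    cdk4_sanger_i += 1
                    p.observed_variants.append(
                        ObservedVariant("CDK4", cls, codon, vid)
                    )
                elif gene == "CDK4":
                    vid, cls, codon = _CDK4_NGS_EXTRA
                    p.observed_variants.append(
                        ObservedVariant("CDK4", cls, codon, vid)
                    )
                elif gene == "MITF":
                    if mitf_i < 7:
                        p.observed_variants.append(
                            ObservedVariant("MITF", "P", 318, "MITF:c.952G>A")
                        )
                    else:
                        p.observed_variants.append(
                            ObservedVariant(
                                "MITF", "VUS", None, f"MITF:VUS{mitf_i - 6}"
                            )
                        )
                    mitf_i += 1
                else:
                    p.observed_variants.append(
                        ObservedVariant(gene, "VUS", None, f"{gene}:VUS")
                    )
            patients.append(p)

    # two extra carrier observations -> first two CDKN2A patients carry two
    while obs_i < n_carriers:
        host = cdkn2a_patients[(n_carriers - 1) - obs_i]
        extra = obs_queue[obs_i]
        if extra.variant_id == host.observed_variants[0].variant_id:
            host = cdkn2a_patients[obs_i]
        host.observed_variants.append(extra)
        obs_i += 1

    assert len(patients) == sum(cat_sizes.values())
    return patients
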