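"""Readers and writers for the formats the pipeline touches.

Variants enter either as a VCF v4.2 subset (site columns only, genomic-strand
alleles, anchored-base indel convention) or as a coding-strand TSV matching
the curated-table schema.  Both dialects produce identical
:class:`~melpanel.consequence.VariantRecord` objects: VCF alleles are
reverse-complemented onto the coding strand for minus-strand genes and the
anchored base is stripped from indels.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .consequence import (
    IsoformConsequence,
    VariantRecord,
    annotate_variant,
    combined_impact,
    render_variant_string,
)
from .transcript import GeneModel, GenomicPosition, reverse_complement

__all__ = [
    "ParseError",
    "read_variants",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "annotation_table",
    "summary_report",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A variant or cohort file fails to parse (includes the line/record)."""


def _vcf_to_record(model: GeneModel, chrom, pos, ref, alt, vid) -> VariantRecord:
    """Convert one VCF site allele (genomic strand, anchored-base indels)."""
    ref, alt = ref.upper(), alt.upper()
    # reduce the anchored-base VCF convention to pure allele strings
    if len(ref) == len(alt):
        while len(ref) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        while len(ref) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    elif len(ref) > len(alt):  # deletion
        if not (alt and ref.startswith(alt)):
            raise ParseError(f"{chrom}:{pos}: unsupported complex allele")
        pos += len(alt)
        ref, alt = ref[len(alt):], ""
    else:  # insertion
        if not (ref and alt.startswith(ref)):
            raise ParseError(f"{chrom}:{pos}: unsupported complex allele")
        pos += len(ref) - 1  # genomic base 5' of the insertion point
        ref, alt = "", alt[len(ref):]
    if model.strand == "+":
        anchor = pos if ref else pos  # first ref base / base 5' of insertion
        c_ref, c_alt = ref, alt
    else:
        c_ref = reverse_complement(ref) if ref else ""
        c_alt = reverse_complement(alt) if alt else ""
        if ref:  # substitution / deletion: coding-first base = highest genomic
            anchor = pos + len(ref) - 1
        else:  # insertion between pos and pos+1 -> coding base 5' is pos+1
            anchor = pos + 1
    return VariantRecord(
        gene=model.symbol,
        position=GenomicPosition(chrom, anchor),
        ref=c_ref,
        alt=c_alt,
        id=vid or "",
    )


def read_variants(path, fmt: str, model: GeneModel) -> list[VariantRecord]:
    """Read variants as ``vcf`` (genomic strand) or ``coding-tsv``.

    The coding TSV has columns ``chrom  pos  ref  alt`` (plus optional ``id``)
    with coding-strand alleles and the coding-strand anchor convention of
    :class:`VariantRecord`.  Multiallelic VCF records are split with a
    warning; non-ACGT alleles raise :class:`ParseError`.
    """
    if fmt == "vcf":
        import pysam

        out = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vcf = pysam.VariantFile(str(path))
            for rec in vcf:
                alts = rec.alts or ()
                if len(alts) > 1:
                    log.warning(
                        "%s:%s multiallelic record split into %d variants",
                        rec.chrom, rec.pos, len(alts),
                    )
                for alt in alts:
                    if any(b not in "ACGT" for b in (rec.ref or "") + alt):
                        raise ParseError(
                            f"{rec.chrom}:{rec.pos}: non-ACGT allele "
                            f"{rec.ref}>{alt}"
                        )
                    try:
                        out.append(
                            _vcf_to_record(
                                model, rec.chrom, rec.pos, rec.ref, alt,
                                rec.id,
                            )
                        )
                    except ValueError as exc:
                        raise ParseError(f"{rec.chrom}:{rec.pos}: {exc}") from exc
        return out
    if fmt == "coding-tsv":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        out = []
        for i, row in df.iterrows():
            try:
                out.append(
                    VariantRecord(
                        gene=row.get("gene", model.symbol) or model.symbol,
                        position=GenomicPosition(row["chrom"], int(row["pos"])),
                        ref=row.get("ref", ""),
                        alt=row.get("alt", ""),
                        id=row.get("id", ""),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path} line {i + 2}: {exc}") from exc
        return out
    raise ValueError(f"unknown variant format {fmt!r}")


def annotation_table(model: GeneModel, variants: list[VariantRecord]) -> pd.DataFrame:
    """One row per variant x isoform plus a combined row per variant."""
    rows = []
    for v in variants:
        cons: list[IsoformConsequence] = annotate_variant(model, v)
        for c in cons:
            rows.append(
                {
                    "id": v.id, "gene": v.gene, "chrom": v.position.chrom,
                    "pos": v.position.pos, "ref": v.ref, "alt": v.alt,
                    "isoform": c.isoform, "region": c.region,
                    "category": str(c.category), "hgvs_c": c.hgvs_c,
                    "hgvs_p": c.hgvs_p,
                }
            )
        rows.append(
            {
                "id": v.id, "gene": v.gene, "chrom": v.position.chrom,
                "pos": v.position.pos, "ref": v.ref, "alt": v.alt,
                "isoform": "combined", "region": "",
                "category": combined_impact(cons).label,
                "hgvs_c": render_variant_string(cons), "hgvs_p": "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort TSV (versioned header)
# ---------------------------------------------------------------------------

COHORT_SCHEMA_VERSION = "melpanel-cohort-v1"
_COHORT_COLUMNS = [
    "id", "sex", "age_first_melanoma", "n_melanomas", "relatives",
    "other_cancers", "test_year", "observed_variants",
]


def write_cohort_tsv(patients, path) -> None:
    from .cohort import PatientRecord  # noqa: F401

    import json

    rows = []
    for p in patients:
        rows.append(
            {
                "id": p.id,
                "sex": p.sex,
                "age_first_melanoma": f"{p.age_first_melanoma:.1f}",
                "n_melanomas": p.n_melanomas,
                "relatives": json.dumps(
                    [[r.degree, r.cancer] for r in p.relatives],
                    separators=(",", ":"),
                ),
                "other_cancers": json.dumps(p.other_cancers, separators=(",", ":")),
                "test_year": p.test_year,
                # variant ids may contain arbitrary punctuation: JSON-encode
                "observed_variants": json.dumps(
                    [
                        [ov.gene, ov.class_label, ov.codon, ov.variant_id]
                        for ov in p.observed_variants
                    ],
                    separators=(",", ":"),
                    ensure_ascii=False,
                ),
            }
        )
    with open(path, "w") as fh:
        fh.write(f"# {COHORT_SCHEMA_VERSION}\n")
        pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(
            fh, sep="\t", index=False
        )


def read_cohort_tsv(path) -> list:
    from .cohort import ObservedVariant, PatientRecord, Relative

    with open(path) as fh:
        header = fh.readline()
        if COHORT_SCHEMA_VERSION not in header:
            raise ParseError(
                f"{path}: missing schema header {COHORT_SCHEMA_VERSION!r}"
            )
        df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    import json

    patients = []
    for i, row in df.iterrows():
        try:
            relatives = [
                Relative(int(d), cancer)
                for d, cancer in json.loads(row["relatives"] or "[]")
            ]
            variants = [
                ObservedVariant(gene, cls, codon, vid)
                for gene, cls, codon, vid in json.loads(
                    row["observed_variants"] or "[]"
                )
            ]
            patients.append(
                PatientRecord(
                    id=row["id"],
                    sex=row["sex"],
                    age_first_melanoma=float(row["age_first_melanoma"]),
                    n_melanomas=int(row["n_melanomas"]),
                    relatives=relatives,
                    other_cancers=list(json.loads(row["other_cancers"] or "[]")),
                    test_year=int(row["test_year"]),
                    observed_variants=variants,
                )
            )
        except (ValueError, IndexError, json.JSONDecodeError) as exc:
            raise ParseError(f"{path} line {i + 3}: {exc}") from exc
    return patients


def summary_report(summary) -> str:
    """Plain-text cohort report mirroring the published table layout.

    Both raw fractions and integer-rounded percentages are rendered so that
    comparisons against printed values are unambiguous.
    """
    from .cohort import round_pct

    n = summary.n_patients
    lines = ["Cohort summary", "=============", ""]
    lines.append("A. Cases referred to genetic testing")
    for cat in ("low", "high"):
        c = summary.category_counts[cat]
        mean, sd = summary.onset_age[cat]
        lines.append(
            f"  {cat:>4} significance: {c}/{n} ({round_pct(c, n)}%)  "
            f"M/F {summary.sex_counts[cat]['M']}/{summary.sex_counts[cat]['F']}  "
            f"onset {mean:.0f} y ± {sd:.0f} y  "
            f"other cancer {summary.other_cancer_counts[cat]}"
        )
    lines.append("")
    lines.append("B. Positivity by stratum (category × panel)")
    for (cat, panel), s in sorted(summary.strata.items()):
        lines.append(
            f"  {cat:>4} × {panel:<11}: {s['positive']}/{s['tested']} "
            f"({round_pct(s['positive'], s['tested'])}%)"
        )
    npos = summary.n_positive
    lines.append(
        f"  total positive: {npos}/{n} ({round_pct(npos, n)}%)"
    )
    lines.append("")
    lines.append("C. Positive patients per gene")
    for gene, k in sorted(summary.gene_positive.items(), key=lambda kv: -kv[1]):
        lines.append(f"  {gene:<7} {k:3d} ({round_pct(k, npos)}% of positives)")
    return "\n".join(lines) + "\n"
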