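"""Annotate CDKN2A variants across the four overlapping isoforms.

The same genomic substitution can have different consequences in different
reading frames: chr9:21971146 A>G is the missense change p.N71S in p16INK4a
but the synonymous change p.Q85Q in p14ARF, because p14ARF reads the shared
exon 2 shifted by one base.
"""

from melpanel import GenomicPosition, VariantRecord, annotate_variant
from melpanel.consequence import combined_impact, render_variant_string
from melpanel.fixtures import load_panel_models

cdkn2a = load_panel_models()["CDKN2A"]

variants = [
    ("hotspot missense", VariantRecord("CDKN2A", GenomicPosition("chr9", 21971146), "A", "G")),
    ("splice donor", VariantRecord("CDKN2A", GenomicPosition("chr9", 21994137), "G", "A")),
    ("4-nt duplication", VariantRecord("CDKN2A", GenomicPosition("chr9", 21971164), "", "TGCT")),
    ("intronic for p16, coding for p12",
     VariantRecord("CDKN2A", GenomicPosition("chr9", 21974672), "G", "T")),
]

for label, v in variants:
    cons = annotate_variant(cdkn2a, v)
    print(f"{label}  ({v.position} {v.ref or '-'}>{v.alt or '-'})")
    for c in cons:
        p = f" {c.hgvs_p}" if c.hgvs_p else ""
        print(f"    {c.isoform:5s} {str(c.category):18s} {c.hgvs_c}{p}")
    print(f"    combined impact: {combined_impact(cons).label}")
    print(f"    report string:   {render_variant_string(cons)}")
    print()

print(
    "Each block lists the per-isoform consequence; the combined impact keeps\n"
    "only the strongest tier, and the report string groups isoforms that\n"
    "share the same HGVS names."
)
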