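# Packaged data

All files here are plain text and checksummed (`checksums.json`); they are
loaded and validated by `melpanel.fixtures`.

## Synthetic panel loci (`panel_loci.fasta`, `*_model.yaml`)

The CDKN2A, CDK4, MITF, BAP1 and POT1 locus sequences are **synthetic,
anchor-consistent reconstructions**, not copies of the reference genome.
The CDKN2A model reproduces the real locus architecture — four isoforms
(p16INK4a, p14ARF, p12, p16γ) on the minus strand of chromosome 9, with
p14ARF reading the shared exon 2 in a frame shifted by +43 coding bases and
p12 reading through the exon-1α donor site — and every coordinate anchor of
the curated variant table below:

* all genomic ↔ c. coordinate pairs of the table;
* every printed reference base, and every reference codon implied by a
  printed protein call, in **all overlapping frames simultaneously**
  (e.g. chr9:21971146 must be both p16 codon 71 = AAC and the third base of
  p14 codon 85 = CAA);
* the frame-0 backbone is the canonical 156-residue p16INK4a protein;
* every frameshift stop distance (p.H66Afs*55, p.A68Rfs*78, p.R82Afs*90,
  p.P80Cfs*82, p.D146Gfs*19), which pins stop codons in the shifted frames —
  consistently, these constraints imply a p14ARF open reading frame of
  exactly 132 residues, the true length of human p14ARF;
* canonical GT/AG splice dinucleotides at every modelled junction.

Sequence between anchors is designed filler. The CDK4/MITF/BAP1/POT1 models
are single-exon simplifications carrying only the variants the pipeline
needs (CDK4 codon 24 R24H/R24L, codon 48 G48del; MITF E318K).
Built and verified by `tools/build_reference_locus.py`.

## Curated variant table (`table3_variants.tsv`)

Machine-readable transcription of the published 33-variant CDKN2A spectrum
(variant strings normalized to remove typographic spacing). Columns `pos`,
`ref`, `alt` give the *curated* coding-strand representation (anchor = first
coding-strand base; insertions anchor on the base 5' of the insertion
point). Known internal inconsistencies of the source table, flagged in the
`flags` column:

* `p14:c.193+1G>A` — printed position 21994136 disagrees by 1 nt with the
  position implied by the `p14:c.161 ↔ 21994170` anchor; the curated
  position (21994137, a canonical GT donor) follows the latter
  (`pos_discrepant`).
* `c.202_203` row — printed position 21971154 is off by 2 from the position
  implied by every other exon-2 anchor; the p16 half prints alt `TT` while
  the p14 half of the same row prints `delGCinsCT` (alt `CT`). Only GC>CT is
  consistent with both printed protein calls (p.A68L and p.R82P); the
  curated alleles are GC>CT (`pos_discrepant,alt_discrepant`).
* `c.212A>T (p.N71I)` row — the p14 half prints `c.255A>G` but the protein
  call p.Q85H is only consistent with A>T; excluded from byte-exact
  regression (`alt_discrepant,excluded`).
* `p16:c.458-105A>G (p.156_157del)` row — pairs an intronic coding position
  with an in-frame-deletion protein call; carried verbatim, not recomputed
  (`excluded`).

The body text of the source also prints `c.71G>T (p.R24P)` once; the table's
`c.71G>C` is the change consistent with Arg→Pro and is what this fixture
stores. Carrier counts sum to 100 across 98 CDKN2A-positive patients (two
patients carry two variants each).

## Cohort fixtures

* `strata_counts.tsv` — tested/positive patients per clinical category ×
  test era (418/13, 120/23, 268/67, 82/25; totals 888 tested, 128 positive).
* `gene_positive_counts.tsv` — positive patients per gene (98/10/9/9/2).
* `table2_cohort.tsv` — cohort description counts (sex, onset age mean±SD,
  other cancers) for referred patients and for carriers.
* `primers.tsv` — PCR primer sequences of the historical Sanger assay
  (data only; no in-silico PCR is performed).
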