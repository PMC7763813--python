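# Methods

This note documents the models, rules and numerical choices behind
`melpanel`, and what the packaged synthetic data can and cannot show.

## Gene and transcript model

Genes are modelled as ordered exon lists per isoform with transcript-space
CDS bounds; all public coordinates are 1-based inclusive (HGVS/VCF style)
and internal exon arithmetic is 0-based half-open. CDKN2A is modelled on the
minus strand of chr9 with four isoforms:

| isoform | exons | CDS | note |
|---|---|---|---|
| p16INK4a | 1α, 2, 3 | 471 nt (156 aa) | canonical numbering used throughout |
| p14ARF | 1β, 2, 3 | 399 nt (132 aa) | alternate first exon ~20 kb upstream; exon-2 frame shifted by +43 coding bases relative to p16; stops inside exon 2 |
| p12 | extended 1α | 249 nt | reads through the exon-1α donor into intron 1 |
| p16γ | 1α, 2, 2γ, 3 | 507 nt | private exon 2γ inside intron 2; shares p16 numbering to c.457 |

Intronic positions are anchored to the nearest exon boundary (donor `+k`,
acceptor `−k`, ties to the donor); 5'UTR positions are `−n`, 3'UTR `*n`.
The projection is exactly invertible on exonic positions (tested over every
exonic base of every isoform).

### The packaged locus is synthetic

No reference-genome sequence is bundled. Instead the locus is *designed*:
every genomic↔c. anchor, printed reference base, reference codon implied by
a protein call in any of the overlapping frames, frameshift stop distance
(`fs*N`), and splice dinucleotide is imposed as a constraint, and a
backtracking search over synonymous codons fills the rest
(`tools/build_reference_locus.py`; fixed build seed). Two observations give
confidence in the reconstruction: the constraint system is satisfiable at
all (33 published variant rows interlock over four reading frames), and the
anchors *imply* a p14ARF open reading frame of exactly 132 residues — the
true length of human p14ARF — without that ever being imposed. Consequence
calls at the anchors therefore behave exactly as on the real locus;
consequence calls at non-anchor positions are correct *relative to the
synthetic sequence* and are exercised only by property tests, never
interpreted clinically.

## Consequence calling

For each isoform containing a variant, the engine classifies by region and
recomputes the protein by editing the spliced transcript:

* **Substitutions** — codon comparison: silent (`p.A17A`), missense,
  nonsense. Nonsense is rendered in the clinical `X` style (`p.E27X`) by
  default, `Ter` optionally. Stop-loss renders as an extension (`ext*N`).
* **Indels** — 3'-normalized (HGVS shifting rule) on the coding strand
  before naming. Frame-preserving deletions are named at their most
  C-terminal equivalent protein position (removing one Gly codon from a
  Gly₄ run at residues 45–48 names `p.G48del`); frameshifts re-translate
  the mutated sequence through the 3'UTR and report the first changed
  residue plus the new stop distance, counting the changed residue as 1
  (`p.H66Afs*55`); a frameshift whose first changed residue is itself a
  stop collapses to the nonsense style (`p.Y44X`).
* **Duplication style** — an insertion identical to its upstream neighbour
  is written `dup` for units of ≥ 2 bases and `ins` for single bases
  (`c.191_194dupTGCT` but `c.436_437insG`), matching the source table's
  usage; multi-nucleotide substitutions are written `delins`.
* **Splice window** — intronic offsets |k| ≤ 2 are *splicing*; offsets
  2 < |k| ≤ 50 are *splicing* only when the same genomic position is exonic
  in a sibling isoform (this reproduces the splicing/missense labels at
  +5/+37/+49 where p12 reads the p16 intron as coding, without flagging
  deep-intronic positions); both bounds are configurable arguments.
* **Combined impact** — distinct categories joined by `/` in priority order
  truncating > splicing > missense > in-frame deletion > silent > UTR >
  intronic; only the strongest tier is kept (a silent or UTR call in one
  isoform is suppressed by a coding call in another). The aggregate report
  string groups isoforms with identical HGVS names and falls back to the
  canonical isoform for UTR/intronic-only variants.

Edits that span an exon/intron junction are refused (`UnsupportedEditError`)
rather than guessed. Region classification happens *before* indel
normalization, so a repeat deletion straddling the UTR/CDS boundary is not
reclassified by its shifted name.

## Bayesian ACMG classification

Criterion counts map to the exponent
`X = (8·nPVS + 4·nPS + 2·nPM + nPP − 4·nBS − nBP)/8`; posterior odds are
`O^X · prior/(1−prior)`. Defaults: prior 0.10, very-strong odds O = 350.
Class bands are uniformly half-open, upper-inclusive at 1.0:
P [0.99, 1], LP [0.90, 0.99), VUS-3B [0.675, 0.90), VUS [0.325, 0.675),
VUS-favoring-benign [0.10, 0.325), LB [0.001, 0.10), B [0, 0.001).
The tripartition of the uncertain region is provisional and, like the prior
and odds, a configuration value. Benign evidence is weighted symmetrically
to pathogenic evidence of the same strength; a stand-alone benign criterion
(BA1) short-circuits to class B. With no evidence the posterior equals the
prior exactly and sits at the benign-leaning edge of the uncertain region.
Evidence profiles for the curated variant table are *not* reconstructed —
the published classes are carried as given labels.

## Cohort rules

* **Eligibility** — at least one melanoma, and (MPM and/or FM referral):
  a single melanoma with no affected relative is not referable.
* **Triage** — high: ≥3 melanomas, or 2 + ≥1 affected first/second-degree
  relative, or 1 + ≥2 affected relatives; low: 2 + 0, or 1 + 1. "Affected"
  counts cutaneous melanoma only; pancreatic-cancer relatives do not change
  the category (they only trigger the CDKN2A pancreatic-surveillance
  branch). Relatives are counted individually; same-side-of-family
  aggregation is not modelled.
* **Panels** — Sanger-Test: full CDKN2A coding plus CDK4 codon 24 (a
  protein-position filter); NGS-Test: CDKN2A, CDK4, BAP1, MITF, POT1. Era
  assignment: test year ≤ 2017 → Sanger, ≥ 2018 → NGS, overridable per
  record. Positivity = at least one visible variant in {P, LP, VUS-3B, VUS}.
* **Spectrum accounting** — one causal gene per positive patient, with
  precedence CDKN2A > CDK4 > BAP1 > MITF > POT1 for the rare multi-gene
  carrier (logged). The curated carrier counts sum to 100 over 98 CDKN2A
  patients; the reference cohort gives two patients two variants each, and
  the summarizer counts patients.
* **Destabilization tally** — a missense variant counts as destabilizing
  when any isoform's modelling label is Hd, D or Sd (highly/ordinarily/
  slightly destabilizing); Ss (slightly stabilizing) and N (neutral) do not
  count. On the curated table this yields 17 of 20 missense variants.
* **Rounding** — report percentages are rounded half away from zero. Note
  538/888 = 60.6% renders as 61%, whereas the source prints the looser
  60%/40% pair; count-level comparisons are exact.
* **Surveillance** — rule-engine output per final result: negative →
  8–10-month skin checks + re-counselling at 12 months; VUS-only →
  6-month checks + 6-month VUS re-review; CDKN2A (P/LP/VUS-3B) → 3-month
  checks, plus gastroenterological evaluation and pancreas MRI/EUS when a
  first/second-degree relative has pancreatic cancer; CDK4 → 3-month
  checks; BAP1 → biannual checks from age 18 and annual eye examination
  from 16 plus periodic visceral imaging; MITF → 6-month checks, abdominal
  ultrasound and 6-month urinary cytology; POT1 → Li-Fraumeni-style
  follow-up flag.

## Synthetic data

The cohort generator emulates a testing-referral population: 60/40 low/high
category mix, onset age Normal(47 y, 14 y) truncated to [10, 90], male
fraction 434/888, Sanger:NGS era mix 686:202, per-stratum positivity
3%/19%/25%/30%, gene weights 98:10:9:9:2, other-cancer rates 9% (low) and
14% (high), and a 5% rate of pancreatic-cancer family history to exercise
the surveillance branch. Melanoma counts and affected-relative counts are
drawn uniformly from the category-compatible sets (the source states only
category membership, not a count distribution) — so triage recovers the
assigned category by construction, which is a *design guarantee*, not an
empirical finding. Sanger-era positives are restricted to Sanger-visible
variants; CDKN2A variants are drawn from the curated table weighted by
carrier counts; BAP1/POT1 simulate only VUS findings, matching the observed
spectrum. One explicit `numpy` generator per cohort; the seed is mandatory.

What the simulator does **not** emulate: real family pedigree structure
(relatives are independent draws), genotype–phenotype correlation, age or
sex effects on positivity, sequencing error, or variant calling — positives
are injected at the record level. Passing tests on synthetic cohorts
therefore validate the *bookkeeping* (triage, masking, counting, rates),
not any biological claim.

The toy-gene generator builds small multi-exon genes with an optional
second isoform that reads a shared exon in a shifted frame and ends at that
frame's first stop, mimicking the p16/p14ARF architecture; 3'UTRs are
seeded with stops in all three frames so frameshift renaming always
terminates. It is the substrate for the oracle-equivalence property test
(annotator vs an independent brute-force mutate–splice–translate
implementation, 100% category agreement required).

## Problem sizes and determinism

Default verification sizes: ≥ 1000 random variants across 14 toy genes for
oracle equivalence, a 10,000-patient synthetic cohort for rate recovery
(each stratum within 3 binomial standard errors), exhaustive projection
round-trips over every exonic base of every CDKN2A isoform, and the
deterministic 888-patient reference cohort for the published percentages.
All randomness flows from explicit seeds; identical seeds give byte-identical
cohorts and gene models.

## Known limitations

* Single-variant, single-gene annotation: no multi-allelic VCF
  normalization beyond splitting, no complex alleles (non-shared-prefix
  REF/ALT pairs are rejected), no trans-phasing.
* No start-codon scanning: an insertion exactly between the 5'UTR and the
  first CDS base, or edits of the initiator codon, are outside the
  annotator's contract.
* The seven-class VUS tripartition bounds (0.325/0.675) follow the
  framework family the defaults come from but are not uniquely determined;
  they are configuration, not science.
* CDK4/MITF/BAP1/POT1 are single-exon synthetic models carrying only the
  panel-relevant variants; their non-anchor sequence is filler.
* No penetrance or survival modelling, and no statistical tests between
  categories.
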