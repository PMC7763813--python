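"""Seeded synthetic data: clinical cohorts and toy overlapping-frame genes.

The cohort generator emulates the statistical structure of a referral cohort
for melanoma genetic testing: a 60/40 low/high clinical-category mix, onset
ages ~ Normal(47, 14) truncated to [10, 90], era-specific panels in 686:202
proportion, per-stratum positivity (3% low x Sanger, 19% low x NGS, 25%
high x Sanger, 30% high x NGS) and a per-gene spectrum among positives
proportional to 98:10:9:9:2 (CDKN2A:MITF:CDK4:BAP1:POT1).  Patient histories
are drawn *conditional on the assigned category* so triage provably recovers
it; Sanger-era positives are restricted to Sanger-visible variants.

The toy-gene generator builds small multi-exon genes, optionally with a
second isoform that reads a shared exon in a shifted frame (the architecture
that makes CDKN2A annotation hard), for property-based testing of the
annotator against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import MELANOMA, PANCREATIC, ObservedVariant, PatientRecord, Relative
from .transcript import Exon, GeneModel, Isoform, LocusSequence, reverse_complement

__all__ = [
    "CohortSimConfig",
    "ToyGeneConfig",
    "generate_cohort",
    "generate_toy_gene",
]

_DEFAULT_RATES = {
    ("low", "Sanger-Test"): 0.03,
    ("low", "NGS-Test"): 0.19,
    ("high", "Sanger-Test"): 0.25,
    ("high", "NGS-Test"): 0.30,
}
_DEFAULT_GENE_WEIGHTS = {"CDKN2A": 98, "MITF": 10, "CDK4": 9, "BAP1": 9, "POT1": 2}

#: compact variant catalogs used to decorate simulated positives
_SANGER_VISIBLE = {"CDKN2A", "CDK4"}
_GENE_VARIANTS = {
    "CDK4": [("CDK4:c.71G>A (p.R24H)", "P", 24),
             ("CDK4:c.71G>T (p.R24L)", "P", 24),
             ("CDK4:c.132_134delAGG (p.G48del)", "VUS", 48)],
    "MITF": [("MITF:c.952G>A (p.E318K)", "P", 318),
             ("MITF:VUS-1", "VUS", None),
             ("MITF:VUS-2", "VUS", None),
             ("MITF:VUS-3", "VUS", None)],
    "BAP1": [("BAP1:VUS-1", "VUS", None), ("BAP1:VUS-2", "VUS", None)],
    "POT1": [("POT1:VUS-1", "VUS", None), ("POT1:VUS-2", "VUS", None)],
}


@dataclass
class CohortSimConfig:
    n_patients: int
    seed: int
    category_mix: tuple[float, float] = (0.60, 0.40)  # (low, high)
    male_fraction: float = 434 / 888
    onset_age_mean: float = 47.0
    onset_age_sd: float = 14.0
    onset_age_bounds: tuple[float, float] = (10.0, 90.0)
    positivity: dict = field(default_factory=lambda: dict(_DEFAULT_RATES))
    gene_weights: dict = field(default_factory=lambda: dict(_DEFAULT_GENE_WEIGHTS))
    sanger_fraction: float = 686 / 888
    other_cancer_rate: dict = field(
        default_factory=lambda: {"low": 0.09, "high": 0.14}
    )
    pancreatic_family_rate: float = 0.05

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category mix must sum to 1")
        for k, r in self.positivity.items():
            if not 0 <= r <= 1:
                raise ValueError(f"positivity rate {k} = {r} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _draw_history(rng: np.random.Generator, category: str) -> tuple[int, int]:
    """(n_melanomas, n_affected_relatives) consistent with the category."""
    if category == "high":
        pattern = rng.integers(3)
        if pattern == 0:
            return int(rng.integers(3, 6)), int(rng.integers(0, 3))
        if pattern == 1:
            return 2, int(rng.integers(1, 4))
        return 1, int(rng.integers(2, 4))
    return (2, 0) if rng.integers(2) == 0 else (1, 1)


from functools import lru_cache


@lru_cache(maxsize=1)
def _cdkn2a_catalog():
    from .fixtures import _variant_codon, load_fixtures

    t3 = load_fixtures().table3
    w = t3["carriers"].to_numpy(dtype=float)
    rows = [
        (r["variant"], r["acmg_class"], _variant_codon(r["variant"]))
        for _, r in t3.iterrows()
    ]
    return rows, w / w.sum()


def _pick_cdkn2a_variant(rng: np.random.Generator):
    """CDKN2A variant drawn from the curated table, weighted by carriers."""
    rows, p = _cdkn2a_catalog()
    return rows[int(rng.choice(len(rows), p=p))]


def generate_cohort(cfg: CohortSimConfig) -> list[PatientRecord]:
    """Fully reproducible synthetic cohort; triage recovers every category."""
    rng = np.random.default_rng(cfg.seed)
    patients: list[PatientRecord] = []
    genes = list(cfg.gene_weights)
    weights = np.array([cfg.gene_weights[g] for g in genes], dtype=float)
    weights /= weights.sum()
    sanger_idx = [i for i, g in enumerate(genes) if g in _SANGER_VISIBLE]
    w_sanger = weights[sanger_idx] / weights[sanger_idx].sum()

    for i in range(cfg.n_patients):
        category = "low" if rng.random() < cfg.category_mix[0] else "high"
        sanger_era = rng.random() < cfg.sanger_fraction
        panel = "Sanger-Test" if sanger_era else "NGS-Test"
        test_year = int(rng.integers(1998, 2018)) if sanger_era else 2018
        n_mel, n_rel = _draw_history(rng, category)
        relatives = [
            Relative(int(rng.integers(1, 3)), MELANOMA) for _ in range(n_rel)
        ]
        if rng.random() < cfg.pancreatic_family_rate:
            relatives.append(Relative(int(rng.integers(1, 3)), PANCREATIC))
        age = float(
            np.clip(
                rng.normal(cfg.onset_age_mean, cfg.onset_age_sd),
                *cfg.onset_age_bounds,
            )
        )
        p = PatientRecord(
            id=f"S{i + 1:05d}",
            sex="M" if rng.random() < cfg.male_fraction else "F",
            age_first_melanoma=age,
            n_melanomas=n_mel,
            relatives=relatives,
            other_cancers=(
                ["other cancer"]
                if rng.random() < cfg.other_cancer_rate[category]
                else []
            ),
            test_year=test_year,
        )
        p.category = category  # latent assignment; triage must recover it
        if rng.random() < cfg.positivity[(category, panel)]:
            if sanger_era:
                gene = genes[sanger_idx[int(rng.choice(len(sanger_idx), p=w_sanger))]]
            else:
                gene = genes[int(rng.choice(len(genes), p=weights))]
            if gene == "CDKN2A":
                vid, cls, codon = _pick_cdkn2a_variant(rng)
            else:
                candidates = _GENE_VARIANTS[gene]
                if sanger_era and gene == "CDK4":
                    candidates = [c for c in candidates if c[2] == 24]
                vid, cls, codon = candidates[int(rng.integers(len(candidates)))]
            p.observed_variants.append(ObservedVariant(gene, cls, codon, vid))
        patients.append(p)
    return patients


# ---------------------------------------------------------------------------
# toy genes
# ---------------------------------------------------------------------------


@dataclass
class ToyGeneConfig:
    seed: int
    n_exons: int = 3
    exon_len: tuple[int, int] = (30, 90)  # multiples not required
    intron_len: tuple[int, int] = (20, 60)
    strand: str = "+"
    dual_isoform: bool = False
    utr5: int = 12
    utr3: int = 30

    def __post_init__(self):
        if self.n_exons < 1 or self.exon_len[0] < 9 or self.intron_len[0] < 6:
            raise ValueError("impossible toy-gene geometry")
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")


_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    out = ["ATG"]
    while len(out) < n_codons:
        c = "".join(rng.choice(list(_BASES), 3))
        if c not in _STOPS and c != "ATG":
            out.append(c)
    return "".join(out)


def generate_toy_gene(cfg: ToyGeneConfig) -> GeneModel:
    """A validated toy gene with locus sequence (plus a frame-shifted second
    isoform over the shared exons when ``dual_isoform`` is set).

    The second isoform mimics the p14ARF architecture: a private first exon
    upstream, then the shared exons read in a frame shifted by 1 or 2, with
    its CDS ending at the first stop of that frame.  The 3'UTR is seeded with
    stops in all frames so frameshift naming always terminates.
    """
    rng = np.random.default_rng(cfg.seed)
    for _attempt in range(200):
        model = _try_toy_gene(rng, cfg)
        if model is not None:
            return model
    raise RuntimeError("could not generate a toy gene for this configuration")


def _try_toy_gene(rng: np.random.Generator, cfg: ToyGeneConfig) -> GeneModel | None:
    exon_lens = [
        int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        for _ in range(cfg.n_exons)
    ]
    tx_len = sum(exon_lens)
    cds_len = tx_len - cfg.utr5 - cfg.utr3
    cds_len -= cds_len % 3
    if cds_len < 30:
        return None
    cds = _random_orf(rng, cds_len // 3 - 1) + "TGA"
    utr3_len = tx_len - cfg.utr5 - len(cds)
    stop_pad = "TAAATAAATAAA"  # a stop in every reading frame
    utr3 = (
        "".join(rng.choice(list(_BASES), max(utr3_len - len(stop_pad), 0)))
        + stop_pad
    )[:utr3_len]
    if utr3_len >= len(stop_pad):
        utr3 = stop_pad + utr3[len(stop_pad):]
    tx = "".join(rng.choice(list(_BASES), cfg.utr5)) + cds + utr3

    intron_lens = [
        int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        for _ in range(cfg.n_exons - 1)
    ]
    # genomic layout on the coding strand, 5'->3'
    exon_bounds = []
    offset5 = 40  # leader before the first exon
    genome_coding = []
    genome_coding.append("".join(rng.choice(list(_BASES), offset5)))
    pos = offset5
    t = 0
    for i, L in enumerate(exon_lens):
        exon_bounds.append((pos, pos + L - 1))  # 0-based coding-strand coords
        genome_coding.append(tx[t : t + L])
        t += L
        pos += L
        if i < len(intron_lens):
            genome_coding.append("".join(rng.choice(list(_BASES), intron_lens[i])))
            pos += intron_lens[i]
    tail = 40
    genome_coding.append("".join(rng.choice(list(_BASES), tail)))
    coding_seq = "".join(genome_coding)

    isoforms_coding = [
        # (name, exon bounds in coding-strand 0-based coords, cds_start, cds_end)
        ("isoA", list(exon_bounds), cfg.utr5 + 1, cfg.utr5 + len(cds)),
    ]

    if cfg.dual_isoform and cfg.n_exons >= 2:
        # private first exon inserted into the leader region
        shift = int(rng.integers(1, 3))  # frame offset 1 or 2
        privA_len = 3 * int(rng.integers(4, 8)) + shift
        priv_utr5 = 6
        priv_len = priv_utr5 + privA_len
        if priv_len > offset5 - 10:
            return None
        priv_lo = 2
        priv_hi = priv_lo + priv_len - 1
        priv_cds = _random_orf(rng, (privA_len - shift) // 3)
        priv_cds += "".join(rng.choice(list(_BASES), shift))
        priv_seq = "".join(rng.choice(list(_BASES), priv_utr5)) + priv_cds
        coding_seq = (
            coding_seq[:priv_lo] + priv_seq + coding_seq[priv_hi + 1 :]
        )
        # isoform B: private exon + shared exons 2..n
        b_bounds = [(priv_lo, priv_hi)] + list(exon_bounds[1:])
        b_tx = priv_seq + "".join(
            coding_seq[s : e + 1] for s, e in exon_bounds[1:]
        )
        b_cds_start = priv_utr5 + 1
        # read frame from B's ATG; CDS ends at the first stop
        read = b_tx[b_cds_start - 1 :]
        stop_at = None
        for k in range(0, len(read) - 2, 3):
            if read[k : k + 3] in _STOPS:
                stop_at = k
                break
        if stop_at is None or stop_at < privA_len + 9:
            return None
        b_cds_end = b_cds_start + stop_at + 2
        isoforms_coding.append(("isoB", b_bounds, b_cds_start, b_cds_end))

    # map coding-strand coordinates onto the genome for the requested strand
    n = len(coding_seq)
    offset = 1000
    if cfg.strand == "+":
        locus = LocusSequence(coding_seq, offset, "chrT")

        def to_genomic(span):
            return (offset + span[0], offset + span[1])

    else:
        locus = LocusSequence(reverse_complement(coding_seq), offset, "chrT")

        def to_genomic(span):
            # coding-strand index i -> genomic offset + (n - 1 - i)
            return (offset + n - 1 - span[1], offset + n - 1 - span[0])

    isoforms = []
    for name, bounds, cs, ce in isoforms_coding:
        g = [to_genomic(b) for b in bounds]
        if cfg.strand == "-":
            pass  # bounds are already in transcript order (5'->3' coding)
        exons = [Exon(start=lo, end=hi, rank=i + 1) for i, (lo, hi) in enumerate(g)]
        try:
            isoforms.append(
                Isoform(
                    name=name, strand=cfg.strand, exons=exons,
                    cds_start=cs, cds_end=ce,
                )
            )
        except Exception:
            return None
    try:
        return GeneModel(
            symbol="TOY", chrom="chrT", strand=cfg.strand,
            isoforms=isoforms, reference=locus,
        )
    except Exception:
        return None
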