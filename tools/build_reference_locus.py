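"""Build the packaged synthetic panel loci and report-table fixtures.

The CDKN2A locus shipped with the package is a SYNTHETIC reconstruction:
real public annotation is not bundled; instead every coordinate anchor,
printed reference base, reference codon implied by a protein call (in all
four overlapping reading frames), frameshift stop distance and splice anchor
of the curated variant table is imposed as a hard constraint on a designed
sequence, which is then verified end-to-end by annotating every variant with
the package and comparing against the expected strings.  The frame-0 backbone
is the canonical 156-residue p16INK4a protein sequence.

Run from the repository root:  python tools/build_reference_locus.py
Outputs go to src/melpanel/data/ (FASTA, YAML gene models, fixture TSVs,
checksums).  The script is deterministic (fixed seed).
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from melpanel.consequence import (  # noqa: E402
    VariantRecord,
    annotate_variant,
    combined_impact,
    render_variant_string,
)
from melpanel.transcript import (  # noqa: E402
    GenomicPosition,
    LocusSequence,
    load_gene_model,
    reverse_complement,
    translate_cds,
)

DATA = ROOT / "src" / "melpanel" / "data"

SEED = 93202011
RNG = np.random.default_rng(SEED)

STOPS = {"TAA", "TAG", "TGA"}

SYN = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "*": ["TAA", "TAG", "TGA"],
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# canonical p16INK4a, 156 residues
P16_AA = (
    "MEPAAGSSMEPSADWLATAAARGRVEEVRALLEAGALPNAPNSYGRRPIQ"
    "VMMMGSARVAELLLLHGAEPNCADPATLTRPVHDAAREGFLDTLVVLHRA"
    "GARLDVRDAWGRLPVDLAEELGHRDVARYLRAAAGGTRGSNHARIDAAEG"
    "PSDIPD"
)
assert len(P16_AA) == 156

# fully pinned p16 codons (cross-frame anchors of the curated variant table)
FIXED_CODONS = {
    17: "GCC", 18: "ACG", 19: "GCC", 24: "CGG", 44: "TAC",
    55: "GGC", 56: "AGC", 58: "CGA", 59: "GTG", 64: "CTG", 65: "CTC",
    66: "CAC", 67: "GGC", 68: "GCG", 69: "GAG", 70: "CCC", 71: "AAC",
    83: "CAC", 84: "GAC", 100: "GCC", 101: "GGG", 113: "CTG", 114: "CCT",
    118: "GCT", 119: "GAG", 126: "GTC", 142: "CAC", 144: "CGC", 145: "ATA",
    146: "GAC", 153: "GAC",
}
# codon 152 (Ser) must not end in T (a T at c.456 before the exon-3 / exon-2g
# junction base would create a stop in the shifted frame read by p.D146Gfs*19)
RESTRICTED = {152: [c for c in SYN["S"] if c[2] != "T"]}

# transcript-space no-stop windows (window = 3 bases starting at the given
# p16 c. position), from the frames read by p14ARF and by the frameshifted
# mutants of the curated table
NOSTOP_STARTS = (
    set(range(153, 352, 3))   # p14ARF ORF (stop must be exactly at 354)
    | set(range(197, 432, 3))  # +2-shift frame (A68Rfs*78 / P80Cfs*82 read)
    | set(range(438, 487, 3))  # 0-shift frame past the insG site (D146Gfs*19)
)
STOP_STARTS = {354, 434, 489}  # p14 natural stop; fs*78/*82 stop; fs*19 stop

UTR3_FIXED = {489: "T", 490: "G", 491: "A", 502: "G", 513: "C"}  # *18-20, *31, *42
UTR3_LEN = 127  # c.472 .. c.598 (*1 .. *127)


def rng_choice(seq):
    return seq[int(RNG.integers(len(seq)))]


def random_bases(n, gc=0.62):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(RNG.choice(list("ATGC"), size=n, p=[p[0], p[3], p[2], p[1]]))


def build_p16_with_frames() -> str:
    """p16 CDS (471 nt) + 3'UTR (127 nt) honouring all cross-frame windows.

    Backtracking over codon units 51..157 (157 = stop) then base units for
    the 3'UTR; each placement is checked against every fully-determined
    window constraint.
    """
    # exon 1 part (codons 1..50): single frame, no cross constraints
    exon1 = []
    for i in range(1, 51):
        aa = P16_AA[i - 1]
        codon = FIXED_CODONS.get(i) or rng_choice(SYN[aa])
        assert translate_cds(codon) == aa
        exon1.append(codon)
    head = "".join(exon1)  # c.1-150

    # units from c.151 onwards
    units = []  # (kind, payload-domain)
    for i in range(51, 157):
        aa = P16_AA[i - 1]
        if i in FIXED_CODONS:
            dom = [FIXED_CODONS[i]]
        elif i in RESTRICTED:
            dom = list(RESTRICTED[i])
        else:
            dom = list(SYN[aa])
        assert all(translate_cds(c) == aa for c in dom)
        units.append(("codon", dom))
    units.append(("codon", ["TGA"]))  # stop, c.469-471
    for c in range(472, 472 + UTR3_LEN):
        if c in UTR3_FIXED:
            dom = [UTR3_FIXED[c]]
        else:
            dom = list("ACGT")
        units.append(("base", dom))

    offsets = [151]
    for kind, _ in units:
        offsets.append(offsets[-1] + (3 if kind == "codon" else 1))

    def windows_ok(buf: str, upto_c: int) -> bool:
        # check all constrained windows fully contained in [151, upto_c]
        for s in NOSTOP_STARTS | STOP_STARTS:
            if s < 151 or s + 2 > upto_c:
                continue
            w = buf[s - 151 : s - 148]
            if s in STOP_STARTS:
                if len(w) == 3 and w not in STOPS:
                    return False
            elif w in STOPS:
                return False
        return True

    order = [list(RNG.permutation(len(dom))) for _, dom in units]

    def backtrack(k: int, buf: str) -> str | None:
        if k == len(units):
            return buf
        kind, dom = units[k]
        for j in order[k]:
            cand = buf + dom[j]
            if windows_ok(cand, offsets[k + 1] - 1):
                res = backtrack(k + 1, cand)
                if res is not None:
                    return res
        return None

    tail = backtrack(0, "")
    if tail is None:
        raise RuntimeError("no sequence satisfies the frame constraints")
    return head + tail  # c.1 .. c.598 in transcript space


def build_exon1b() -> str:
    """p14ARF exon 1beta coding part, c.1-193 (codon 54 = CGC for p.R54H)."""
    codons = ["ATG"]
    for i in range(2, 65):
        if i == 54:
            codons.append("CGC")
        else:
            codons.append(rng_choice(SYN[rng_choice(AA20)]))
    return "".join(codons) + "C"  # c.193 = first base of junction codon 65


def build_p12_extension() -> str:
    """p12 coding read-through into intron 1: p12 c.151-249 (99 nt).

    Starts with the canonical GT donor (p12 codon 51 = GTx), carries the
    G52V / G63R / R67W anchors, ends at the p12 stop (c.247-249).
    """
    fixed = {51: None, 52: None, 63: None, 67: "AGG", 83: "TGA"}
    codons = []
    for i in range(51, 84):
        if i == 51:
            codons.append("GT" + rng_choice("ACGT"))
        elif i in (52, 63):
            codons.append("GG" + rng_choice("ACGT"))
        elif i == 67:
            codons.append("AGG")
        elif i == 83:
            codons.append("TGA")
        else:
            codons.append(rng_choice(SYN[rng_choice(AA20)]))
    ext = "".join(codons)
    assert len(ext) == 99
    assert "*" not in translate_cds(ext[:-3])
    return ext


def build_exon2gamma(c457_base: str) -> str:
    """p16gamma private exon (200 nt, gamma c.458-657).

    Codon 153 completes across the junction (G + 'AC'); R165S / H166Y anchors
    at gamma c.493-498; the 0-shift frame read by p.D146Gfs*19 must hit its
    first stop at gamma c.489-491 (shared stop with the p16 path is at the
    same c. position by construction of the two exon sequences).
    """
    assert c457_base == "G"
    fixed_bases = {489: "T", 490: "G", 491: "A"}
    for attempt in range(10000):
        parts = {458: "A", 459: "C"}  # codon 153 = GAC
        # codons 154..168 at gamma c.460..504
        seq = {}
        c = 460
        for i in range(154, 169):
            if i == 165:
                codon = "AGG"
            elif i == 166:
                codon = "CAC"
            elif i == 163:
                codon = rng_choice([x for x in SYN[rng_choice(AA20)] if x[2] == "T"] or ["GGT"])
            elif i == 164:
                codon = rng_choice(["GAT", "GAC", "GAA", "GAG"])
            else:
                codon = rng_choice(SYN[rng_choice(AA20)])
            for k, b in enumerate(codon):
                seq[c + k] = b
            c += 3
        # stop codon 169 at gamma c.505-507
        for k, b in enumerate("TGA"):
            seq[505 + k] = b
        for pos, b in fixed_bases.items():
            if seq.get(pos, b) != b:
                break
            seq[pos] = b
        else:
            # 3'UTR gamma c.508-657
            for pos in range(508, 658):
                seq[pos] = rng_choice("ACGT")
            seq.update(parts)
            s = "".join(seq[p] for p in range(458, 658))
            # frame windows: no stop at gamma starts 459..486, stop at 489
            ok = True
            full = c457_base + s  # c.457 onward, contiguous in gamma transcript
            for st in range(459, 487, 3):
                if full[st - 457 : st - 454] in STOPS:
                    ok = False
            if full[489 - 457 : 492 - 457] not in STOPS:
                ok = False
            # gamma ORF itself must be stop-free through codon 168
            if "*" in translate_cds(s[2:47 * 3 - 141] if False else s[2 : 2 + 45]):
                ok = False
            if ok:
                return s
    raise RuntimeError("could not satisfy p16gamma constraints")


def random_cds(n_aa: int, fixed: dict[int, str]) -> str:
    """Random CDS of n_aa residues + stop, with pinned codons."""
    codons = ["ATG"]
    for i in range(2, n_aa + 1):
        codons.append(fixed.get(i) or rng_choice(SYN[rng_choice(AA20)]))
    for i, c in fixed.items():
        codons[i - 1] = c
    codons.append("TGA")
    return "".join(codons)


# ---------------------------------------------------------------------------
# CDKN2A assembly
# ---------------------------------------------------------------------------

G_MIN, G_MAX = 21968050, 21994450

EXON1B = (21994138, 21994430)
EXON1A = (21974677, 21974876)
P12_EXON = (21974545, 21974876)
EXON2 = (21970901, 21971207)
EXON2G = (21968571, 21968770)
EXON3 = (21968101, 21968241)

C1_P16 = 21974826   # genomic position of p16 c.1
C151_P16 = 21971207  # genomic position of p16 c.151 (exon 2 first base)
C458_P16 = 21968241  # genomic position of p16 c.458 (exon 3 first base)
C1_P14 = 21994330   # genomic position of p14 c.1


def assemble_cdkn2a() -> tuple[str, dict]:
    coding = {}  # genomic pos -> coding-strand base

    def put(g_hi: int, seq: str):
        """Place a coding-strand (5'->3') string whose first base sits at
        genomic position g_hi, descending (minus-strand gene)."""
        for i, b in enumerate(seq):
            g = g_hi - i
            if coding.get(g, b) != b:
                raise RuntimeError(f"conflicting base at {g}")
            coding[g] = b

    p16 = build_p16_with_frames()  # c.1-598 transcript space
    cds471 = p16[:471]
    utr3 = p16[471:]

    # 5'UTR of exon 1alpha (c.-50 .. c.-1), with the c.-31 / c.-19 anchors
    utr5 = list(random_bases(50))
    utr5[50 - 31] = "G"  # c.-31
    utr5[50 - 19] = "G"  # c.-19
    put(21974876, "".join(utr5))
    put(C1_P16, cds471[:150])           # exon 1alpha CDS
    put(C151_P16, cds471[150:457])      # exon 2
    put(C458_P16, cds471[457:] + utr3)  # exon 3 CDS tail + 3'UTR

    # p12 read-through (intron-1 donor GT is p12 codon 51) + p12 3'UTR
    put(21974676, build_p12_extension())
    put(21974577, random_bases(33))

    # exon 1beta: 100 nt 5'UTR + 193 nt CDS, donor GT after it
    put(21994430, random_bases(100))
    put(C1_P14, build_exon1b())
    put(21994137, "GT")

    # exon 2gamma with its acceptor/donor
    put(21968772, "AG"[::-1])  # acceptor AG = positions 21968772 (A), 21968771 (G)
    coding[21968772], coding[21968771] = "A", "G"
    put(21968770, build_exon2gamma(cds471[456]))
    put(21968570, "GT")

    # shared intron boundaries
    put(21971209, "AG")
    coding[21971209], coding[21971208] = "A", "G"
    put(21970900, "GT")
    put(21968243, "AG")
    coding[21968243], coding[21968242] = "A", "G"

    # deep-intronic anchor c.458-105
    coding[21968346] = "A"

    # fill the rest
    for g in range(G_MIN, G_MAX + 1):
        if g not in coding:
            coding[g] = rng_choice("ACGT")

    coding_str = "".join(coding[g] for g in range(G_MAX, G_MIN - 1, -1))
    plus = reverse_complement(coding_str)

    model = {
        "symbol": "CDKN2A",
        "chrom": "chr9",
        "strand": "-",
        "sequence_offset": G_MIN,
        "isoforms": [
            {"name": "p16", "exons": [list(EXON1A), list(EXON2), list(EXON3)],
             "cds_start": 51, "cds_end": 521},
            {"name": "p12", "exons": [list(P12_EXON)],
             "cds_start": 51, "cds_end": 299},
            {"name": "p16γ",
             "exons": [list(EXON1A), list(EXON2), list(EXON2G), list(EXON3)],
             "cds_start": 51, "cds_end": 557},
            {"name": "p14", "exons": [list(EXON1B), list(EXON2), list(EXON3)],
             "cds_start": 101, "cds_end": 499},
        ],
    }
    return plus, model


# ---------------------------------------------------------------------------
# other panel genes (synthetic single-exon models)
# ---------------------------------------------------------------------------


def assemble_simple_gene(symbol, chrom, strand, offset, span, utr5, n_aa, fixed):
    cds = random_cds(n_aa, fixed)
    total = span
    utr3 = total - utr5 - len(cds)
    assert utr3 > 0
    coding = random_bases(utr5) + cds + random_bases(utr3)
    plus = coding if strand == "+" else reverse_complement(coding)
    lo = offset
    hi = offset + total - 1
    model = {
        "symbol": symbol,
        "chrom": chrom,
        "strand": strand,
        "sequence_offset": lo,
        "isoforms": [
            {"name": f"{symbol}-201", "exons": [[lo, hi]],
             "cds_start": utr5 + 1, "cds_end": utr5 + len(cds)}
        ],
    }
    return plus, model


# ---------------------------------------------------------------------------
# curated variant table (the packaged report-table fixture)
# ---------------------------------------------------------------------------

# columns: variant(list printed, normalized), genomic printed, curated coding
# anchor, ref, alt, impact printed, carriers, class, modelling labels, flags
TABLE3 = [
    ("p14:c.161G>A (p.R54H)", "chr9:21994170", 21994170, "G", "A",
     "missense", 2, "VUS-3B", "-", "-", "-", "n.a.", ""),
    ("p14:c.193+1G>A", "chr9:21994136", 21994137, "G", "A",
     "Splicing", 7, "P", "", "", "", "", "pos_discrepant"),
    ("p16:c.-31G>C", "chr9:21974857", 21974857, "G", "C",
     "5′UTR", 1, "VUS", "", "", "", "", ""),
    ("p16:c.-19G>C", "chr9:21974845", 21974845, "G", "C",
     "5′UTR", 1, "VUS", "", "", "", "", ""),
    ("p16,p12,p16γ:c.51C>T (p.A17A)", "chr9:21974776", 21974776, "C", "T",
     "silent", 1, "VUS", "", "", "", "", ""),
    ("p16,p12,p16γ:c.52_57delACGGCC (p.T18_A19del)", "chr9:21974770_21974775",
     21974775, "ACGGCC", "", "in frame deletion", 2, "LP", "", "", "", "", ""),
    ("p16,p12,p16γ:c.71G>C (p.R24P)", "chr9:21974756", 21974756, "G", "C",
     "missense", 17, "LP", "Hd", "Hd", "Hd", "-", ""),
    ("p16,p12,p16γ:c.79G>T (p.E27X)", "chr9:21974748", 21974748, "G", "T",
     "truncating", 1, "P", "", "", "", "", ""),
    ("p16,p12,p16γ:c.132delC (p.Y44X)", "chr9:21974695", 21974695, "C", "",
     "truncating", 1, "P", "", "", "", "", ""),
    ("p16,p12,p16γ:c.142C>A (p.P48T)", "chr9:21974685", 21974685, "C", "A",
     "missense", 3, "LP", "Hd", "Hd", "Hd", "-", ""),
    ("p16,p16γ:c.150+5G>T; p12:c.155G>T (p.G52V)", "chr9:21974672",
     21974672, "G", "T", "splicing/missense", 1, "VUS", "-", "-", "Hd", "-", ""),
    ("p16,p16γ:c.150+37G>C; p12:c.187G>C (p.G63R)", "chr9:21974640",
     21974640, "G", "C", "splicing/missense", 3, "VUS", "-", "-", "Hd", "-", ""),
    ("p16,p16γ:c.150+49A>T; p12:c.199A>T (p.R67W)", "chr9:21974628",
     21974628, "A", "T", "splicing/missense", 1, "VUS", "-", "-", "Sd", "-", ""),
    ("p16,p16γ:c.167G>T (p.S56I); p14:c.210G>T (p.Q70H)", "chr9:21971191",
     21971191, "G", "T", "missense", 3, "LP", "D", "Ss", "-", "n.a.", ""),
    ("p16,p16γ:c.176T>G (p.V59G); p14:c.219T>G (p.S73R)", "chr9:21971182",
     21971182, "T", "G", "missense", 4, "LP", "Hd", "Hd", "-", "n.a.", ""),
    ("p16,p16γ:c.191_194dupTGCT (p.H66Afs*55); p14:c.234_237dupTGCT (p.P80Cfs*82)",
     "chr9:21971164_21971167", 21971164, "", "TGCT",
     "truncating", 1, "P", "", "", "", "", ""),
    ("p16,p16γ:c.199G>C (p.G67R); p14:c.242G>C (p.R81P)", "chr9:21971159",
     21971159, "G", "C", "missense", 3, "VUS-3B", "Hd", "Hd", "-", "n.a.", ""),
    ("p16,p16γ:c.201delC (p.A68Rfs*78); p14:c.244delC (p.R82Afs*90)",
     "chr9:21971157", 21971157, "C", "",
     "truncating", 1, "P", "", "", "", "", ""),
    ("p16,p16γ:c.202_203delGCinsCT (p.A68L); p14:c.245_246delGCinsCT (p.R82P)",
     "chr9:21971154", 21971156, "GC", "CT",
     "missense", 2, "VUS-3B", "Hd", "Hd", "-", "n.a.",
     "pos_discrepant,alt_discrepant"),
    ("p16,p16γ:c.212A>G (p.N71S); p14:c.255A>G (p.Q85Q)", "chr9:21971146",
     21971146, "A", "G", "missense", 11, "LP", "Sd", "Hd", "-", "n.a.", ""),
    ("p16,p16γ:c.212A>T (p.N71I); p14:c.255A>T (p.Q85H)", "chr9:21971146",
     21971146, "A", "T", "missense", 5, "LP", "Ss", "Ss", "-", "n.a.",
     "alt_discrepant,excluded"),
    ("p16,p16γ:c.249C>A (p.H83Q); p14:c.292C>A (p.R98R)", "chr9:21971109",
     21971109, "C", "A", "missense", 2, "VUS-3B", "D", "Hd", "-", "n.a.", ""),
    ("p16,p16γ:c.301G>T (p.G101W); p14:c.344G>T (p.R115L)", "chr9:21971057",
     21971057, "G", "T", "missense", 16, "LP", "Hd", "Hd", "-", "n.a.", ""),
    ("p16,p16γ:c.340C>T (p.P114S); p14:c.383C>T (p.A128V)", "chr9:21971018",
     21971018, "C", "T", "missense", 1, "LP", "Hd", "Hd", "-", "-", ""),
    ("p16,p16γ:c.377T>A (p.V126D)", "chr9:21970981", 21970981, "T", "A",
     "missense", 1, "LP", "Hd", "Hd", "-", "-", ""),
    ("p16,p16γ:c.425A>G (p.H142R)", "chr9:21970933", 21970933, "A", "G",
     "missense", 1, "VUS-3B", "Sd", "N", "-", "-", ""),
    ("p16,p16γ:c.430C>T (p.R144C)", "chr9:21970928", 21970928, "C", "T",
     "missense", 1, "VUS", "Sd", "N", "-", "-", ""),
    ("p16,p16γ:c.436_437insG (p.D146Gfs*19)", "chr9:21970922", 21970922,
     "", "G", "truncating", 1, "LP", "", "", "", "", ""),
    ("p16γ:c.496C>T (p.H166Y)", "chr9:21968732", 21968732, "C", "T",
     "missense", 1, "VUS", "-", "Ss", "-", "-", ""),
    ("p16:c.458-105A>G (p.156_157del)", "chr9:21968346", 21968346, "A", "G",
     "in frame deletion", 2, "VUS-3B", "", "", "", "", "excluded"),
    ("p16γ:c.495G>C (p.R165S)", "chr9:21968733", 21968733, "G", "C",
     "missense", 1, "VUS", "-", "D", "-", "-", ""),
    ("p16:c.*31G>A", "chr9:21968197", 21968197, "G", "A",
     "3′UTR", 1, "VUS", "", "", "", "", ""),
    ("p16:c.*42C>A", "chr9:21968186", 21968186, "C", "A",
     "3′UTR", 1, "VUS", "", "", "", "", ""),
]


def verify_cdkn2a(model) -> None:
    anchors = [  # (isoform, genomic, expected c.)
        ("p16", 21974756, "71"), ("p16", 21974857, "-31"),
        ("p16", 21968197, "*31"), ("p16", 21968186, "*42"),
        ("p16", 21974672, "150+5"), ("p12", 21974672, "155"),
        ("p16", 21974640, "150+37"), ("p12", 21974640, "187"),
        ("p16", 21974628, "150+49"), ("p12", 21974628, "199"),
        ("p16", 21971146, "212"), ("p14", 21971146, "255"),
        ("p16", 21971057, "301"), ("p14", 21994170, "161"),
        ("p14", 21994137, "193+1"), ("p16", 21968346, "458-105"),
        ("p16γ", 21968733, "495"), ("p16γ", 21968732, "496"),
    ]
    from melpanel.transcript import project_genomic_to_cds

    for iso_name, g, expect in anchors:
        iso = model.isoform(iso_name)
        got = str(project_genomic_to_cds(iso, GenomicPosition("chr9", g)))
        assert got == expect, f"{iso_name} {g}: got c.{got}, want c.{expect}"

    # proteins
    locus = model.reference
    p16 = model.isoform("p16").cds_sequence(locus)
    assert translate_cds(p16, to_stop=True) == P16_AA
    p14 = model.isoform("p14").cds_sequence(locus)
    aa14 = translate_cds(p14)
    assert aa14.endswith("*") and "*" not in aa14[:-1] and len(aa14) == 133
    p12 = model.isoform("p12").cds_sequence(locus)
    aa12 = translate_cds(p12)
    assert aa12.endswith("*") and "*" not in aa12[:-1]
    assert aa12[:50] == P16_AA[:50]
    pg = model.isoform("p16γ").cds_sequence(locus)
    aag = translate_cds(pg)
    assert aag.endswith("*") and "*" not in aag[:-1]
    assert aag[:152] == P16_AA[:152]

    # every recomputable table row must reproduce exactly
    bad = []
    for row in TABLE3:
        (variant, _gp, pos, ref, alt, impact, *_rest) = row
        flags = row[-1]
        if "excluded" in flags:
            continue
        v = VariantRecord("CDKN2A", GenomicPosition("chr9", pos), ref, alt)
        cons = annotate_variant(model, v)
        rendered = render_variant_string(cons)
        label = combined_impact(cons).label
        if rendered != variant or label.lower() != impact.lower():
            bad.append((variant, rendered, impact, label))
    if bad:
        for b in bad:
            print("MISMATCH:", *b, sep="\n  ")
        raise RuntimeError(f"{len(bad)} table rows failed to reproduce")
    print(f"CDKN2A verified: {len(TABLE3)} rows "
          f"({sum('excluded' in r[-1] for r in TABLE3)} excluded passthroughs)")


def verify_others(models, loci) -> None:
    cdk4 = models["CDK4"]
    tests = [
        ("CDK4", 58145370, "G", "A", "c.71G>A", "p.R24H", "missense"),
        ("CDK4", 58145370, "G", "T", "c.71G>T", "p.R24L", "missense"),
        ("CDK4", 58145309, "AGG", "", "c.132_134delAGG", "p.G48del",
         "in frame deletion"),
        ("MITF", 69789001, "G", "A", "c.952G>A", "p.E318K", "missense"),
    ]
    for gene, pos, ref, alt, hc, hp, cat in tests:
        m = models[gene]
        v = VariantRecord(gene, GenomicPosition(m.chrom, pos), ref, alt)
        (c,) = annotate_variant(m, v)
        assert c.hgvs_c == hc, (gene, c.hgvs_c, hc)
        assert c.hgvs_p == hp, (gene, c.hgvs_p, hp)
        assert str(c.category) == cat
    print("CDK4 / MITF anchors verified")


def write_fasta(path: Path, records: list[tuple[str, str, str]]):
    with open(path, "w") as fh:
        for name, desc, seq in records:
            fh.write(f">{name} {desc}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def main():
    DATA.mkdir(parents=True, exist_ok=True)

    plus, cdkn2a_doc = assemble_cdkn2a()
    gene_docs = {"CDKN2A": cdkn2a_doc}
    seqs = {"CDKN2A": plus}

    others = [
        ("CDK4", "chr12", "-", 58145000, 501, 60, 100,
         {24: "CGC", 44: "GCA", 45: "GGT", 46: "GGC", 47: "GGT", 48: "GGC",
          49: "CTG"}),
        ("MITF", "chr3", "+", 69788000, 1201, 50, 319, {318: "GAA"}),
        ("BAP1", "chr3", "-", 52435000, 601, 50, 100, {}),
        ("POT1", "chr7", "-", 124462000, 601, 50, 100, {}),
    ]
    for symbol, chrom, strand, offset, span, utr5, n_aa, fixed in others:
        seq, doc = assemble_simple_gene(
            symbol, chrom, strand, offset, span, utr5, n_aa, fixed
        )
        gene_docs[symbol] = doc
        seqs[symbol] = seq

    # load through the package and verify before freezing anything
    models = {}
    for symbol, doc in gene_docs.items():
        locus = LocusSequence(seqs[symbol], doc["sequence_offset"], doc["chrom"])
        models[symbol] = load_gene_model(doc, locus=locus)
    verify_cdkn2a(models["CDKN2A"])
    verify_others(models, seqs)

    # ---- write data files ----
    import yaml

    fasta_records = [
        (s, f"offset={gene_docs[s]['sequence_offset']} chrom={gene_docs[s]['chrom']} "
            "synthetic anchor-consistent locus", seqs[s])
        for s in ["CDKN2A", "CDK4", "MITF", "BAP1", "POT1"]
    ]
    write_fasta(DATA / "panel_loci.fasta", fasta_records)
    for symbol, doc in gene_docs.items():
        with open(DATA / f"{symbol.lower()}_model.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, allow_unicode=True, sort_keys=False)

    header = [
        "variant", "genomic_printed", "pos", "ref", "alt", "impact",
        "carriers", "acmg_class", "mm_p16", "mm_p16g", "mm_p12", "mm_p14",
        "flags",
    ]
    with open(DATA / "table3_variants.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in TABLE3:
            fh.write("\t".join(str(x) for x in row) + "\n")

    with open(DATA / "strata_counts.tsv", "w") as fh:
        fh.write("category\tpanel\ttested\tpositive\n")
        for cat, panel, n, k in [
            ("low", "Sanger-Test", 418, 13),
            ("low", "NGS-Test", 120, 23),
            ("high", "Sanger-Test", 268, 67),
            ("high", "NGS-Test", 82, 25),
        ]:
            fh.write(f"{cat}\t{panel}\t{n}\t{k}\n")

    with open(DATA / "gene_positive_counts.tsv", "w") as fh:
        fh.write("gene\tpositive_patients\n")
        for g, n in [("CDKN2A", 98), ("MITF", 10), ("CDK4", 9), ("BAP1", 9),
                     ("POT1", 2)]:
            fh.write(f"{g}\t{n}\n")

    with open(DATA / "table2_cohort.tsv", "w") as fh:
        fh.write("section\tfield\tlow\thigh\n")
        rows = [
            ("referred", "patients", 538, 350),
            ("referred", "males", 254, 180),
            ("referred", "females", 284, 170),
            ("referred", "onset_age_mean", 47, 47),
            ("referred", "onset_age_sd", 14, 15),
            ("referred", "other_cancer", 50, 48),
            ("carriers", "patients", 36, 92),
            ("carriers", "males", 11, 42),
            ("carriers", "females", 25, 50),
            ("carriers", "onset_age_mean", 44, 41),
            ("carriers", "onset_age_sd", 13, 14),
            ("carriers", "other_cancer", 2, 9),
        ]
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")

    with open(DATA / "primers.tsv", "w") as fh:
        fh.write("amplicon\tforward\treverse\n")
        for r in [
            ("CDKN2A exon 1α", "CACCAGAGGGTGGGGCGGA", "CAGGGCGTCGCCAGGAGGA"),
            ("CDKN2A exon 1β", "TCCCAGTCTGCAGTTAAGG", "CGGGTTTACAACGACTTAGAC"),
            ("CDKN2A exon 2", "GGCGGTGAGGGGGCTCTACA", "ACCGATTGGCGCGTGAGCTG"),
            ("CDKN2A exon 3", "GCCGGTAGGGACGGCAAGAG", "AAAGCGGGGTGGGTTGTGGC"),
            ("CDK4 codon24 (exon2)", "GGATGCTGGTGGTGTTCTTT",
             "TTATTTCCTCAGGGTCCCCA"),
        ]:
            fh.write("\t".join(r) + "\n")

    # checksums over everything except the checksum file itself
    sums = {}
    for p in sorted(DATA.iterdir()):
        if p.name in {"checksums.json"} or p.is_dir():
            continue
        sums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(DATA / "checksums.json", "w") as fh:
        json.dump(sums, fh, indent=1, sort_keys=True)

    total = sum(p.stat().st_size for p in DATA.iterdir() if p.is_file())
    print(f"wrote {len(sums) + 1} data files, {total / 1024:.1f} KiB total")


if __name__ == "__main__":
    main()
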