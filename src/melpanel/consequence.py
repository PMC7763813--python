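"""Per-isoform variant consequence calling and HGVS-style naming.

Given a gene model with an attached locus sequence, each variant is projected
into every isoform that contains it and classified as UTR / silent / missense
/ truncating / in-frame deletion / splicing / intronic.  Protein changes are
computed by editing the coding sequence and re-translating (frameshifts read
through into the 3'UTR until the first stop), which is what makes the calls
correct on overlapping reading frames: the same genomic substitution can be
missense in p16INK4a and silent in p14ARF.

Naming style follows the clinical-report conventions of the source data:
one-letter amino-acid codes, nonsense as ``p.E27X``, frameshifts as
``p.H66Afs*55``, and indels 3'-normalized (HGVS shifting rule) before naming.
Duplications are written ``dup`` for units of two or more bases; single-base
insertions are written ``ins``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .transcript import (
    CdsCoordinate,
    GeneModel,
    GenomicPosition,
    Isoform,
    LocusSequence,
    OutOfTranscriptError,
    translate_cds,
)

__all__ = [
    "Category",
    "VariantRecord",
    "IsoformConsequence",
    "CombinedImpact",
    "CdsEdit",
    "annotate_variant",
    "protein_change",
    "combined_impact",
    "render_variant_string",
    "NoOverlapError",
    "ReferenceMismatchError",
    "UnsupportedEditError",
]

# splice-window defaults: |offset| <= CORE is always "splicing"; offsets up to
# EXTENDED are "splicing" only when the same genomic position is exonic in a
# sibling isoform (a change that is intronic for one frame but coding for
# another is plausibly splice-relevant and is reported as such in the source
# data at +5/+37/+49).
SPLICE_CORE_WINDOW = 2
SPLICE_EXTENDED_WINDOW = 50

_ACGT = re.compile(r"^[ACGT]*$")


class NoOverlapError(ValueError):
    """Variant lies outside every isoform of the gene model."""


class ReferenceMismatchError(ValueError):
    """Declared reference allele disagrees with the locus sequence."""


class UnsupportedEditError(ValueError):
    """Edit spans a splice junction or otherwise cannot be named."""


class Category(str, Enum):
    TRUNCATING = "truncating"
    SPLICING = "splicing"
    MISSENSE = "missense"
    INFRAME_DELETION = "in frame deletion"
    INFRAME_INSERTION = "in frame insertion"
    SILENT = "silent"
    FIVE_UTR = "5′UTR"
    THREE_UTR = "3′UTR"
    INTRONIC = "intronic"

    def __str__(self) -> str:
        return self.value


#: priority order for combined-impact labels (highest first)
_PRIORITY = [
    Category.TRUNCATING,
    Category.SPLICING,
    Category.MISSENSE,
    Category.INFRAME_DELETION,
    Category.INFRAME_INSERTION,
    Category.SILENT,
    Category.FIVE_UTR,
    Category.THREE_UTR,
    Category.INTRONIC,
]
#: categories that describe an effect on the protein or on splicing
_CODING_TIER = set(_PRIORITY[:5])


@dataclass(frozen=True)
class VariantRecord:
    """A genomic change with coding-strand alleles.

    ``position`` anchors the variant on the genome: for substitutions and
    deletions it is the genomic coordinate of the *first coding-strand base*
    of ``ref`` (on minus-strand genes this is the highest genomic coordinate
    of the affected range); for insertions it is the coding-strand base
    immediately 5' of the insertion point.  ``ref``/``alt`` are coding-strand
    allele strings; an empty ``alt`` denotes a deletion and an empty ``ref``
    an insertion.
    """

    gene: str
    position: GenomicPosition
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.id or self.position}: ref equals alt")
        for allele in (self.ref, self.alt):
            if not _ACGT.match(allele):
                raise ValueError(
                    f"{self.id or self.position}: allele {allele!r} not over ACGT"
                )
        if not self.ref and not self.alt:
            raise ValueError("ref and alt both empty")

    @property
    def kind(self) -> str:
        if self.ref and self.alt:
            return "snv" if len(self.ref) == len(self.alt) == 1 else "mnv"
        return "del" if self.ref else "ins"


@dataclass(frozen=True)
class IsoformConsequence:
    isoform: str
    region: str  # 5'UTR | 3'UTR | CDS | intronic | splice-window
    category: Category
    hgvs_c: str
    hgvs_p: str = ""


@dataclass(frozen=True)
class CombinedImpact:
    label: str
    categories: tuple[Category, ...]

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class CdsEdit:
    """An edit expressed in CDS coordinates of one isoform.

    ``start`` is the 1-based CDS position of the first reference base
    (for insertions: the base 5' of the insertion point).
    """

    start: int
    ref: str
    alt: str


# ---------------------------------------------------------------------------
# protein-level naming helpers
# ---------------------------------------------------------------------------


def _aa_change_snv(ref_aa: str, pos: int, mut_aa: str, nonsense_style: str) -> tuple[Category, str]:
    if mut_aa == ref_aa:
        return Category.SILENT, f"p.{ref_aa}{pos}{ref_aa}"
    if mut_aa == "*":
        stop = "X" if nonsense_style == "X" else "Ter"
        return Category.TRUNCATING, f"p.{ref_aa}{pos}{stop}"
    return Category.MISSENSE, f"p.{ref_aa}{pos}{mut_aa}"


def _name_protein_deletion(ref_p: str, mut_p: str) -> str:
    """Name an in-frame protein deletion, 3'-shifted at the protein level.

    The longest-common-prefix alignment of reference and mutant proteins
    places the deleted run at its most C-terminal possible position, which
    is the HGVS convention (e.g. removing one glycine codon from a Gly run
    spanning residues 45-48 is named at residue 48).
    """
    k = len(ref_p) - len(mut_p)
    a = 0
    while a < len(mut_p) and ref_p[a] == mut_p[a]:
        a += 1
    if ref_p[a + k :] != mut_p[a:]:
        # deletion also substituted the flanking residue: delins naming
        b = 0
        while b < len(mut_p) - a and ref_p[-1 - b] == mut_p[-1 - b]:
            b += 1
        ref_seg = ref_p[a : len(ref_p) - b]
        mut_seg = mut_p[a : len(mut_p) - b]
        start, end = a + 1, len(ref_p) - b
        return (
            f"p.{ref_p[a]}{start}_{ref_p[end - 1]}{end}delins{mut_seg}"
            if mut_seg
            else f"p.{ref_p[a]}{start}_{ref_p[end - 1]}{end}del"
        )
    first, last = a + 1, a + k
    if k == 1:
        return f"p.{ref_p[a]}{first}del"
    return f"p.{ref_p[a]}{first}_{ref_p[a + k - 1]}{last}del"


def _name_protein_insertion(ref_p: str, mut_p: str) -> str:
    k = len(mut_p) - len(ref_p)
    a = 0
    while a < len(ref_p) and ref_p[a] == mut_p[a]:
        a += 1
    inserted = mut_p[a : a + k]
    if ref_p[a:] != mut_p[a + k :]:
        return f"p.{ref_p[a]}{a + 1}delins{mut_p[a : a + k + 1]}"
    if a == 0:
        return f"p.ins{inserted}"
    left, right = a, a + 1
    return f"p.{ref_p[left - 1]}{left}_{ref_p[right - 1] if right <= len(ref_p) else '?'}{right}ins{inserted}"


# ---------------------------------------------------------------------------
# core CDS-edit engine
# ---------------------------------------------------------------------------


def _normalize_indel_3prime(tseq: str, t0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Shift a pure insertion or deletion to its 3'-most equivalent position.

    ``t0`` is the 0-based transcript index of the first deleted base, or of
    the base 5' of the insertion point.  Returns the shifted (t0, ref, alt).
    """
    if ref and not alt:  # deletion
        L = len(ref)
        while t0 + L < len(tseq) and tseq[t0] == tseq[t0 + L]:
            t0 += 1
        return t0, tseq[t0 : t0 + L], alt
    if alt and not ref:  # insertion
        ins = alt
        while t0 + 1 < len(tseq) and ins[0] == tseq[t0 + 1]:
            ins = ins[1:] + ins[0]
            t0 += 1
        return t0, ref, ins
    return t0, ref, alt


def _cds_positions_str(iso: Isoform, t_first: int, t_last: int) -> tuple[str, str]:
    c1 = iso.transcript_to_cds(t_first + 1)
    c2 = iso.transcript_to_cds(t_last + 1)
    return str(c1), str(c2)


def _consequence_for_cds_edit(
    iso: Isoform,
    locus: LocusSequence,
    t0: int,
    ref: str,
    alt: str,
    nonsense_style: str = "X",
) -> tuple[Category, str, str]:
    """Classify and name an exonic edit (0-based transcript index ``t0``)."""
    tseq = iso.transcript_sequence(locus)
    # region is decided on the edit as given; the HGVS 3' shifting rule is
    # applied afterwards for naming only (a repeat deletion straddling the
    # UTR/CDS boundary must not be reclassified by its shifted name)
    orig_first_c = iso.transcript_to_cds(t0 + 1)
    if ref:
        orig_in_cds = (
            orig_first_c.in_cds or iso.transcript_to_cds(t0 + len(ref)).in_cds
        )
    else:
        cs0, ce0 = iso.cds_start - 1, iso.cds_end
        orig_in_cds = cs0 <= t0 < ce0 - 1
    t0, ref, alt = _normalize_indel_3prime(tseq, t0, ref, alt)

    # hgvs_c -----------------------------------------------------------------
    if ref and alt and len(ref) == len(alt) == 1:
        c = str(iso.transcript_to_cds(t0 + 1))
        hgvs_c = f"c.{c}{ref}>{alt}"
    elif ref and alt:
        c1, c2 = _cds_positions_str(iso, t0, t0 + len(ref) - 1)
        hgvs_c = f"c.{c1}_{c2}del{ref}ins{alt}"
    elif ref:  # deletion
        if len(ref) == 1:
            c = str(iso.transcript_to_cds(t0 + 1))
            hgvs_c = f"c.{c}del{ref}"
        else:
            c1, c2 = _cds_positions_str(iso, t0, t0 + len(ref) - 1)
            hgvs_c = f"c.{c1}_{c2}del{ref}"
    else:  # insertion
        L = len(alt)
        if L >= 2 and t0 - L + 1 >= 0 and tseq[t0 - L + 1 : t0 + 1] == alt:
            c1, c2 = _cds_positions_str(iso, t0 - L + 1, t0)
            hgvs_c = f"c.{c1}_{c2}dup{alt}"
        else:
            c1, c2 = _cds_positions_str(iso, t0, t0 + 1)
            hgvs_c = f"c.{c1}_{c2}ins{alt}"

    # outside the CDS there is no protein call -------------------------------
    first_c = iso.transcript_to_cds(t0 + 1)
    if not orig_in_cds:
        cat = (
            Category.FIVE_UTR
            if orig_first_c.base < 0 and not orig_first_c.utr3
            else Category.THREE_UTR
        )
        return cat, hgvs_c, ""

    # protein ----------------------------------------------------------------
    if ref:
        mutant = tseq[:t0] + alt + tseq[t0 + len(ref) :]
    else:
        mutant = tseq[: t0 + 1] + alt + tseq[t0 + 1 :]
    ref_read = tseq[iso.cds_start - 1 :]
    mut_read = mutant[iso.cds_start - 1 :]
    ref_p = translate_cds(ref_read, to_stop=True)
    mut_p = translate_cds(mut_read, to_stop=False)
    mut_full = mut_p
    mut_p = mut_p[: mut_full.index("*")] if "*" in mut_full else mut_full

    shift = len(alt) - len(ref)
    if shift % 3 == 0:
        if mut_p == ref_p:
            if len(ref) == len(alt) == 1:
                i = (first_c.base - 1) // 3
                if i >= len(ref_p):  # synonymous change within the stop codon
                    return Category.SILENT, hgvs_c, "p.="
                return Category.SILENT, hgvs_c, f"p.{ref_p[i]}{i + 1}{ref_p[i]}"
            return Category.SILENT, hgvs_c, "p.="
        if len(ref) == len(alt):
            # substitution: locate changed residues
            diffs = [i for i in range(min(len(ref_p), len(mut_p))) if ref_p[i] != mut_p[i]]
            if not diffs and len(mut_p) < len(ref_p):
                i = len(mut_p)
                stop = "X" if nonsense_style == "X" else "Ter"
                return Category.TRUNCATING, hgvs_c, f"p.{ref_p[i]}{i + 1}{stop}"
            if not diffs and len(mut_p) > len(ref_p):
                # stop-loss: translation extends into the 3'UTR
                i = len(ref_p)
                n_extra = len(mut_p) - len(ref_p)
                return (
                    Category.MISSENSE,
                    hgvs_c,
                    f"p.*{i + 1}{mut_p[i]}ext*{n_extra}",
                )
            if len(diffs) == 1 and len(mut_p) == len(ref_p):
                i = diffs[0]
                cat, hgvs_p = _aa_change_snv(ref_p[i], i + 1, mut_p[i], nonsense_style)
                return cat, hgvs_c, hgvs_p
            i, j = diffs[0], diffs[-1]
            return (
                Category.MISSENSE,
                hgvs_c,
                f"p.{ref_p[i]}{i + 1}_{ref_p[j]}{j + 1}delins{mut_p[i : j + 1]}",
            )
        k = abs(shift) // 3
        if shift < 0:
            clean = len(ref_p) - len(mut_p) == k and any(
                ref_p[:a] == mut_p[:a] and ref_p[a + k :] == mut_p[a:]
                for a in range(len(mut_p) + 1)
            )
            if clean:
                return (
                    Category.INFRAME_DELETION,
                    hgvs_c,
                    _name_protein_deletion(ref_p, mut_p),
                )
        else:
            clean = len(mut_p) - len(ref_p) == k and any(
                ref_p[:a] == mut_p[:a] and mut_p[a + k :] == ref_p[a:]
                for a in range(len(ref_p) + 1)
            )
            if clean:
                return (
                    Category.INFRAME_INSERTION,
                    hgvs_c,
                    _name_protein_insertion(ref_p, mut_p),
                )
        # in-frame length change with a flanking substitution or an early stop
        i = 0
        while i < min(len(ref_p), len(mut_p)) and ref_p[i] == mut_p[i]:
            i += 1
        expected_len = len(ref_p) + (k if shift > 0 else -k)
        if i >= len(ref_p):
            # divergence begins at the stop codon: translation extends
            cat = (
                Category.TRUNCATING
                if len(mut_p) < expected_len
                else (
                    Category.INFRAME_DELETION
                    if shift < 0
                    else Category.INFRAME_INSERTION
                )
            )
            n_extra = len(mut_p) - len(ref_p)
            return (
                cat,
                hgvs_c,
                f"p.*{len(ref_p) + 1}{mut_p[i] if i < len(mut_p) else '?'}"
                f"ext*{n_extra}",
            )
        if len(mut_p) < expected_len:  # stop gained
            if i >= len(mut_p):
                stop = "X" if nonsense_style == "X" else "Ter"
                return Category.TRUNCATING, hgvs_c, f"p.{ref_p[i]}{i + 1}{stop}"
            return (
                Category.TRUNCATING,
                hgvs_c,
                f"p.{ref_p[i]}{i + 1}delins{mut_p[i:]}",
            )
        b = 0
        while b < min(len(ref_p), len(mut_p)) - i and ref_p[-1 - b] == mut_p[-1 - b]:
            b += 1
        seg = mut_p[i : len(mut_p) - b]
        cat = Category.INFRAME_DELETION if shift < 0 else Category.INFRAME_INSERTION
        end = min(max(len(ref_p) - b, i + 1), len(ref_p))
        hgvs_p = (
            f"p.{ref_p[i]}{i + 1}_{ref_p[end - 1]}{end}delins{seg}"
            if end > i + 1
            else f"p.{ref_p[i]}{i + 1}delins{seg}"
        )
        return cat, hgvs_c, hgvs_p

    # frameshift -------------------------------------------------------------
    ref_with_stop = ref_p + "*"
    i = 0
    while i < len(mut_full) and i < len(ref_with_stop) and mut_full[i] == ref_with_stop[i]:
        i += 1
    if i == len(ref_with_stop):
        # the shifted read reproduces the whole protein and its stop (repeat
        # indel absorbed at the CDS end): no protein-level change
        return Category.SILENT, hgvs_c, "p.="
    if i >= len(mut_full):
        raise UnsupportedEditError(
            "frameshift runs off the transcript without diverging"
        )
    ref_res = ref_with_stop[i] if i < len(ref_with_stop) else "?"
    if mut_full[i] == "*":
        stop = "X" if nonsense_style == "X" else "Ter"
        return Category.TRUNCATING, hgvs_c, f"p.{ref_res}{i + 1}{stop}"
    stop_idx = mut_full.find("*", i)
    n = f"{stop_idx - i + 1}" if stop_idx != -1 else "?"
    return Category.TRUNCATING, hgvs_c, f"p.{ref_res}{i + 1}{mut_full[i]}fs*{n}"


def protein_change(
    isoform: Isoform,
    edit: CdsEdit,
    locus: LocusSequence,
    nonsense_style: str = "X",
) -> str:
    """Protein HGVS string for an edit given in CDS coordinates.

    Substitutions are named silent/missense/nonsense; frameshifts re-translate
    the mutated coding sequence (through the 3'UTR) to locate the new stop and
    are named ``p.<ref><pos><new>fs*N`` with N counting the changed residue as
    1; in-frame deletions are named at their most C-terminal equivalent
    position.
    """
    if edit.start < 1 or edit.start + max(len(edit.ref), 1) - 1 > isoform.cds_length:
        raise OutOfTranscriptError(
            f"edit at c.{edit.start} outside the CDS of {isoform.name}"
        )
    t0 = isoform.cds_start - 1 + edit.start - 1
    _, _, hgvs_p = _consequence_for_cds_edit(
        isoform, locus, t0, edit.ref, edit.alt, nonsense_style
    )
    return hgvs_p


# ---------------------------------------------------------------------------
# per-isoform annotation
# ---------------------------------------------------------------------------


def _affected_genomic(v: VariantRecord, strand: str) -> list[int]:
    step = 1 if strand == "+" else -1
    n = max(len(v.ref), 1)
    return [v.position.pos + step * i for i in range(n)]


def _check_reference(iso: Isoform, locus: LocusSequence, v: VariantRecord) -> None:
    if not v.ref:
        return
    from .transcript import reverse_complement

    for i, gpos in enumerate(_affected_genomic(v, iso.strand)):
        plus = locus.base(gpos)
        coding = plus if iso.strand == "+" else reverse_complement(plus)
        if coding != v.ref[i]:
            raise ReferenceMismatchError(
                f"{v.id or v.position}: declared ref {v.ref[i]!r} != locus "
                f"{coding!r} at {v.position.chrom}:{gpos} (coding strand)"
            )


def annotate_variant(
    model: GeneModel,
    v: VariantRecord,
    nonsense_style: str = "X",
    splice_core: int = SPLICE_CORE_WINDOW,
    splice_extended: int = SPLICE_EXTENDED_WINDOW,
) -> list[IsoformConsequence]:
    """Annotate ``v`` against every isoform of ``model`` that contains it.

    Returns one :class:`IsoformConsequence` per overlapping isoform, in the
    model's isoform order.  Raises :class:`NoOverlapError` when no isoform
    contains the variant and :class:`ReferenceMismatchError` when the declared
    reference allele disagrees with the locus sequence.
    """
    locus = model.reference
    anchor = v.position.pos
    exonic_in = {iso.name for iso in model.isoforms if iso.is_exonic(anchor)}
    out: list[IsoformConsequence] = []
    for iso in model.isoforms:
        positions = _affected_genomic(v, iso.strand)
        if not any(iso.contains(p) for p in positions):
            continue
        if locus is not None:
            _check_reference(iso, locus, v)
        exonic = [iso.is_exonic(p) for p in positions]
        if all(exonic):
            if locus is None:
                raise ValueError(
                    f"{model.symbol}: locus sequence required for coding calls"
                )
            t0 = iso.genomic_to_transcript(positions[0]) - 1
            cat, hgvs_c, hgvs_p = _consequence_for_cds_edit(
                iso, locus, t0, v.ref, v.alt, nonsense_style
            )
            region = (
                "CDS"
                if cat
                in {
                    Category.SILENT,
                    Category.MISSENSE,
                    Category.TRUNCATING,
                    Category.INFRAME_DELETION,
                    Category.INFRAME_INSERTION,
                }
                else ("5'UTR" if cat is Category.FIVE_UTR else "3'UTR")
            )
            out.append(
                IsoformConsequence(iso.name, region, cat, hgvs_c, hgvs_p)
            )
        elif not any(exonic):
            c = project_genomic_to_cds_checked(iso, v.position)
            k = abs(c.offset)
            if k <= splice_core:
                cat = Category.SPLICING
            elif k <= splice_extended and (exonic_in - {iso.name}):
                cat = Category.SPLICING
            else:
                cat = Category.INTRONIC
            region = "splice-window" if cat is Category.SPLICING else "intronic"
            if v.kind == "snv":
                hgvs_c = f"c.{c}{v.ref}>{v.alt}"
            else:
                c2 = project_genomic_to_cds_checked(
                    iso, GenomicPosition(v.position.chrom, positions[-1])
                )
                if v.kind == "del":
                    body = f"del{v.ref}" if len(v.ref) > 1 else f"del{v.ref}"
                    hgvs_c = (
                        f"c.{c}{body}" if len(v.ref) == 1 else f"c.{c}_{c2}{body}"
                    )
                elif v.kind == "ins":
                    hgvs_c = f"c.{c}_{c2}ins{v.alt}"
                else:
                    hgvs_c = f"c.{c}_{c2}del{v.ref}ins{v.alt}"
            out.append(IsoformConsequence(iso.name, region, cat, hgvs_c, ""))
        else:
            raise UnsupportedEditError(
                f"{v.id or v.position}: edit spans an exon/intron junction of "
                f"{iso.name}"
            )
    if not out:
        raise NoOverlapError(
            f"{v.id or v.position} outside every isoform of {model.symbol}"
        )
    return out


def project_genomic_to_cds_checked(iso: Isoform, g: GenomicPosition) -> CdsCoordinate:
    from .transcript import project_genomic_to_cds

    return project_genomic_to_cds(iso, g)


# ---------------------------------------------------------------------------
# combined impact and report rendering
# ---------------------------------------------------------------------------


def combined_impact(consequences: list[IsoformConsequence]) -> CombinedImpact:
    """Slash-joined distinct categories in priority order.

    Only the strongest tier is reported: protein/splice-level categories
    suppress silent, UTR and intronic calls from other isoforms; silent
    suppresses UTR/intronic; the UTRs suppress intronic.
    """
    if not consequences:
        raise ValueError("combined_impact of empty consequence list")
    cats = {c.category for c in consequences}
    coding = [c for c in _PRIORITY[:5] if c in cats]
    if coding:
        chosen = coding
    elif Category.SILENT in cats:
        chosen = [Category.SILENT]
    else:
        utr = [c for c in (Category.FIVE_UTR, Category.THREE_UTR) if c in cats]
        chosen = utr if utr else [Category.INTRONIC]
    return CombinedImpact("/".join(str(c) for c in chosen), tuple(chosen))


#: isoform display order used by the aggregate variant table
_DISPLAY_ORDER = ["p16", "p12", "p16γ", "p14"]


def render_variant_string(
    consequences: list[IsoformConsequence],
    isoform_order: list[str] | None = None,
) -> str:
    """Render the grouped multi-isoform variant string of the report table.

    Isoforms with identical (hgvs_c, hgvs_p) are grouped (``p16,p16γ:c.212A>G
    (p.N71S)``); groups are joined by ``"; "``.  Consequences in the coding/
    splicing tier (plus silent) are shown; UTR or intronic consequences are
    shown only when no isoform has a stronger call, and then only for the
    first isoform in display order (the canonical transcript).
    """
    order = isoform_order or _DISPLAY_ORDER

    def sort_key(c: IsoformConsequence):
        return order.index(c.isoform) if c.isoform in order else len(order)

    strong = [
        c
        for c in consequences
        if c.category in _CODING_TIER or c.category is Category.SILENT
    ]
    if strong:
        shown = sorted(strong, key=sort_key)
    else:
        shown = [min(consequences, key=sort_key)]
    groups: list[tuple[tuple[str, str], list[str]]] = []
    for c in shown:
        key = (c.hgvs_c, c.hgvs_p)
        for k, names in groups:
            if k == key:
                names.append(c.isoform)
                break
        else:
            groups.append((key, [c.isoform]))
    parts = []
    for (hc, hp), names in groups:
        body = f"{hc} ({hp})" if hp else hc
        parts.append(f"{','.join(names)}:{body}")
    return "; ".join(parts)
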