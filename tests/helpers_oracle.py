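"""Brute-force consequence oracle, independent of the annotation engine.

Rebuilds the mutated genomic sequence with plain string edits, re-splices the
transcript directly from the exon model, translates with Biopython, and
derives the consequence category by comparing reference and mutant proteins.
It shares no code path with ``melpanel.consequence``: no HGVS machinery, no
CDS projection, no indel normalization.

Scope: exonic variants that do not span an exon/intron junction or a
CDS/UTR boundary (which is how the random test variants are generated).
"""

from __future__ import annotations

from Bio.Seq import Seq

from melpanel.consequence import Category, VariantRecord
from melpanel.transcript import GeneModel, Isoform


def _plus_edit(model: GeneModel, v: VariantRecord):
    """(plus-strand 0-based insertion/replace index, plus_ref, plus_alt)."""
    locus = model.reference
    rc = lambda s: str(Seq(s).reverse_complement()) if s else ""
    if model.strand == "+":
        i = v.position.pos - locus.offset
        if v.ref:
            return i, v.ref, v.alt
        return i + 1, "", v.alt  # insert between anchor and the next base
    if v.ref:
        lo = v.position.pos - len(v.ref) + 1
        return lo - locus.offset, rc(v.ref), rc(v.alt)
    return v.position.pos - locus.offset, "", rc(v.alt)


def _splice(seq: str, isoform: Isoform, bounds: list[tuple[int, int]]) -> str:
    parts = []
    for s, t in bounds:
        chunk = seq[s : t + 1]
        if isoform.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        parts.append(chunk)
    return "".join(parts)


def _translate_to_stop(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    aa = str(Seq(seq[:usable]).translate())
    return aa[: aa.index("*")] if "*" in aa else aa


def oracle_category(model: GeneModel, v: VariantRecord, isoform: Isoform) -> Category:
    """Consequence category from first principles."""
    locus = model.reference
    plus = locus.seq
    i, pref, palt = _plus_edit(model, v)
    if pref:
        assert plus[i : i + len(pref)] == pref, "oracle: reference mismatch"
        mutated = plus[:i] + palt + plus[i + len(pref) :]
        edit_hi = i + len(pref) - 1
    else:
        mutated = plus[:i] + palt + plus[i:]
        edit_hi = i - 1  # insertion sits between edit_hi and edit_hi + 1
    delta = len(palt) - len(pref)

    # region first, from transcript coordinates of the coding-strand anchor
    tpos = isoform.genomic_to_transcript(v.position.pos)
    assert tpos is not None, "oracle handles exonic variants only"
    t0 = tpos - 1  # 0-based
    cs, ce = isoform.cds_start - 1, isoform.cds_end  # 0-based half-open CDS
    if v.ref:
        lo_t, hi_t = t0, t0 + len(v.ref) - 1
        if hi_t < cs:
            return Category.FIVE_UTR
        if lo_t >= ce:
            return Category.THREE_UTR
        assert cs <= lo_t and hi_t < ce, "edit spans a CDS boundary"
    else:
        if t0 < cs:
            return Category.FIVE_UTR
        if t0 >= ce - 1:
            return Category.THREE_UTR

    # re-splice with exon bounds adjusted for the length change; a start
    # boundary inside a deletion clamps to the first surviving base, an end
    # boundary clamps to the last base before the deletion
    def shift_start(x: int) -> int:
        if delta == 0:
            return x
        if pref:  # pure deletion of [i, edit_hi]
            if x > edit_hi:
                return x + delta
            return i if x >= i else x
        return x + delta if x >= i else x  # insertion at index i

    def shift_end(x: int) -> int:
        if delta == 0:
            return x
        if pref:
            if x > edit_hi:
                return x + delta
            return i - 1 if x >= i else x
        return x + delta if x >= i else x

    adj = []
    for e in isoform.exons:
        s0, t0g = e.start - locus.offset, e.end - locus.offset
        adj.append((shift_start(s0), shift_end(t0g)))
    ref_tx = _splice(plus, isoform, [
        (e.start - locus.offset, e.end - locus.offset) for e in isoform.exons
    ])
    mut_tx = _splice(mutated, isoform, adj)

    refp = _translate_to_stop(ref_tx[cs:])
    mutp = _translate_to_stop(mut_tx[cs:])

    if mutp == refp:
        return Category.SILENT
    if delta % 3 != 0:
        return Category.TRUNCATING
    if delta == 0:
        return Category.TRUNCATING if len(mutp) < len(refp) else Category.MISSENSE
    k = abs(delta) // 3
    expected = len(refp) - k if delta < 0 else len(refp) + k
    if len(mutp) < expected:
        return Category.TRUNCATING
    return Category.INFRAME_DELETION if delta < 0 else Category.INFRAME_INSERTION
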