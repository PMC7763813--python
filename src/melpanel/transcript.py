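"""Gene and transcript models with genomic<->CDS coordinate projection.

The central difficulty this module handles is the CDKN2A locus, where four
transcript isoforms (p16INK4a, p14ARF, p12, p16gamma) overlap on the minus
strand of chromosome 9 and read a shared exon in different frames.  A single
genomic position therefore maps to a different coding (c.) coordinate -- and
potentially a different functional consequence -- in each isoform.

Conventions
-----------
* All public coordinates are 1-based inclusive (HGVS / VCF style); internal
  exon arithmetic is 0-based half-open.
* Coding coordinates follow HGVS: ``c.n`` within the CDS, ``c.-n`` in the
  5'UTR, ``c.*n`` in the 3'UTR, and ``c.n+k`` / ``c.n-k`` for intronic
  positions anchored to the nearest exon boundary.
* On minus-strand genes, transcript order runs from high genomic coordinate
  to low, and all sequences returned here are coding-strand sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml
from Bio.Seq import Seq

__all__ = [
    "GenomicPosition",
    "Exon",
    "Isoform",
    "GeneModel",
    "LocusSequence",
    "CdsCoordinate",
    "GeneModelError",
    "OutOfTranscriptError",
    "AlphabetError",
    "load_gene_model",
    "project_genomic_to_cds",
    "project_cds_to_genomic",
    "translate_cds",
    "reverse_complement",
]

_ISOFORM_ALIASES = {"p16g": "p16γ", "p16gamma": "p16γ"}


def canonical_isoform_name(name: str) -> str:
    """Resolve ASCII aliases (``p16g``) to the canonical UTF-8 name."""
    return _ISOFORM_ALIASES.get(name, name)


class GeneModelError(ValueError):
    """Invalid gene-model configuration."""


class OutOfTranscriptError(ValueError):
    """A position falls outside the transcript (or CDS/UTR) extent."""


class AlphabetError(ValueError):
    """A sequence contains a symbol outside A/C/G/T."""


@dataclass(frozen=True)
class GenomicPosition:
    chrom: str
    pos: int  # 1-based on the reference assembly (hg19)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"genomic position must be >= 1, got {self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class Exon:
    start: int  # 1-based inclusive genomic
    end: int
    rank: int  # ordinal in transcript 5'->3' order

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CdsCoordinate:
    """HGVS-style coding coordinate.

    ``base`` is the 1-based CDS position; negative values denote the 5'UTR
    (``c.-n``).  ``utr3`` marks 3'UTR positions (``c.*n``, with ``base`` = n).
    ``offset`` is the signed intronic offset relative to the nearest exonic
    base (0 for exonic positions).
    """

    base: int
    offset: int = 0
    utr3: bool = False

    def __post_init__(self):
        if self.base == 0:
            raise ValueError("CDS coordinate base 0 does not exist in HGVS")
        if self.utr3 and self.base < 0:
            raise ValueError("a coordinate cannot be in both UTRs")

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0

    @property
    def in_cds(self) -> bool:
        return self.offset == 0 and self.base > 0 and not self.utr3

    def __str__(self) -> str:
        stem = f"*{self.base}" if self.utr3 else str(self.base)
        if self.offset == 0:
            return stem
        sign = "+" if self.offset > 0 else "-"
        return f"{stem}{sign}{abs(self.offset)}"

    @classmethod
    def parse(cls, text: str) -> "CdsCoordinate":
        m = re.fullmatch(r"(\*)?(-?\d+)([+-]\d+)?", text.strip())
        if not m:
            raise ValueError(f"cannot parse CDS coordinate {text!r}")
        utr3 = m.group(1) is not None
        base = int(m.group(2))
        offset = int(m.group(3)) if m.group(3) else 0
        return cls(base=base, offset=offset, utr3=utr3)


class LocusSequence:
    """A locus-scale nucleotide sequence anchored to genomic coordinates.

    ``offset`` is the genomic (hg19) position of the first base of ``seq``.
    The stored sequence is the plus (genomic) strand.
    """

    def __init__(self, seq: str, offset: int, chrom: str = ""):
        self.seq = seq.upper()
        self.offset = int(offset)
        self.chrom = chrom

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        return self.offset + len(self.seq) - 1

    def base(self, pos: int) -> str:
        """Plus-strand base at 1-based genomic position ``pos``."""
        if not (self.start <= pos <= self.end):
            raise OutOfTranscriptError(
                f"position {pos} outside locus sequence [{self.start}, {self.end}]"
            )
        return self.seq[pos - self.offset]

    def slice(self, start: int, end: int) -> str:
        """Plus-strand sequence for the 1-based inclusive interval."""
        if start > end:
            raise ValueError("start > end")
        if not (self.start <= start and end <= self.end):
            raise OutOfTranscriptError(
                f"interval {start}-{end} outside locus sequence"
            )
        return self.seq[start - self.offset : end - self.offset + 1]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class Isoform:
    """One transcript isoform: ordered exons plus transcript-space CDS bounds.

    ``exons`` are in transcript (5'->3') order: ascending genomic start on
    '+', descending on '-'.  ``cds_start``/``cds_end`` are 1-based positions
    in transcript space (concatenated exon sequence).
    """

    name: str
    strand: str
    exons: list[Exon]
    cds_start: int
    cds_end: int
    frame_exception: bool = False  # reference-annotation CDS not divisible by 3

    def __post_init__(self):
        self.name = canonical_isoform_name(self.name)
        if self.strand not in {"+", "-"}:
            raise GeneModelError(
                f"isoform {self.name}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise GeneModelError(f"isoform {self.name}: no exons")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise GeneModelError(
                    f"isoform {self.name}: exons {a.rank} and {b.rank} overlap"
                )
        expect = ordered if self.strand == "+" else ordered[::-1]
        if [e.rank for e in self.exons] != [e.rank for e in expect] or list(
            self.exons
        ) != expect:
            raise GeneModelError(
                f"isoform {self.name}: exon order inconsistent with strand "
                f"{self.strand}"
            )
        if not (1 <= self.cds_start < self.cds_end <= self.transcript_length):
            raise GeneModelError(
                f"isoform {self.name}: CDS [{self.cds_start}, {self.cds_end}] "
                f"outside transcript of length {self.transcript_length}"
            )
        if self.cds_length % 3 and not self.frame_exception:
            raise GeneModelError(
                f"isoform {self.name}: CDS length {self.cds_length} not a "
                "multiple of 3 (set frame_exception to keep it)"
            )

    # -- basic geometry -----------------------------------------------------

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min, max) of the transcript, introns included."""
        return (
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def is_exonic(self, pos: int) -> bool:
        return any(pos in e for e in self.exons)

    # -- transcript-space mapping -------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int | None:
        """1-based transcript coordinate of an exonic genomic position."""
        t = 0
        for e in self.exons:
            if pos in e:
                within = (pos - e.start) if self.strand == "+" else (e.end - pos)
                return t + within + 1
            t += e.length
        return None

    def transcript_to_genomic(self, t: int) -> int:
        if not (1 <= t <= self.transcript_length):
            raise OutOfTranscriptError(
                f"transcript position {t} outside isoform {self.name}"
            )
        for e in self.exons:
            if t <= e.length:
                return e.start + t - 1 if self.strand == "+" else e.end - t + 1
            t -= e.length
        raise AssertionError("unreachable")

    def transcript_to_cds(self, t: int) -> CdsCoordinate:
        if t < self.cds_start:
            return CdsCoordinate(base=-(self.cds_start - t))
        if t > self.cds_end:
            return CdsCoordinate(base=t - self.cds_end, utr3=True)
        return CdsCoordinate(base=t - self.cds_start + 1)

    def cds_to_transcript(self, c: CdsCoordinate) -> int:
        if c.utr3:
            t = self.cds_end + c.base
        elif c.base < 0:
            t = self.cds_start + c.base  # c.-n -> cds_start - n
        else:
            t = self.cds_start + c.base - 1
        if not (1 <= t <= self.transcript_length):
            raise OutOfTranscriptError(
                f"c.{c} beyond the extent of isoform {self.name}"
            )
        return t

    # -- sequences ----------------------------------------------------------

    def transcript_sequence(self, locus: LocusSequence) -> str:
        parts = []
        for e in self.exons:
            s = locus.slice(e.start, e.end)
            parts.append(s if self.strand == "+" else reverse_complement(s))
        return "".join(parts)

    def cds_sequence(self, locus: LocusSequence) -> str:
        return self.transcript_sequence(locus)[self.cds_start - 1 : self.cds_end]


@dataclass
class GeneModel:
    symbol: str
    chrom: str
    strand: str
    isoforms: list[Isoform]
    reference: LocusSequence | None = None
    _by_name: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        names = [iso.name for iso in self.isoforms]
        if len(set(names)) != len(names):
            raise GeneModelError(f"{self.symbol}: duplicate isoform names")
        for iso in self.isoforms:
            if iso.strand != self.strand:
                raise GeneModelError(
                    f"{self.symbol}: isoform {iso.name} strand differs from gene"
                )
            if self.reference is not None:
                lo, hi = iso.span
                if lo < self.reference.start or hi > self.reference.end:
                    raise GeneModelError(
                        f"{self.symbol}: isoform {iso.name} exons outside the "
                        "locus sequence extent"
                    )
        self._by_name = {iso.name: iso for iso in self.isoforms}

    def isoform(self, name: str) -> Isoform:
        name = canonical_isoform_name(name)
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"{self.symbol} has no isoform {name!r}; available: "
                f"{sorted(self._by_name)}"
            ) from None

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(iso.span[0] for iso in self.isoforms),
            max(iso.span[1] for iso in self.isoforms),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def project_genomic_to_cds(isoform: Isoform, g: GenomicPosition) -> CdsCoordinate:
    """Project a genomic position into HGVS c. space for one isoform.

    Exonic positions get offset 0; intronic positions are anchored to the
    nearest exon boundary in transcript orientation (donor side ``+k``,
    acceptor side ``-k``; ties break to the donor side, as HGVS prescribes
    for the intron midpoint).
    """
    pos = g.pos
    if not isoform.contains(pos):
        raise OutOfTranscriptError(
            f"{g} outside the transcript span of isoform {isoform.name}"
        )
    t = isoform.genomic_to_transcript(pos)
    if t is not None:
        return isoform.transcript_to_cds(t)
    # intronic: find flanking exons in transcript order
    for up, down in zip(isoform.exons, isoform.exons[1:]):
        if isoform.strand == "+":
            inside = up.end < pos < down.start
            d_donor = pos - up.end
            d_acceptor = down.start - pos
        else:
            inside = down.end < pos < up.start
            d_donor = up.start - pos
            d_acceptor = pos - down.end
        if inside:
            t_up = isoform.genomic_to_transcript(
                up.end if isoform.strand == "+" else up.start
            )
            t_down = isoform.genomic_to_transcript(
                down.start if isoform.strand == "+" else down.end
            )
            if d_donor <= d_acceptor:
                anchor = isoform.transcript_to_cds(t_up)
                return CdsCoordinate(anchor.base, offset=d_donor, utr3=anchor.utr3)
            anchor = isoform.transcript_to_cds(t_down)
            return CdsCoordinate(anchor.base, offset=-d_acceptor, utr3=anchor.utr3)
    raise AssertionError("position inside span but in no exon/intron")


def project_cds_to_genomic(
    isoform: Isoform, c: CdsCoordinate, chrom: str = ""
) -> GenomicPosition:
    """Inverse of :func:`project_genomic_to_cds` (round-trip identity holds)."""
    t = isoform.cds_to_transcript(CdsCoordinate(c.base, 0, c.utr3))
    pos = isoform.transcript_to_genomic(t)
    if c.offset:
        step = 1 if isoform.strand == "+" else -1
        pos = pos + step * c.offset
        if isoform.is_exonic(pos) or not isoform.contains(pos):
            raise OutOfTranscriptError(
                f"c.{c} does not fall in an intron of isoform {isoform.name}"
            )
    return GenomicPosition(chrom or "?", pos)


_CODON_RE = re.compile(r"[^ACGT]")


def translate_cds(cds_sequence: str, to_stop: bool = False) -> str:
    """Standard-code translation; stop codons render as ``*``.

    Translation continues to the end of the given sequence (trailing partial
    codons are ignored); with ``to_stop`` the result is truncated at the
    first stop.
    """
    seq = cds_sequence.upper()
    if len(seq) < 3:
        raise ValueError("CDS sequence shorter than one codon")
    m = _CODON_RE.search(seq)
    if m:
        raise AlphabetError(
            f"non-ACGT symbol {seq[m.start()]!r} at position {m.start() + 1}"
        )
    usable = len(seq) - len(seq) % 3
    aa = str(Seq(seq[:usable]).translate())
    if to_stop and "*" in aa:
        aa = aa[: aa.index("*")]
    return aa


# ---------------------------------------------------------------------------
# gene-model files
# ---------------------------------------------------------------------------


def _parse_isoform(symbol: str, strand: str, spec: dict) -> Isoform:
    name = spec.get("name")
    try:
        exons = [
            Exon(start=int(s), end=int(e), rank=i + 1)
            for i, (s, e) in enumerate(spec["exons"])
        ]
        return Isoform(
            name=name,
            strand=strand,
            exons=exons,
            cds_start=int(spec["cds_start"]),
            cds_end=int(spec["cds_end"]),
            frame_exception=bool(spec.get("frame_exception", False)),
        )
    except (KeyError, TypeError) as exc:
        raise GeneModelError(f"{symbol}: malformed isoform {name!r}: {exc}") from exc


def load_gene_model(source, locus: LocusSequence | None = None) -> GeneModel:
    """Load and validate a gene model from YAML (path, text, or dict).

    The document lists ``symbol``, ``chrom``, ``strand`` and per-isoform exon
    coordinates (1-based inclusive, in transcript order) plus transcript-space
    CDS extents.  A locus sequence may be attached afterwards or passed here.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = source
        if hasattr(source, "read"):
            text = source.read()
        elif isinstance(source, str) and "\n" not in source and source.endswith(
            (".yaml", ".yml")
        ):
            with open(source) as fh:
                text = fh.read()
        elif not isinstance(source, str):
            with open(source) as fh:
                text = fh.read()
        doc = yaml.safe_load(text)
    try:
        symbol = doc["symbol"]
        chrom = doc["chrom"]
        strand = doc["strand"]
        iso_specs = doc["isoforms"]
    except (KeyError, TypeError) as exc:
        raise GeneModelError(f"gene-model document missing field: {exc}") from exc
    if strand not in {"+", "-"}:
        raise GeneModelError(f"{symbol}: unknown strand {strand!r}")
    isoforms = [_parse_isoform(symbol, strand, s) for s in iso_specs]
    return GeneModel(
        symbol=symbol, chrom=chrom, strand=strand, isoforms=isoforms, reference=locus
    )
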