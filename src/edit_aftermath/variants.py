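"""Caller-agnostic variant records and VCF 4.2 round-trip.

Small variants use explicit left-anchored REF/ALT alleles.  Structural
variants come in two shapes, mirroring VCF semantics:

* symbolic records (``<INV>``, ``<DEL>``, ``<DUP>``) with an ``END`` and
  ``SVLEN``;
* breakend (BND) records, paired through ``MATEID`` — or single
  breakends (``t.`` / ``.t`` ALTs) for one-sided junctions such as
  telomere-capped chromosome truncations.

Breakend orientation vocabulary used throughout the package:

* ``right-open``  — the retained sequence lies at or left of ``pos``;
  the break is immediately 3' of ``pos``.
* ``left-open``   — the retained sequence lies at or right of ``pos``;
  the break is immediately 5' of ``pos``.

A junction therefore reads: (segment named by locus-a, in its stated
orientation) + inserted-sequence + (segment named by locus-b).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pysam

RIGHT_OPEN = "right-open"
LEFT_OPEN = "left-open"


class VariantType(str, Enum):
    SNV = "SNV"
    INS = "insertion"
    DEL = "deletion"
    SV = "SV"


@dataclass(frozen=True)
class BreakendLocus:
    chrom: str
    pos: int  # 1-based
    orientation: str  # RIGHT_OPEN or LEFT_OPEN

    def __post_init__(self) -> None:
        if self.orientation not in (RIGHT_OPEN, LEFT_OPEN):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class BreakendPair:
    """One SV junction: two partner loci plus optional inserted sequence.

    ``partner_linked`` is False for single breakends (the partner locus
    is unknown; ``locus_b`` is then None).
    """

    locus_a: BreakendLocus
    locus_b: BreakendLocus | None
    inserted_sequence: str = ""
    partner_linked: bool = True

    def __post_init__(self) -> None:
        if self.partner_linked and self.locus_b is None:
            raise ValueError("partner_linked pair needs locus_b")


@dataclass
class VariantCall:
    """One VCF record in internal form."""

    variant_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str  # explicit allele, symbolic (<INV>...), or BND ALT string
    var_type: VariantType
    net_length_change: int = 0
    supporting_reads: int = 0
    colony_mode: str = "pooled-5"
    colony_id: str | None = None
    end: int | None = None  # symbolic SV END (1-based inclusive)
    sv_type: str | None = None  # BND / INV / DEL / DUP for SVs
    mate_id: str | None = None
    breakend: BreakendPair | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.var_type == VariantType.SNV and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(f"{self.variant_id}: SNV alleles must be length 1")

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive reference span of the variant.

        Insertions span only their anchor base; symbolic SVs span
        POS..END; breakends span their own locus position.
        """
        if self.end is not None:
            return (self.pos, self.end)
        if self.var_type == VariantType.INS or self.breakend is not None:
            return (self.pos, self.pos)
        return (self.pos, self.pos + len(self.ref) - 1)

    @property
    def key(self) -> tuple:
        """Identity key for subtraction/recurrence matching of small variants."""
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# BND ALT string <-> BreakendPair

_BND_RE = re.compile(
    r"^(?:(?P<t1>[A-Za-z]+)(?P<b1>[\[\]])(?P<p1>[^\[\]]+)(?P=b1)"
    r"|(?P<b2>[\[\]])(?P<p2>[^\[\]]+)(?P=b2)(?P<t2>[A-Za-z]+))$"
)


def bnd_alt_string(ref_base: str, self_orient: str, partner: BreakendLocus, inserted: str) -> str:
    """VCF 4.2 BND ALT for a record at a locus with the given orientation."""
    mate = f"{partner.chrom}:{partner.pos}"
    bracket = "[" if partner.orientation == LEFT_OPEN else "]"
    if self_orient == RIGHT_OPEN:
        return f"{ref_base}{inserted}{bracket}{mate}{bracket}"
    return f"{bracket}{mate}{bracket}{inserted}{ref_base}"


def parse_bnd_alt(alt: str, chrom: str, pos: int) -> BreakendPair | None:
    """Parse a (possibly single-) breakend ALT into a BreakendPair.

    Returns None when ``alt`` is not a breakend ALT.
    """
    if alt.endswith(".") and not alt.startswith("."):
        # single breakend, sequence retained to the left
        ref_plus_ins = alt[:-1]
        return BreakendPair(
            BreakendLocus(chrom, pos, RIGHT_OPEN),
            None,
            inserted_sequence=ref_plus_ins[1:],
            partner_linked=False,
        )
    if alt.startswith(".") and not alt.endswith("."):
        ins_plus_ref = alt[1:]
        return BreakendPair(
            BreakendLocus(chrom, pos, LEFT_OPEN),
            None,
            inserted_sequence=ins_plus_ref[:-1],
            partner_linked=False,
        )
    m = _BND_RE.match(alt)
    if not m:
        return None
    if m.group("t1") is not None:
        self_orient, bracket, loc, t = RIGHT_OPEN, m.group("b1"), m.group("p1"), m.group("t1")
        inserted = t[1:]
    else:
        self_orient, bracket, loc, t = LEFT_OPEN, m.group("b2"), m.group("p2"), m.group("t2")
        inserted = t[:-1]
    partner_orient = LEFT_OPEN if bracket == "[" else RIGHT_OPEN
    pchrom, ppos = loc.rsplit(":", 1)
    return BreakendPair(
        BreakendLocus(chrom, pos, self_orient),
        BreakendLocus(pchrom, int(ppos), partner_orient),
        inserted_sequence=inserted,
    )


# ---------------------------------------------------------------------------
# VCF I/O (pysam)

_INFO_LINES = [
    ('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">'),
    ('##INFO=<ID=END,Number=1,Type=Integer,Description="End of symbolic SV">'),
    ('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length change">'),
    ('##INFO=<ID=MATEID,Number=1,Type=String,Description="Breakend mate record">'),
    ('##INFO=<ID=COLONY,Number=1,Type=String,Description="Originating colony">'),
    ('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read count">'),
]


def _build_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for line in _INFO_LINES:
        header.add_line(line)
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP,Description="Duplication">')
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    return header


def write_vcf(calls: list[VariantCall], path: str | Path, contigs: dict[str, int]) -> None:
    """Write calls as an uncompressed, coordinate-sorted VCF 4.2."""
    header = _build_header(contigs)
    order = {name: i for i, name in enumerate(contigs)}
    calls = sorted(calls, key=lambda c: (order.get(c.chrom, 1 << 30), c.pos, c.variant_id))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                alleles=(c.ref, c.alt),
                id=c.variant_id,
            )
            if c.sv_type is not None:
                rec.info["SVTYPE"] = c.sv_type
            # SVLEN=0 would make htslib re-derive END as 0 for symbolic
            # alleles, so it is only written when nonzero
            if c.var_type == VariantType.SV and c.breakend is None and c.net_length_change:
                rec.info["SVLEN"] = c.net_length_change
            if c.mate_id is not None:
                rec.info["MATEID"] = c.mate_id
            if c.colony_id is not None:
                rec.info["COLONY"] = c.colony_id
            if c.supporting_reads:
                rec.info["SUPPORT"] = c.supporting_reads
            # set last: htslib resyncs INFO/END from rlen on info updates
            if c.end is not None:
                rec.stop = c.end
            elif c.sv_type == "BND":
                rec.stop = c.pos
            vcf.write(rec)


def _classify(ref: str, alt: str, sv_type: str | None, net: int) -> VariantType:
    if sv_type == "BND" or alt.startswith("<") or "[" in alt or "]" in alt or "." in alt:
        return VariantType.SV
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if abs(net) >= 50:
        return VariantType.SV
    return VariantType.INS if net > 0 else VariantType.DEL


def read_vcf(path: str | Path, sample_id: str = "", colony_mode: str = "pooled-5") -> list[VariantCall]:
    """Read a VCF into VariantCall records (first ALT allele only)."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else rec.ref
            sv_type = rec.info.get("SVTYPE")
            breakend = None
            end = None
            if alt.startswith("<"):
                end = rec.stop  # pysam stop is 1-based inclusive END
                net = int(rec.info.get("SVLEN", 0))
            elif "[" in alt or "]" in alt or alt.endswith(".") or alt.startswith("."):
                breakend = parse_bnd_alt(alt, rec.contig, rec.pos)
                net = int(rec.info.get("SVLEN", 0))
            else:
                net = len(alt) - len(rec.ref)
            vtype = _classify(rec.ref, alt, sv_type, net)
            calls.append(
                VariantCall(
                    variant_id=rec.id or f"{rec.contig}_{rec.pos}",
                    sample_id=sample_id,
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    var_type=vtype,
                    net_length_change=net,
                    supporting_reads=int(rec.info.get("SUPPORT", 0)),
                    colony_mode=colony_mode,
                    colony_id=rec.info.get("COLONY"),
                    end=end,
                    sv_type=sv_type,
                    mate_id=rec.info.get("MATEID"),
                    breakend=breakend,
                )
            )
    return calls
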