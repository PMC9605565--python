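"""Synthetic data generator emulating a pooled-colony CRISPR resequencing design.

The generator produces, in order:

1. a random multi-chromosome annotated genome (:func:`generate_genome`);
2. per-colony repair outcomes at the guide target loci
   (:func:`plan_colony_outcomes`) spanning the observed outcome classes —
   small indels (< 50 bp), large indels (>= 50 bp), inter-locus
   rearrangements, telomere-capped chromosome truncations and
   inversions;
3. whole-genome sequence surgery per colony (:func:`apply_edits`);
4. paired 150 bp reads from ~550 bp fragments for pools of up to five
   colonies at a configured fold-coverage (:func:`simulate_pool_reads`).

Every step is deterministic for a fixed seed.  The truth manifest (TSV)
and truth variants (VCF, SVs as breakends) allow exact recovery checks
downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .dna import decode, encode, random_dna, revcomp
from .genome import AnnotatedGenome, GeneRecord
from .variants import (
    LEFT_OPEN,
    RIGHT_OPEN,
    BreakendLocus,
    BreakendPair,
    VariantCall,
    VariantType,
    bnd_alt_string,
)

#: Telomere seed motif appended at truncation junctions.  The repeat unit
#: is a configuration value shared by the simulator and the truncation
#: detector; the default is an arbitrary TG-rich 8-mer.
TELOMERE_MOTIF = "GGTGTAGT"


class SimulationError(ValueError):
    pass


class PlacementError(SimulationError):
    """Gene placement failed after bounded retries."""


class EditClass(str, Enum):
    NONE = "none"
    SMALL_INDEL = "small-indel"
    LARGE_INDEL = "large-indel"
    REARRANGEMENT = "rearrangement"
    TRUNCATION = "truncation"
    INVERSION = "inversion"


@dataclass
class EditEvent:
    """One repair outcome at (or joining) target loci.

    ``position`` is the 1-based anchor: for indels the left-anchored
    VCF position (first REF base), for truncations the last retained
    base, for inversions the base before the inverted segment, for
    rearrangements the last base of the first derivative's left part.
    """

    edit_class: EditClass
    chrom: str
    position: int
    target_id: str = ""
    ref: str = ""
    alt: str = ""
    end: int | None = None  # inversion: last base of inverted segment
    chrom2: str | None = None  # rearrangement partner chromosome
    position2: int | None = None
    net_length_change: int = 0
    telomere_capped: bool = False
    inserted_sequence: str = ""

    def __post_init__(self) -> None:
        n = abs(self.net_length_change)
        if self.edit_class == EditClass.SMALL_INDEL and not 1 <= n <= 49:
            raise SimulationError(f"small-indel net change {n} outside 1..49")
        if self.edit_class == EditClass.LARGE_INDEL and n < 50:
            raise SimulationError(f"large-indel net change {n} below 50")
        if self.edit_class == EditClass.TRUNCATION and not self.telomere_capped:
            raise SimulationError("truncation events must be telomere-capped")
        if self.edit_class == EditClass.REARRANGEMENT and (
            self.chrom2 is None or self.position2 is None
        ):
            raise SimulationError("rearrangement needs both partner loci")

    def ref_spans(self) -> list[tuple[str, int, int]]:
        """Reference intervals this edit touches (chrom, start, end)."""
        if self.edit_class == EditClass.NONE:
            return []
        if self.edit_class in (EditClass.SMALL_INDEL, EditClass.LARGE_INDEL):
            return [(self.chrom, self.position, self.position + len(self.ref) - 1)]
        if self.edit_class == EditClass.INVERSION:
            return [(self.chrom, self.position, self.end or self.position)]
        if self.edit_class == EditClass.TRUNCATION:
            # everything 3' of the cut is lost; claim an open-ended span
            return [(self.chrom, self.position + 1, 1 << 60)]
        # rearrangement claims both whole chromosomes
        return [(self.chrom, 1, 1 << 60), (self.chrom2, 1, 1 << 60)]


@dataclass
class ColonyTruth:
    """Ground-truth edit list for one colony."""

    colony_id: str
    pool_id: str
    edits: list[EditEvent] = field(default_factory=list)

    def validate(self) -> "ColonyTruth":
        spans = [s for e in self.edits for s in e.ref_spans()]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                (c1, s1, e1), (c2, s2, e2) = spans[i], spans[j]
                if c1 == c2 and s1 <= e2 and s2 <= e1:
                    raise SimulationError(
                        f"{self.colony_id}: overlapping edits "
                        f"{self.edits[i].edit_class.value}@{c1}:{s1} and "
                        f"{self.edits[j].edit_class.value}@{c2}:{s2}"
                    )
        return self


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(
    n_chromosomes: int,
    chromosome_lengths: list[int],
    n_genes: int,
    essential_fraction: float,
    seed: int,
    gene_length_range: tuple[int, int] = (300, 1503),
    max_tries: int = 200,
) -> AnnotatedGenome:
    """Random annotated genome with non-overlapping single-exon genes.

    Gene lengths are multiples of 3 drawn uniformly from
    ``gene_length_range``; essential flags are Bernoulli draws with the
    given fraction.  Deterministic for a fixed seed.
    """
    if len(chromosome_lengths) != n_chromosomes:
        raise SimulationError("need one length per chromosome")
    if any(l < 10_000 for l in chromosome_lengths):
        raise SimulationError("chromosome lengths must be >= 10 kb")
    rng = np.random.default_rng(seed)
    names = [f"chr{i+1}" for i in range(n_chromosomes)]
    chroms = {name: random_dna(rng, l) for name, l in zip(names, chromosome_lengths)}

    total = sum(chromosome_lengths)
    weights = np.asarray(chromosome_lengths, dtype=float) / total
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    genes: list[GeneRecord] = []
    for i in range(n_genes):
        placed = False
        for _ in range(max_tries):
            chrom = names[rng.choice(n_chromosomes, p=weights)]
            length = 3 * int(rng.integers(gene_length_range[0] // 3, gene_length_range[1] // 3 + 1))
            l_chrom = len(chroms[chrom])
            if length >= l_chrom:
                continue
            start = int(rng.integers(1, l_chrom - length + 2))
            end = start + length - 1
            if any(s <= end and start <= e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            genes.append(
                GeneRecord(
                    gene_id=f"gene{i+1:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    essential=bool(rng.random() < essential_fraction),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place gene {i+1} of {n_genes} after {max_tries} tries"
            )
    return AnnotatedGenome(chroms, genes).validate()


# ---------------------------------------------------------------------------
# outcome planning


@dataclass
class IndelSizeModel:
    """Uniform size models for the indel classes and the other SV shapes."""

    small: tuple[int, int] = (1, 15)  # bp, inclusive; < 50 enforced
    large: tuple[int, int] = (50, 2500)  # bp, inclusive; >= 50 enforced
    inversion: tuple[int, int] = (200, 2000)
    deletion_fraction: float = 0.8  # remainder are insertions
    telomere_copies: tuple[int, int] = (5, 15)

    def __post_init__(self) -> None:
        if not 1 <= self.small[0] <= self.small[1] <= 49:
            raise SimulationError("small indel sizes must lie in 1..49")
        if self.large[0] < 50:
            raise SimulationError("large indel sizes must be >= 50")


def plan_colony_outcomes(
    genome: AnnotatedGenome,
    guides: list,
    n_colonies: int,
    class_probabilities: dict[str, float],
    indel_size_model: IndelSizeModel | None = None,
    seed: int = 0,
    pool_size: int = 5,
    telomere_motif: str = TELOMERE_MOTIF,
) -> list[ColonyTruth]:
    """Draw one repair outcome per target locus for each colony.

    A rearrangement outcome (allowed only with two guides) replaces the
    outcome at *both* loci with a single reciprocal junction between the
    two cut sites; it is drawn first at its configured probability, then
    the per-locus classes are drawn from the renormalised remainder.
    """
    model = indel_size_model or IndelSizeModel()
    probs = {EditClass(k): float(v) for k, v in class_probabilities.items()}
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise SimulationError("class probabilities must sum to 1")
    if not 1 <= pool_size <= 5:
        raise SimulationError("pool size must be 1..5")
    p_rearr = probs.get(EditClass.REARRANGEMENT, 0.0)
    if p_rearr > 0 and len(guides) < 2:
        raise SimulationError("rearrangement outcomes need two guides")

    rest = {c: p for c, p in probs.items() if c != EditClass.REARRANGEMENT}
    rest_total = sum(rest.values())
    rng = np.random.default_rng(seed)
    truths: list[ColonyTruth] = []
    for ci in range(n_colonies):
        colony_id = f"colony{ci+1:03d}"
        pool_id = f"pool{ci // pool_size + 1}"
        for _ in range(50):  # bounded retries against edit overlap
            edits: list[EditEvent] = []
            if p_rearr > 0 and rng.random() < p_rearr:
                g1, g2 = guides[0], guides[1]
                edits.append(
                    EditEvent(
                        EditClass.REARRANGEMENT,
                        chrom=g1.chrom,
                        position=g1.cut_locus,
                        target_id=f"{g1.guide_id}+{g2.guide_id}",
                        chrom2=g2.chrom,
                        position2=g2.cut_locus,
                    )
                )
            elif rest_total > 0:
                for g in guides:
                    cls = _draw_class(rng, rest, rest_total)
                    edits.append(
                        _make_event(rng, genome, g, cls, model, telomere_motif)
                    )
            truth = ColonyTruth(colony_id, pool_id, edits)
            try:
                truth.validate()
            except SimulationError:
                continue
            truths.append(truth)
            break
        else:
            raise SimulationError(f"could not draw non-overlapping edits for {colony_id}")
    return truths


def _draw_class(rng: np.random.Generator, probs: dict[EditClass, float], total: float) -> EditClass:
    u = rng.random() * total
    acc = 0.0
    for cls, p in probs.items():
        acc += p
        if u < acc:
            return cls
    return next(reversed(probs))


def _make_event(
    rng: np.random.Generator,
    genome: AnnotatedGenome,
    guide,
    cls: EditClass,
    model: IndelSizeModel,
    telomere_motif: str,
) -> EditEvent:
    chrom, cut = guide.chrom, guide.cut_locus
    l_chrom = genome.chrom_length(chrom)
    if cls == EditClass.NONE:
        return EditEvent(EditClass.NONE, chrom, cut, target_id=guide.guide_id)
    if cls in (EditClass.SMALL_INDEL, EditClass.LARGE_INDEL):
        lo, hi = model.small if cls == EditClass.SMALL_INDEL else model.large
        size = int(rng.integers(lo, hi + 1))
        is_del = rng.random() < model.deletion_fraction
        if is_del and cut + size > l_chrom:
            is_del = False
        if is_del:
            ref = genome.fetch(chrom, cut, cut + size)
            return EditEvent(
                cls, chrom, cut, guide.guide_id, ref=ref, alt=ref[0],
                net_length_change=-size,
            )
        anchor = genome.fetch(chrom, cut, cut)
        return EditEvent(
            cls, chrom, cut, guide.guide_id, ref=anchor,
            alt=anchor + random_dna(rng, size), net_length_change=size,
        )
    if cls == EditClass.INVERSION:
        lo, hi = model.inversion
        size = int(rng.integers(lo, hi + 1))
        end = min(cut + size, l_chrom)
        return EditEvent(
            EditClass.INVERSION, chrom, cut, guide.guide_id, end=end,
            net_length_change=0,
        )
    if cls == EditClass.TRUNCATION:
        copies = int(rng.integers(*model.telomere_copies))
        tel = telomere_motif * copies
        net = -(l_chrom - cut) + len(tel)
        return EditEvent(
            EditClass.TRUNCATION, chrom, cut, guide.guide_id,
            net_length_change=net, telomere_capped=True, inserted_sequence=tel,
        )
    raise SimulationError(f"cannot build event for class {cls}")


def plant_background_snvs(
    genome: AnnotatedGenome,
    n: int,
    rng: np.random.Generator,
    exclude: list[tuple[str, int, int]] | None = None,
    id_prefix: str = "snv",
    sample_id: str = "",
) -> list[VariantCall]:
    """Random SNV calls away from excluded intervals.

    These are call-level only (used for base-strain backgrounds and
    random de novo SNVs in the triage path); they are not applied to
    the simulated sequences.
    """
    exclude = exclude or []
    calls: list[VariantCall] = []
    chroms = sorted(genome.chromosomes)
    lengths = np.array([genome.chrom_length(c) for c in chroms], dtype=float)
    tries = 0
    while len(calls) < n and tries < 100 * max(n, 1):
        tries += 1
        chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        pos = int(rng.integers(1, genome.chrom_length(chrom) + 1))
        if any(c == chrom and s <= pos <= e for c, s, e in exclude):
            continue
        ref = genome.fetch(chrom, pos, pos)
        if ref not in "ACGT":
            continue
        alt = str(rng.permutation([b for b in "ACGT" if b != ref])[0])
        calls.append(
            VariantCall(
                f"{id_prefix}{len(calls)+1:03d}", sample_id, chrom, pos, ref,
                alt, VariantType.SNV,
            )
        )
    if len(calls) < n:
        raise SimulationError("could not place background SNVs")
    return calls


def plant_microhomology(
    genome: AnnotatedGenome,
    guide_a,
    guide_b,
    length: int = 5,
    mismatches: int = 2,
) -> AnnotatedGenome:
    """Engineer an MMEJ-style junction signature between two cut sites.

    Rewrites the reference so that the ``length`` bases lost past the
    cut of ``guide_a`` agree with the first retained bases past the cut
    of ``guide_b`` at exactly ``length - mismatches`` positions, with
    the following base mismatching (capping the homology window).  A
    rearrangement joining the two cut sites then carries a
    ``(length, mismatches)`` microhomology at its first derivative
    junction.
    """
    if mismatches >= length:
        raise SimulationError("mismatches must be fewer than the homology length")
    chroms = dict(genome.chromosomes)
    a_chrom, a = guide_a.chrom, guide_a.cut_locus
    b_chrom, b = guide_b.chrom, guide_b.cut_locus
    donor = list(chroms[a_chrom][a : a + length + 1])  # bases a+1 .. a+L+1
    # distribute mismatches over the window interior, never position 1
    mism_pos = set(range(2, 2 + mismatches))
    window = []
    for i in range(length):
        base = donor[i]
        if (i + 1) in mism_pos:
            base = "ACGT"[("ACGT".index(base) + 1) % 4]
        window.append(base)
    cap = "ACGT"[("ACGT".index(donor[length]) + 1) % 4]  # force mismatch at L+1
    target = chroms[b_chrom]
    chroms[b_chrom] = (
        target[:b] + "".join(window) + cap + target[b + length + 1 :]
    )
    return AnnotatedGenome(chroms, list(genome.genes))


# ---------------------------------------------------------------------------
# genome surgery


def apply_edits(genome: AnnotatedGenome, truth: ColonyTruth) -> AnnotatedGenome:
    """Apply one colony's edits to the reference, returning a new genome.

    Per-chromosome edits are applied right-to-left so reference
    coordinates stay valid; a rearrangement (reciprocal translocation)
    must be the only edit on its two chromosomes.  The returned genome
    carries no gene annotation (coordinates are not lifted over).
    """
    truth.validate()
    chroms = dict(genome.chromosomes)
    rearrangements = [e for e in truth.edits if e.edit_class == EditClass.REARRANGEMENT]
    for e in sorted(
        (e for e in truth.edits
         if e.edit_class not in (EditClass.REARRANGEMENT, EditClass.NONE)),
        key=lambda e: (e.chrom, -e.position),
    ):
        seq = chroms[e.chrom]
        if e.edit_class in (EditClass.SMALL_INDEL, EditClass.LARGE_INDEL):
            if seq[e.position - 1 : e.position - 1 + len(e.ref)] != e.ref:
                raise SimulationError(f"REF mismatch for edit at {e.chrom}:{e.position}")
            chroms[e.chrom] = seq[: e.position - 1] + e.alt + seq[e.position - 1 + len(e.ref):]
        elif e.edit_class == EditClass.INVERSION:
            start, end = e.position + 1, e.end  # inverted segment
            chroms[e.chrom] = seq[: start - 1] + revcomp(seq[start - 1 : end]) + seq[end:]
        elif e.edit_class == EditClass.TRUNCATION:
            chroms[e.chrom] = seq[: e.position] + e.inserted_sequence
    for e in rearrangements:
        a_seq, b_seq = chroms[e.chrom], chroms[e.chrom2]
        a, b = e.position, e.position2
        ins = e.inserted_sequence
        chroms[e.chrom] = a_seq[:a] + ins + b_seq[b:]
        chroms[e.chrom2] = b_seq[:b] + a_seq[a:]
    return AnnotatedGenome(chroms, [])


# ---------------------------------------------------------------------------
# truth serialization


def truth_to_calls(genome: AnnotatedGenome, truths: list[ColonyTruth]) -> list[VariantCall]:
    """Convert truth edits to VCF-shaped VariantCall records.

    Indels become explicit left-anchored alleles, inversions symbolic
    ``<INV>`` records, truncations single breakends with the appended
    telomere sequence, and rearrangements two reciprocal breakend pairs
    (four BND records linked by MATEID).
    """
    calls: list[VariantCall] = []
    for truth in truths:
        for k, e in enumerate(t for t in truth.edits if t.edit_class != EditClass.NONE):
            stem = f"{truth.colony_id}_e{k+1}"
            if e.edit_class in (EditClass.SMALL_INDEL, EditClass.LARGE_INDEL):
                vtype = (
                    VariantType.SV
                    if abs(e.net_length_change) >= 50
                    else (VariantType.INS if e.net_length_change > 0 else VariantType.DEL)
                )
                calls.append(
                    VariantCall(
                        stem, truth.pool_id, e.chrom, e.position, e.ref, e.alt,
                        vtype, e.net_length_change, colony_id=truth.colony_id,
                    )
                )
            elif e.edit_class == EditClass.INVERSION:
                anchor = genome.fetch(e.chrom, e.position, e.position)
                calls.append(
                    VariantCall(
                        stem, truth.pool_id, e.chrom, e.position, anchor, "<INV>",
                        VariantType.SV, 0, colony_id=truth.colony_id,
                        end=e.end, sv_type="INV",
                    )
                )
            elif e.edit_class == EditClass.TRUNCATION:
                anchor = genome.fetch(e.chrom, e.position, e.position)
                pair = BreakendPair(
                    BreakendLocus(e.chrom, e.position, RIGHT_OPEN), None,
                    inserted_sequence=e.inserted_sequence, partner_linked=False,
                )
                calls.append(
                    VariantCall(
                        stem, truth.pool_id, e.chrom, e.position, anchor,
                        anchor + e.inserted_sequence + ".",
                        VariantType.SV, e.net_length_change,
                        colony_id=truth.colony_id, sv_type="BND", breakend=pair,
                    )
                )
            elif e.edit_class == EditClass.REARRANGEMENT:
                calls.extend(_rearrangement_calls(genome, truth, stem, e))
    return calls


def _rearrangement_calls(
    genome: AnnotatedGenome, truth: ColonyTruth, stem: str, e: EditEvent
) -> list[VariantCall]:
    a_chrom, a = e.chrom, e.position
    b_chrom, b = e.chrom2, e.position2
    ins = e.inserted_sequence
    junctions = [
        # derivative 1: left of a joined to right of b+1
        (f"{stem}a1", a_chrom, a, RIGHT_OPEN, b_chrom, b + 1, LEFT_OPEN, f"{stem}a2"),
        (f"{stem}a2", b_chrom, b + 1, LEFT_OPEN, a_chrom, a, RIGHT_OPEN, f"{stem}a1"),
        # derivative 2: left of b joined to right of a+1
        (f"{stem}b1", b_chrom, b, RIGHT_OPEN, a_chrom, a + 1, LEFT_OPEN, f"{stem}b2"),
        (f"{stem}b2", a_chrom, a + 1, LEFT_OPEN, b_chrom, b, RIGHT_OPEN, f"{stem}b1"),
    ]
    calls = []
    for vid, chrom, pos, orient, pchrom, ppos, porient, mate in junctions:
        ref = genome.fetch(chrom, pos, pos)
        partner = BreakendLocus(pchrom, ppos, porient)
        alt = bnd_alt_string(ref, orient, partner, ins)
        calls.append(
            VariantCall(
                vid, truth.pool_id, chrom, pos, ref, alt, VariantType.SV, 0,
                colony_id=truth.colony_id, sv_type="BND", mate_id=mate,
                breakend=BreakendPair(BreakendLocus(chrom, pos, orient), partner, ins),
            )
        )
    return calls


_MANIFEST_COLS = [
    "colony_id", "pool_id", "class", "target_id", "chrom", "position", "end",
    "chrom2", "position2", "net_length_change", "telomere_capped", "ref", "alt",
    "inserted_sequence",
]


def write_truth_manifest(truths: list[ColonyTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for t in truths:
            for e in t.edits:
                row = [
                    t.colony_id, t.pool_id, e.edit_class.value, e.target_id,
                    e.chrom, str(e.position), str(e.end or ""),
                    e.chrom2 or "", str(e.position2 or ""),
                    str(e.net_length_change), str(e.telomere_capped).lower(),
                    e.ref, e.alt, e.inserted_sequence,
                ]
                fh.write("\t".join(row) + "\n")


def read_truth_manifest(path: str | Path) -> list[ColonyTruth]:
    truths: dict[str, ColonyTruth] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            t = truths.setdefault(
                row["colony_id"], ColonyTruth(row["colony_id"], row["pool_id"])
            )
            t.edits.append(
                EditEvent(
                    EditClass(row["class"]), row["chrom"], int(row["position"]),
                    target_id=row["target_id"], ref=row["ref"], alt=row["alt"],
                    end=int(row["end"]) if row["end"] else None,
                    chrom2=row["chrom2"] or None,
                    position2=int(row["position2"]) if row["position2"] else None,
                    net_length_change=int(row["net_length_change"]),
                    telomere_capped=row["telomere_capped"] == "true",
                    inserted_sequence=row["inserted_sequence"],
                )
            )
    return list(truths.values())


# ---------------------------------------------------------------------------
# read simulation

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_IDX[_a] = _i
_IDX_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadSet:
    """Paired reads stored as byte matrices, with per-pair truth origin.

    ``mate1``/``mate2`` are (n, read_length) uint8 ASCII arrays; mate2 is
    the reverse-complement end of the fragment.  ``origin_*`` arrays give
    the source colony, chromosome and 1-based fragment start (or -1 /
    empty when reads were loaded from FASTQ and truth is unknown).
    """

    read_length: int
    mate1: np.ndarray
    mate2: np.ndarray
    colony_ids: list[str]
    chrom_ids: list[str]
    origin_colony: np.ndarray  # index into colony_ids, or -1
    origin_chrom: np.ndarray  # index into chrom_ids, or -1
    origin_pos: np.ndarray  # 1-based fragment start, or -1
    quality_char: str = "I"  # constant Phred 40

    @property
    def n_pairs(self) -> int:
        return self.mate1.shape[0]

    def pair(self, i: int) -> tuple[str, str, str]:
        """(read_id, mate1 sequence, mate2 sequence) for pair ``i``."""
        return (f"read{i:08d}", decode(self.mate1[i]), decode(self.mate2[i]))

    def origin(self, i: int) -> tuple[str, str, int]:
        ci, hi = int(self.origin_colony[i]), int(self.origin_chrom[i])
        return (
            self.colony_ids[ci] if ci >= 0 else "",
            self.chrom_ids[hi] if hi >= 0 else "",
            int(self.origin_pos[i]),
        )

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        """Paired gzip FASTQ; gzip mtime pinned to 0 for reproducibility."""
        qual = self.quality_char * self.read_length
        for path, mat, suffix in ((path1, self.mate1, "/1"), (path2, self.mate2, "/2")):
            raw = open(path, "wb")
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as fh:
                chunk: list[bytes] = []
                for i in range(self.n_pairs):
                    chunk.append(
                        f"@read{i:08d}{suffix}\n{decode(mat[i])}\n+\n{qual}\n".encode()
                    )
                    if len(chunk) >= 20000:
                        fh.write(b"".join(chunk))
                        chunk = []
                fh.write(b"".join(chunk))
            raw.close()

    @classmethod
    def from_fastq(cls, path1: str | Path, path2: str | Path) -> "ReadSet":
        """Load paired FASTQ (plain or gzip); truth origin is unknown."""
        def read_all(path):
            op = gzip.open if str(path).endswith(".gz") else open
            seqs = []
            with op(path, "rt") as fh:
                for i, line in enumerate(fh):
                    if i % 4 == 1:
                        seqs.append(line.strip().upper())
            return seqs

        s1, s2 = read_all(path1), read_all(path2)
        if len(s1) != len(s2):
            raise SimulationError("mate files differ in read count")
        rl = len(s1[0]) if s1 else 0
        m1 = np.vstack([encode(s) for s in s1]) if s1 else np.zeros((0, 0), np.uint8)
        m2 = np.vstack([encode(s) for s in s2]) if s2 else np.zeros((0, 0), np.uint8)
        n = len(s1)
        return cls(
            rl, m1, m2, [], [],
            np.full(n, -1), np.full(n, -1), np.full(n, -1),
        )


def simulate_pool_reads(
    genomes: list[AnnotatedGenome],
    coverage: float,
    read_length: int = 150,
    fragment_mean: int = 550,
    fragment_sd: float | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    colony_ids: list[str] | None = None,
) -> ReadSet:
    """Paired-end reads from an equal-share pool of edited genomes.

    Fragments are drawn uniformly along each genome with Normal(mean,
    sd) lengths; mate1 reads the fragment 5' end on the top strand,
    mate2 the 3' end reverse-complemented.  Substitution errors are
    applied at ``error_rate`` per base; qualities are constant.
    """
    if not 1 <= len(genomes) <= 5:
        raise SimulationError("pool size must be 1..5 genomes")
    if coverage <= 0:
        raise SimulationError("coverage must be positive")
    if fragment_mean < read_length:
        raise SimulationError("read length exceeds fragment size")
    if fragment_mean < 2 * read_length:
        import warnings

        warnings.warn("fragment shorter than 2x read length: inner mates overlap")
    if fragment_sd is None:
        fragment_sd = 0.1 * fragment_mean
    rng = np.random.default_rng(seed)
    if colony_ids is None:
        colony_ids = [f"g{i+1}" for i in range(len(genomes))]

    mean_len = float(np.mean([sum(len(s) for s in g.chromosomes.values()) for g in genomes]))
    n_pairs = int(round(coverage * mean_len / (2 * read_length)))
    chrom_ids = sorted({c for g in genomes for c in g.chromosomes})
    chrom_index = {c: i for i, c in enumerate(chrom_ids)}

    colony = rng.integers(0, len(genomes), size=n_pairs)
    frag = np.clip(
        np.rint(rng.normal(fragment_mean, fragment_sd, size=n_pairs)).astype(np.int64),
        read_length, None,
    )
    mate1 = np.empty((n_pairs, read_length), dtype=np.uint8)
    mate2 = np.empty((n_pairs, read_length), dtype=np.uint8)
    origin_chrom = np.empty(n_pairs, dtype=np.int64)
    origin_pos = np.empty(n_pairs, dtype=np.int64)
    offsets = np.arange(read_length)

    for gi, g in enumerate(genomes):
        sel = np.flatnonzero(colony == gi)
        if sel.size == 0:
            continue
        names = list(g.chromosomes)
        lengths = np.array([len(g.chromosomes[n]) for n in names], dtype=float)
        which = rng.choice(len(names), size=sel.size, p=lengths / lengths.sum())
        for ki, name in enumerate(names):
            sub = sel[which == ki]
            if sub.size == 0:
                continue
            arr = encode(g.chromosomes[name])
            l_chrom = arr.size
            f = np.minimum(frag[sub], l_chrom)
            start0 = (rng.random(sub.size) * (l_chrom - f + 1)).astype(np.int64)
            mate1[sub] = arr[start0[:, None] + offsets]
            end0 = start0 + f  # exclusive fragment end
            mate2[sub] = _COMP[arr[(end0 - 1)[:, None] - offsets]]
            origin_chrom[sub] = chrom_index[name]
            origin_pos[sub] = start0 + 1

    # shuffle before error injection so the fragment layout (and hence
    # row order) is identical across runs differing only in error_rate
    perm = rng.permutation(n_pairs)
    mate1, mate2 = mate1[perm], mate2[perm]
    colony, origin_chrom, origin_pos = colony[perm], origin_chrom[perm], origin_pos[perm]

    if error_rate > 0:
        for mat in (mate1, mate2):
            mask = rng.random(mat.shape) < error_rate
            n_err = int(mask.sum())
            if n_err:
                shifted = (_BASE_IDX[mat[mask]].astype(np.int64) + rng.integers(1, 4, n_err)) % 4
                mat[mask] = _IDX_BASE[shifted]

    return ReadSet(
        read_length, mate1, mate2, list(colony_ids), chrom_ids,
        colony, origin_chrom, origin_pos,
    )
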