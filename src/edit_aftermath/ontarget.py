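"""On-target genotype reconstruction, read support and SV junction signatures.

The quantification path mirrors an amplicon-style analysis done on
whole-genome reads: reconstruct one local mutant sequence per distinct
variant at a target locus (plus the wildtype window), assign each read
to the unique best-matching genotype sequence, count only reads that
span the variant position, and report relative read support per
genotype and per outcome class.  Targeting efficiency is the summed
relative support of all non-wildtype genotypes, i.e. ``1 - support(WT)``.

Genotype classes follow the outcome taxonomy used for CRISPR repair
spectra: ``WT``; ``in-frame`` and ``frameshift`` indels (< 50 bp, by
net length mod 3); ``SV`` (indels >= 50 bp, inversions, duplications,
translocations and other breakend junctions); plus ``substitution``
for on-target SNVs, reported separately.

Two junction-level signatures are detected: imperfect microhomology
between the flanks of an SV junction (an MMEJ hallmark) and de novo
telomere repeats appended at one-sided breakends (telomere-capped
chromosome truncation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dna import decode, encode, revcomp
from .genome import AnnotatedGenome
from .guides import Guide
from .simulate import ReadSet
from .variants import (
    LEFT_OPEN,
    RIGHT_OPEN,
    BreakendLocus,
    BreakendPair,
    VariantCall,
    VariantType,
)

CLASS_WT = "WT"
CLASS_IN_FRAME = "in-frame"
CLASS_FRAMESHIFT = "frameshift"
CLASS_SV = "SV"
CLASS_SUBSTITUTION = "substitution"


@dataclass(frozen=True)
class Classification:
    label: str
    frame_preserved: bool


def classify_genotype(
    net_length_change: int,
    variant_type: VariantType | None = None,
    breakend: BreakendPair | None = None,
) -> Classification:
    """Outcome class for one variant.

    Exactly one of an indel/SNV description (``variant_type`` plus net
    length change) or a ``breakend`` must be supplied.  Any breakend
    junction is an SV; explicit indels are SVs from 50 bp net change,
    in-frame/frameshift below; SNVs are substitutions; a zero net
    change with no breakend is wildtype.  ``frame_preserved`` reports
    whether the net change is a multiple of 3 (meaningful for SVs such
    as a 57 bp in-frame deletion).
    """
    frame = net_length_change % 3 == 0
    if breakend is not None:
        return Classification(CLASS_SV, frame)
    if variant_type is None:
        raise ValueError("need a variant type or a breakend")
    if variant_type == VariantType.SNV:
        if net_length_change != 0:
            raise ValueError("SNV with non-zero length change")
        return Classification(CLASS_SUBSTITUTION, True)
    if variant_type == VariantType.SV or abs(net_length_change) >= 50:
        return Classification(CLASS_SV, frame)
    if net_length_change == 0:
        return Classification(CLASS_WT, True)
    return Classification(CLASS_IN_FRAME if frame else CLASS_FRAMESHIFT, frame)


@dataclass
class GenotypeModel:
    """A reconstructed local sequence for one genotype at one target."""

    genotype_id: str
    target_id: str
    class_label: str
    local_sequence: str
    variant_position: int  # 1-based within local_sequence
    source_variant_id: str | None = None  # None for WT
    frame_preserved: bool = True
    colony_id: str | None = None


# ---------------------------------------------------------------------------
# genotype reconstruction


def reconstruct_genotype_sequences(
    genome: AnnotatedGenome,
    target: Guide,
    variants: list[VariantCall],
    flank: int = 1000,
) -> list[GenotypeModel]:
    """One local model per distinct variant at a target, plus wildtype.

    The wildtype model is the reference window ``flank`` bases either
    side of the cut locus.  Small-variant models apply the variant
    within that window; models for deletions or inversions reaching
    past the window keep ``flank`` bases of context on each side of the
    junction; breakend models concatenate the two partner flanks in
    junction orientation (plus any inserted sequence).  Models with
    identical (or reverse-complement-identical) sequences collapse with
    a warning.
    """
    chrom = target.chrom
    l_chrom = genome.chrom_length(chrom)
    cut = target.cut_locus
    ws, we = max(1, cut - flank), min(l_chrom, cut + flank)
    models = [
        GenotypeModel(
            f"{target.guide_id}_WT", target.guide_id, CLASS_WT,
            genome.fetch(chrom, ws, we), cut - ws + 1,
        )
    ]
    for v in variants:
        models.append(_variant_model(genome, target, v, flank, ws, we))
    # collapse duplicate sequences (orientation-agnostic)
    seen: dict[str, str] = {}
    kept: list[GenotypeModel] = []
    for m in models:
        key = min(m.local_sequence, revcomp(m.local_sequence))
        if key in seen:
            warnings.warn(
                f"{m.genotype_id} duplicates {seen[key]}; collapsing"
            )
            continue
        seen[key] = m.genotype_id
        kept.append(m)
    return kept


def _variant_model(
    genome: AnnotatedGenome,
    target: Guide,
    v: VariantCall,
    flank: int,
    ws: int,
    we: int,
) -> GenotypeModel:
    chrom = target.chrom
    l_chrom = genome.chrom_length(chrom)
    gid = f"{target.guide_id}_{v.variant_id}"

    if v.breakend is not None:
        if not v.breakend.partner_linked:
            seq_a, clipped = _segment_toward_junction(genome, v.breakend.locus_a, flank)
            local = seq_a + v.breakend.inserted_sequence
            vpos = len(seq_a)
        else:
            be = v.breakend
            seq_a, _ = _segment_toward_junction(genome, be.locus_a, flank)
            seq_b, _ = _segment_from_junction(genome, be.locus_b, flank)
            local = seq_a + be.inserted_sequence + seq_b
            vpos = len(seq_a)
        cls = classify_genotype(v.net_length_change, v.var_type, v.breakend)
        return GenotypeModel(gid, target.guide_id, cls.label, local, vpos,
                             v.variant_id, cls.frame_preserved, v.colony_id)

    if v.chrom != chrom or not (cut_in := abs(v.pos - target.cut_locus)) <= flank:
        raise ValueError(
            f"{v.variant_id} at {v.chrom}:{v.pos} is not within {flank} bp "
            f"of target {target.guide_id}"
        )

    if v.alt == "<INV>":
        inv_start, inv_end = v.pos + 1, v.end
        left = genome.fetch(chrom, ws, v.pos)
        inv = revcomp(genome.fetch(chrom, inv_start, inv_end))
        right_end = min(l_chrom, inv_end + flank)
        right = genome.fetch(chrom, inv_end + 1, right_end) if inv_end < right_end else ""
        if inv_end > we:  # keep model comparable in reach to the others
            inv = inv[: we - v.pos]
            right = ""
        cls = classify_genotype(0, VariantType.SV)
        return GenotypeModel(gid, target.guide_id, cls.label,
                             left + inv + right, v.pos - ws + 1,
                             v.variant_id, cls.frame_preserved, v.colony_id)

    # explicit-allele SNV or indel (any size)
    ref_end = v.pos + len(v.ref) - 1
    left = genome.fetch(chrom, ws, v.pos - 1) if v.pos > ws else ""
    right_start = ref_end + 1
    right_end = we if ref_end <= we else min(l_chrom, ref_end + flank)
    right = genome.fetch(chrom, right_start, right_end) if right_start <= right_end else ""
    local = left + v.alt + right
    cls = classify_genotype(v.net_length_change, v.var_type)
    return GenotypeModel(gid, target.guide_id, cls.label, local, v.pos - ws + 1,
                         v.variant_id, cls.frame_preserved, v.colony_id)


def _segment_toward_junction(
    genome: AnnotatedGenome, locus: BreakendLocus, flank: int
) -> tuple[str, bool]:
    """Flank of a breakend read 5'->3' *ending* at the junction."""
    l_chrom = genome.chrom_length(locus.chrom)
    if locus.orientation == RIGHT_OPEN:
        start = max(1, locus.pos - flank + 1)
        return genome.fetch(locus.chrom, start, locus.pos), start == 1
    end = min(l_chrom, locus.pos + flank - 1)
    return revcomp(genome.fetch(locus.chrom, locus.pos, end)), end == l_chrom


def _segment_from_junction(
    genome: AnnotatedGenome, locus: BreakendLocus, flank: int
) -> tuple[str, bool]:
    """Flank of a breakend read 5'->3' *starting* at the junction."""
    l_chrom = genome.chrom_length(locus.chrom)
    if locus.orientation == LEFT_OPEN:
        end = min(l_chrom, locus.pos + flank - 1)
        return genome.fetch(locus.chrom, locus.pos, end), end == l_chrom
    start = max(1, locus.pos - flank + 1)
    return revcomp(genome.fetch(locus.chrom, start, locus.pos)), start == 1


# ---------------------------------------------------------------------------
# read assignment

_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_IDX[_a] = _i


@dataclass
class ReadAssignment:
    """Per-model read tallies from :func:`assign_reads`."""

    models: list[GenotypeModel]
    counted: dict[str, int]  # genotype_id -> reads spanning the variant
    assigned: dict[str, int]  # genotype_id -> all uniquely assigned reads
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_not_covering: int = 0


def _pack_kmers(mat: np.ndarray, offsets: list[int], k: int) -> np.ndarray:
    """(n, len(offsets)) uint64 2-bit packed k-mers; invalid -> max uint64."""
    n = mat.shape[0]
    out = np.empty((n, len(offsets)), dtype=np.uint64)
    pow4 = (4 ** np.arange(k, dtype=np.uint64))[::-1]
    for j, off in enumerate(offsets):
        codes = _BASE_IDX[mat[:, off : off + k]].astype(np.uint64)
        bad = (codes == 255).any(axis=1)
        vals = codes @ pow4
        vals[bad] = np.uint64(2**64 - 1)
        out[:, j] = vals
    return out


def _kmer_int(seq: str, k: int) -> int | None:
    val = 0
    for ch in seq:
        i = _BASE_IDX[ord(ch)]
        if i == 255:
            return None
        val = val * 4 + int(i)
    return val


def assign_reads(
    reads: ReadSet,
    models: list[GenotypeModel],
    max_mismatches_per_read: int = 4,
    min_overlap: int = 5,
    seed_k: int = 20,
) -> ReadAssignment:
    """Assign each read to the unique best-matching genotype model.

    Matching is gapless: a read matches a model at an offset found by
    exact ``seed_k``-mer seeding, scored by Hamming distance over the
    full read (both orientations tried).  Reads tying across two or
    more models at their best score are discarded as ambiguous; reads
    exceeding ``max_mismatches_per_read`` everywhere are unassigned.
    An assigned read is *counted* only when it spans the model's
    variant position with at least ``min_overlap`` bases on each side.
    """
    rl = reads.read_length
    if rl < seed_k:
        raise ValueError("reads shorter than the seed k-mer")
    # seed index over model sequences (forward orientation)
    index: dict[int, list[tuple[int, int]]] = {}
    model_arrs = []
    filter_kmers: set[int] = set()
    for mi, m in enumerate(models):
        seq = m.local_sequence
        model_arrs.append(encode(seq))
        for pos in range(0, len(seq) - seed_k + 1):
            val = _kmer_int(seq[pos : pos + seed_k], seed_k)
            if val is not None:
                index.setdefault(val, []).append((mi, pos))
                filter_kmers.add(val)
        for pos in range(0, len(seq) - seed_k + 1):
            val = _kmer_int(revcomp(seq)[pos : pos + seed_k], seed_k)
            if val is not None:
                filter_kmers.add(val)

    probe_offsets = sorted({0, (rl - seed_k) // 2, rl - seed_k})
    filter_arr = np.fromiter(filter_kmers, dtype=np.uint64, count=len(filter_kmers))
    filter_arr.sort()

    counted = {m.genotype_id: 0 for m in models}
    assigned = {m.genotype_id: 0 for m in models}
    result = ReadAssignment(models, counted, assigned)

    for mat in (reads.mate1, reads.mate2):
        if mat.size == 0:
            continue
        packed = _pack_kmers(mat, probe_offsets, seed_k)
        pos_in_sorted = np.searchsorted(filter_arr, packed)
        pos_in_sorted[pos_in_sorted >= filter_arr.size] = filter_arr.size - 1
        is_hit = (filter_arr[pos_in_sorted] == packed).any(axis=1) if filter_arr.size else np.zeros(mat.shape[0], bool)
        for ri in np.flatnonzero(is_hit):
            _assign_one(
                mat[int(ri)], models, model_arrs, index, probe_offsets, seed_k,
                max_mismatches_per_read, min_overlap, result,
            )
    # reads that never touch the prefilter (genome background far from any
    # target window) are silent rather than "unassigned"
    return result


def _assign_one(
    read_row: np.ndarray,
    models: list[GenotypeModel],
    model_arrs: list[np.ndarray],
    index: dict[int, list[tuple[int, int]]],
    probe_offsets: list[int],
    seed_k: int,
    max_mm: int,
    min_overlap: int,
    result: ReadAssignment,
) -> None:
    rl = read_row.size
    best: dict[int, tuple[int, int]] = {}  # model -> (mismatches, offset0)
    for arr in (read_row, encode(revcomp(decode(read_row)))):
        seq = decode(arr)
        for off in probe_offsets:
            val = _kmer_int(seq[off : off + seed_k], seed_k)
            if val is None:
                continue
            for mi, mpos in index.get(val, ()):  # candidate alignment
                o = mpos - off
                marr = model_arrs[mi]
                if o < 0 or o + rl > marr.size:
                    continue
                mm = int((marr[o : o + rl] != arr).sum())
                if mi not in best or mm < best[mi][0]:
                    best[mi] = (mm, o)
    if not best:
        result.n_unassigned += 1
        return
    best_mm = min(mm for mm, _ in best.values())
    if best_mm > max_mm:
        result.n_unassigned += 1
        return
    winners = [mi for mi, (mm, _) in best.items() if mm == best_mm]
    if len(winners) > 1:
        result.n_ambiguous += 1
        return
    mi = winners[0]
    o = best[mi][1]
    model = models[mi]
    result.assigned[model.genotype_id] += 1
    vpos = model.variant_position
    left = vpos - (o + 1) + 1
    right = (o + rl) - vpos + 1
    if left >= min_overlap and right >= min_overlap:
        result.counted[model.genotype_id] += 1
    else:
        result.n_not_covering += 1


# ---------------------------------------------------------------------------
# support tables


@dataclass
class SupportRow:
    target_id: str
    genotype_id: str
    class_label: str
    reads: int
    relative_support: float
    minor_genotype: bool


@dataclass
class SupportTable:
    """Per-genotype and per-class relative read support for one target."""

    target_id: str
    rows: list[SupportRow]
    targeting_efficiency: float | None  # None when no coverage
    discarded_ambiguous: int
    discarded_unassigned: int
    discarded_not_covering: int
    no_coverage: bool = False

    def class_support(self) -> dict[str, float]:
        agg: dict[str, float] = {}
        for r in self.rows:
            agg[r.class_label] = agg.get(r.class_label, 0.0) + r.relative_support
        return agg

    def distinct_genotypes(self) -> dict[str, int]:
        agg: dict[str, int] = {}
        for r in self.rows:
            if r.reads > 0:
                agg[r.class_label] = agg.get(r.class_label, 0) + 1
        return agg


def support_table(
    assignment: ReadAssignment,
    min_reads_minor: int = 5,
) -> SupportTable:
    """Relative read support over retained (variant-spanning) reads.

    Fractions are computed over counted reads only and sum to 1;
    genotypes below ``min_reads_minor`` reads are flagged as minor
    rather than dropped.  With zero retained reads the table carries an
    explicit no-coverage flag and no fractions.
    """
    models = assignment.models
    target_id = models[0].target_id if models else ""
    total = sum(assignment.counted.values())
    if total == 0:
        return SupportTable(
            target_id, [], None,
            assignment.n_ambiguous, assignment.n_unassigned,
            assignment.n_not_covering, no_coverage=True,
        )
    rows = []
    wt_frac = 0.0
    for m in models:
        n = assignment.counted[m.genotype_id]
        frac = n / total
        if m.class_label == CLASS_WT:
            wt_frac += frac
        rows.append(
            SupportRow(m.target_id, m.genotype_id, m.class_label, n, frac,
                       minor_genotype=0 < n < min_reads_minor)
        )
    return SupportTable(
        target_id, rows, 1.0 - wt_frac,
        assignment.n_ambiguous, assignment.n_unassigned,
        assignment.n_not_covering,
    )


def write_support_tsv(tables: list[SupportTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\tgenotype_id\tclass\treads\trelative_support\tminor\n")
        for t in tables:
            for r in t.rows:
                fh.write(
                    f"{r.target_id}\t{r.genotype_id}\t{r.class_label}\t{r.reads}\t"
                    f"{r.relative_support:.6f}\t{str(r.minor_genotype).lower()}\n"
                )


def write_class_support_tsv(tables: list[SupportTable], path: str | Path) -> None:
    """Per-class stacked-bar data: support fraction and distinct genotypes."""
    with open(path, "w") as fh:
        fh.write("target_id\tclass\trelative_support\tdistinct_genotypes\t"
                 "targeting_efficiency\n")
        for t in tables:
            eff = "" if t.targeting_efficiency is None else f"{t.targeting_efficiency:.6f}"
            counts = t.distinct_genotypes()
            for cls, frac in sorted(t.class_support().items()):
                fh.write(
                    f"{t.target_id}\t{cls}\t{frac:.6f}\t{counts.get(cls, 0)}\t{eff}\n"
                )


# ---------------------------------------------------------------------------
# junction signatures


@dataclass(frozen=True)
class MicrohomologyCall:
    junction_id: str
    mh_length: int
    mh_mismatches: int
    mh_sequence_a: str
    mh_sequence_b: str
    clipped: bool = False


def detect_microhomology(
    junction: BreakendPair,
    genome: AnnotatedGenome,
    max_window: int = 25,
    max_mismatches: int = 2,
    junction_id: str = "junction",
) -> MicrohomologyCall:
    """Longest imperfect homology between the two flanks of a junction.

    Reports the largest window length L <= ``max_window`` such that the
    L reference bases continuing past the break on side A agree with
    the first L retained bases of side B with at most
    ``max_mismatches`` mismatches (both read in junction orientation) —
    the repair-template relationship expected under MMEJ.  Windows
    clipped by a chromosome end are flagged.
    """
    if not junction.partner_linked or junction.locus_b is None:
        raise ValueError("microhomology needs both junction partners")
    seq_a, clip_a = _continuation_past_break(genome, junction.locus_a, max_window)
    seq_b, clip_b = _segment_from_junction(genome, junction.locus_b, max_window)
    n = min(len(seq_a), len(seq_b))
    best_len, best_mm = 0, 0
    mism = 0
    for i in range(n):
        if seq_a[i] != seq_b[i]:
            mism += 1
        if mism <= max_mismatches:
            best_len, best_mm = i + 1, mism
        else:
            break
    return MicrohomologyCall(
        junction_id, best_len, best_mm,
        seq_a[:best_len], seq_b[:best_len],
        clipped=clip_a or clip_b or n < max_window,
    )


def _continuation_past_break(
    genome: AnnotatedGenome, locus: BreakendLocus, window: int
) -> tuple[str, bool]:
    """Reference sequence continuing beyond the break, junction direction."""
    l_chrom = genome.chrom_length(locus.chrom)
    if locus.orientation == RIGHT_OPEN:
        end = min(l_chrom, locus.pos + window)
        seq = genome.fetch(locus.chrom, locus.pos + 1, end) if locus.pos < l_chrom else ""
        return seq, end == l_chrom and len(seq) < window
    start = max(1, locus.pos - window)
    seq = genome.fetch(locus.chrom, start, locus.pos - 1) if locus.pos > 1 else ""
    return revcomp(seq), start == 1 and len(seq) < window


@dataclass(frozen=True)
class TruncationCall:
    chrom: str
    truncation_position: int  # last retained base
    telomere_motif_copies: int
    evidence: str  # "one-sided-breakend" or "clipped-read-consensus"


def tandem_motif_copies(seq: str, motif: str) -> int:
    """Longest tandem run of ``motif`` in ``seq`` (final copy may be partial)."""
    m = len(motif)
    best = 0
    for s in range(len(seq)):
        full = 0
        i = s
        while seq[i : i + m] == motif:
            full += 1
            i += m
        partial = 0
        for p in range(min(m - 1, len(seq) - i), 0, -1):
            if seq[i : i + p] == motif[:p]:
                partial = p
                break
        # a trailing partial copy extends a run, but never starts one
        count = full + (1 if full and partial else 0)
        best = max(best, count)
    return best


def detect_truncation(
    junction: BreakendPair | None = None,
    telomere_motif: str | None = None,
    min_copies: int = 3,
    consensus: tuple[str, int, str] | None = None,
) -> TruncationCall | None:
    """Telomere-capped truncation call from one-sided junction evidence.

    Evidence is either a single breakend (appended sequence in
    ``inserted_sequence``) or a clipped-read consensus as
    ``(chrom, position, appended_sequence)``.  Positive iff the
    appended sequence carries at least ``min_copies`` tandem motif
    copies (final copy may be partial).
    """
    if telomere_motif is None or len(telomere_motif) < 4:
        raise ValueError("telomere motif must be at least 4 nt")
    if junction is not None:
        if junction.partner_linked:
            return None  # two-sided junctions are not truncations
        chrom = junction.locus_a.chrom
        pos = junction.locus_a.pos
        appended = junction.inserted_sequence
        evidence = "one-sided-breakend"
    elif consensus is not None:
        chrom, pos, appended = consensus
        evidence = "clipped-read-consensus"
    else:
        raise ValueError("need a junction or a clipped-read consensus")
    copies = tandem_motif_copies(appended, telomere_motif)
    if copies >= min_copies:
        return TruncationCall(chrom, pos, copies, evidence)
    return None


def write_microhomology_tsv(calls: list[MicrohomologyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("junction_id\tmh_length\tmh_mismatches\tseq_a\tseq_b\tclipped\n")
        for c in calls:
            fh.write(
                f"{c.junction_id}\t{c.mh_length}\t{c.mh_mismatches}\t"
                f"{c.mh_sequence_a}\t{c.mh_sequence_b}\t{str(c.clipped).lower()}\n"
            )


def write_truncation_tsv(calls: list[TruncationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\ttruncation_position\ttelomere_motif_copies\tevidence\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.truncation_position}\t{c.telomere_motif_copies}\t"
                f"{c.evidence}\n"
            )


def write_genotypes_fasta(models: list[GenotypeModel], path: str | Path) -> None:
    """Genotype multi-FASTA, the reference set reads are assigned against."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.genotype_id} class={m.class_label} vpos={m.variant_position}\n")
            seq = m.local_sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
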