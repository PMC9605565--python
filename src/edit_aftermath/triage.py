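"""Candidate de-novo-mutation (DNM) triage.

Raw variant calls against the reference contain, besides true editing
outcomes, every difference the *base strain* already carried, recurrent
artefacts seen across unrelated experiments, and (optionally) calls in
a reference-error blacklist.  Triage assigns every call exactly one
fate:

``pre-existing``  -> present in the base-strain call set
``blacklisted``   -> inside a reference-error blacklist interval
``recurrent``     -> seen across experiments with distinct guides
``low-support``   -> below the pooled-sample read-support gate
``dnm-on-target`` -> candidate DNM at a guide cut locus
``dnm-off-target``-> candidate DNM elsewhere

and aggregates the survivors into a per-sample ledger split by variant
type (SNV / InDel / SV), with off-target DNMs further annotated for
coding effect and for proximity to a potential CRISPR binding site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from intervaltree import IntervalTree

from .genome import AnnotatedGenome
from .guides import Guide
from .offtarget import OVERLAPS_SITE, SiteVariantHit
from .variants import BreakendPair, VariantCall, VariantType

FATE_PREEXISTING = "pre-existing"
FATE_BLACKLISTED = "blacklisted"
FATE_RECURRENT = "recurrent"
FATE_LOW_SUPPORT = "low-support"
FATE_ON_TARGET = "dnm-on-target"
FATE_OFF_TARGET = "dnm-off-target"

_TYPE_BUCKET = {
    VariantType.SNV: "SNV",
    VariantType.INS: "InDel",
    VariantType.DEL: "InDel",
    VariantType.SV: "SV",
}


# ---------------------------------------------------------------------------
# base-strain subtraction


def _breakend_signature(call: VariantCall):
    if call.breakend is None:
        return None
    a = call.breakend.locus_a
    b = call.breakend.locus_b
    return (a.chrom, a.pos, a.orientation,
            b.chrom if b else None, b.pos if b else None,
            b.orientation if b else None)


def _sv_matches(a: VariantCall, b: VariantCall, tol: int) -> bool:
    """SV identity within a positional tolerance per breakend/end."""
    sig_a, sig_b = _breakend_signature(a), _breakend_signature(b)
    if (sig_a is None) != (sig_b is None):
        return False
    if sig_a is not None:
        (ca, pa, oa, ca2, pa2, oa2) = sig_a
        (cb, pb, ob, cb2, pb2, ob2) = sig_b
        if (ca, oa, ca2, oa2) != (cb, ob, cb2, ob2):
            return False
        if abs(pa - pb) > tol:
            return False
        if pa2 is not None and abs(pa2 - pb2) > tol:
            return False
        return True
    # symbolic or explicit-allele SVs: same chrom & type, loci within tol
    if a.chrom != b.chrom or a.sv_type != b.sv_type:
        return False
    if abs(a.pos - b.pos) > tol:
        return False
    ea = a.end if a.end is not None else a.pos + len(a.ref) - 1
    eb = b.end if b.end is not None else b.pos + len(b.ref) - 1
    if abs(ea - eb) > tol:
        return False
    if a.end is None and b.end is None and (a.ref, a.alt) != (b.ref, b.alt):
        return False
    return True


def subtract_base_strain(
    calls: list[VariantCall],
    base_strain_calls: list[VariantCall],
    sv_tolerance: int = 10,
) -> list[VariantCall]:
    """Remove calls already present in the base strain.

    Small variants match on exact (chrom, pos, ref, alt); SVs match on
    breakend loci (or symbolic spans) within ``sv_tolerance`` bp.
    Idempotent: applying it twice equals applying it once.
    """
    base_small = {c.key for c in base_strain_calls if c.var_type != VariantType.SV}
    base_svs = [c for c in base_strain_calls if c.var_type == VariantType.SV]
    kept: list[VariantCall] = []
    for c in calls:
        if c.var_type != VariantType.SV:
            if c.key not in base_small:
                kept.append(c)
        elif not any(_sv_matches(c, b, sv_tolerance) for b in base_svs):
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# recurrence filtering


def drop_recurrent(
    calls_by_experiment: dict[str, list[VariantCall]],
    min_experiments: int = 2,
    require_distinct_guides: bool = True,
    experiment_guides: dict[str, set[str]] | None = None,
) -> tuple[dict[str, list[VariantCall]], list[dict]]:
    """Remove variants recurring across experiments with distinct guides.

    A variant is removed everywhere when it occurs in at least
    ``min_experiments`` experiments among which (if required) a subset
    of that size exists whose guide sets are pairwise disjoint — i.e.
    the recurrence cannot be explained by one shared guide.  Returns
    the filtered mapping plus a log of removals with their occurrence
    lists.
    """
    experiment_guides = experiment_guides or {}
    occurrences: dict[tuple, list[str]] = {}
    for exp_id, calls in calls_by_experiment.items():
        for c in calls:
            occurrences.setdefault(c.key, [])
            if exp_id not in occurrences[c.key]:
                occurrences[c.key].append(exp_id)
    removed_keys = set()
    log: list[dict] = []
    for key, exps in occurrences.items():
        if len(exps) < min_experiments:
            continue
        if require_distinct_guides:
            guide_sets = [experiment_guides.get(e, set()) for e in exps]
            ok = any(
                all(ga.isdisjoint(gb) for ga, gb in combinations(combo, 2))
                for combo in combinations(guide_sets, min_experiments)
            )
            if not ok:
                continue
        removed_keys.add(key)
        log.append({"key": key, "experiments": list(exps)})
    filtered = {
        exp_id: [c for c in calls if c.key not in removed_keys]
        for exp_id, calls in calls_by_experiment.items()
    }
    return filtered, log


# ---------------------------------------------------------------------------
# annotation and classification


def annotate_coding_effect(
    call: VariantCall, genome: AnnotatedGenome
) -> tuple[str, str]:
    """(coding|non-coding, frame effect) for a variant.

    Coding iff the reference span intersects any CDS interval; the
    frame effect applies to coding indels only: ``in-frame`` when the
    net length change is a multiple of 3, ``frameshift`` otherwise.
    """
    vs, ve = call.ref_span
    coding = any(
        g.chrom == call.chrom and g.start <= ve and vs <= g.end
        for g in genome.genes
    )
    if not coding:
        return ("non-coding", "none")
    if call.var_type in (VariantType.INS, VariantType.DEL) or (
        call.var_type == VariantType.SV
        and call.breakend is None
        and call.net_length_change != 0
    ):
        frame = "in-frame" if call.net_length_change % 3 == 0 else "frameshift"
    else:
        frame = "none"
    return ("coding", frame)


def classify_on_vs_off_target(
    call: VariantCall,
    guides: list[Guide],
    on_target_radius: int = 100,
) -> str:
    """on-target iff the variant lies within the radius of any cut locus.

    Breakend calls are on-target when either partner locus falls within
    the radius of a cut site (a rearrangement joining two target loci
    counts as on-target at both).
    """
    loci = [(g.chrom, g.cut_locus) for g in guides]

    def near(chrom: str, s: int, e: int) -> bool:
        return any(c == chrom and s - on_target_radius <= p <= e + on_target_radius
                   for c, p in loci)

    if call.breakend is not None:
        be: BreakendPair = call.breakend
        if near(be.locus_a.chrom, be.locus_a.pos, be.locus_a.pos):
            return "on-target"
        if be.locus_b is not None and near(be.locus_b.chrom, be.locus_b.pos, be.locus_b.pos):
            return "on-target"
        return "off-target"
    vs, ve = call.ref_span
    return "on-target" if near(call.chrom, vs, ve) else "off-target"


def load_blacklist(path: str | Path) -> dict[str, IntervalTree]:
    """Reference-error blacklist from a BED file (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start) + 1, int(end) + 1)
    return trees


def filter_low_support(
    calls: list[VariantCall],
    depth: float,
    min_fraction: float = 0.1,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Gate pooled-sample calls on supporting-read fraction of depth.

    The default keeps calls supported by at least one tenth of the
    local depth — half the expected share of one colony in a pool of
    five.  Calls with no recorded support (truth VCFs) pass.
    """
    kept, dropped = [], []
    for c in calls:
        if c.supporting_reads and c.supporting_reads < min_fraction * depth:
            dropped.append(c)
        else:
            kept.append(c)
    return kept, dropped


# ---------------------------------------------------------------------------
# the ledger


@dataclass
class LedgerRow:
    """Counts for one (sample, variant bucket)."""

    sample_id: str
    bucket: str  # SNV / InDel / SV
    total_calls: int = 0
    dnms: int = 0
    on_target: int = 0
    off_target: int = 0
    coding_off_target: int = 0
    crispr_proximal_off_target: int = 0

    def check(self) -> None:
        assert self.dnms <= self.total_calls
        assert self.on_target + self.off_target == self.dnms
        assert self.coding_off_target <= self.off_target


@dataclass
class DnmLedger:
    rows: dict[tuple[str, str], LedgerRow] = field(default_factory=dict)
    fates: list[dict] = field(default_factory=list)

    def row(self, sample_id: str, bucket: str) -> LedgerRow:
        return self.rows.setdefault(
            (sample_id, bucket), LedgerRow(sample_id, bucket)
        )

    def validate(self) -> "DnmLedger":
        for r in self.rows.values():
            r.check()
        return self

    def totals(self) -> dict[str, int]:
        keys = ("total_calls", "dnms", "on_target", "off_target",
                "coding_off_target", "crispr_proximal_off_target")
        return {k: sum(getattr(r, k) for r in self.rows.values()) for k in keys}

    def write_tsv(self, path: str | Path) -> None:
        cols = ["sample_id", "variant_type", "total_calls", "dnms",
                "dnms_on_target", "dnms_off_target", "coding_off_target",
                "crispr_proximal_off_target"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for (sample, bucket) in sorted(self.rows):
                r = self.rows[(sample, bucket)]
                fh.write(
                    f"{sample}\t{bucket}\t{r.total_calls}\t{r.dnms}\t{r.on_target}\t"
                    f"{r.off_target}\t{r.coding_off_target}\t{r.crispr_proximal_off_target}\n"
                )

    def write_fate_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant_id\tsample_id\tchrom\tpos\ttype\tfate\tcoding\tframe\n")
            for f in self.fates:
                fh.write(
                    f"{f['variant_id']}\t{f['sample_id']}\t{f['chrom']}\t{f['pos']}\t"
                    f"{f['type']}\t{f['fate']}\t{f.get('coding','')}\t{f.get('frame','')}\n"
                )


def build_ledger(
    calls_by_sample: dict[str, list[VariantCall]],
    base_strain_calls: list[VariantCall],
    genome: AnnotatedGenome,
    guides_by_sample: dict[str, list[Guide]],
    site_variant_hits: list[SiteVariantHit] | None = None,
    blacklist: dict[str, IntervalTree] | None = None,
    on_target_radius: int = 100,
    sv_tolerance: int = 10,
    recurrence_log: list[dict] | None = None,
) -> DnmLedger:
    """Run the full triage for each sample and tally the ledger.

    Pass the *unfiltered* per-sample calls together with the removal
    log from :func:`drop_recurrent`: recurrent calls then count toward
    ``total_calls`` and receive the ``recurrent`` fate.  Every input
    call receives exactly one fate.
    """
    hit_ids = {h.variant_id for h in (site_variant_hits or [])}
    recurrent_keys = {tuple(r["key"]) for r in (recurrence_log or [])}
    ledger = DnmLedger()
    for sample_id, calls in sorted(calls_by_sample.items()):
        guides = guides_by_sample.get(sample_id, [])
        dnms = subtract_base_strain(calls, base_strain_calls, sv_tolerance)
        dnm_ids = {id(c) for c in dnms}
        for c in calls:
            bucket = _TYPE_BUCKET[c.var_type]
            row = ledger.row(sample_id, bucket)
            row.total_calls += 1
            fate_rec = {
                "variant_id": c.variant_id, "sample_id": sample_id,
                "chrom": c.chrom, "pos": c.pos, "type": bucket,
            }
            if id(c) not in dnm_ids:
                fate_rec["fate"] = FATE_PREEXISTING
                ledger.fates.append(fate_rec)
                continue
            if c.key in recurrent_keys:
                fate_rec["fate"] = FATE_RECURRENT
                ledger.fates.append(fate_rec)
                continue
            if blacklist is not None:
                vs, ve = c.ref_span
                tree = blacklist.get(c.chrom)
                if tree is not None and tree.overlap(vs, ve + 1):
                    fate_rec["fate"] = FATE_BLACKLISTED
                    ledger.fates.append(fate_rec)
                    continue
            side = classify_on_vs_off_target(c, guides, on_target_radius)
            coding, frame = annotate_coding_effect(c, genome)
            fate_rec["coding"], fate_rec["frame"] = coding, frame
            row.dnms += 1
            if side == "on-target":
                row.on_target += 1
                fate_rec["fate"] = FATE_ON_TARGET
            else:
                row.off_target += 1
                fate_rec["fate"] = FATE_OFF_TARGET
                if coding == "coding":
                    row.coding_off_target += 1
                if c.variant_id in hit_ids:
                    row.crispr_proximal_off_target += 1
            ledger.fates.append(fate_rec)
    return ledger.validate()
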