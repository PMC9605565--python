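"""Pipeline orchestration: config, stages, provenance and summary tables.

A single YAML config drives everything; every stage writes its outputs
under a run directory and records each file's SHA-256 in
``provenance.json`` (no wall-clock data, so reruns with identical
config and seed are hash-identical).  Stages:

``simulate``        reference genome + annotation, auto-designed target
                    guides, per-colony truth, pooled reads, truth and
                    base-strain VCFs
``design-guides``   guide enumeration/filtering + NE-region discovery
``scan-offtargets`` binding-site enumeration and variant intersection
``triage``          DNM filtering and the per-sample ledger
``quantify``        genotype reconstruction, read support, junction
                    signatures
``report``          summary tables (ledger shape + per-class support)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import guides as guides_mod
from . import offtarget as offtarget_mod
from . import ontarget as ontarget_mod
from . import simulate as simulate_mod
from . import triage as triage_mod
from .dna import random_dna
from .genome import AnnotatedGenome
from .guides import Guide
from .variants import VariantCall, VariantType, read_vcf, write_vcf

ALL_STAGES = ["simulate", "design-guides", "scan-offtargets", "triage", "quantify", "report"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated stage parameters for a full run."""

    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulate: dict = field(default_factory=dict)
    guides: dict = field(default_factory=dict)
    offtarget: dict = field(default_factory=dict)
    triage: dict = field(default_factory=dict)
    ontarget: dict = field(default_factory=dict)
    #: optional experiment manifest; guides are referenced as "auto:K",
    #: the K-th auto-designed target (1-based)
    experiments: list = field(default_factory=list)

    _DEFAULTS = {
        "simulate": {
            "n_chromosomes": 4,
            "chromosome_lengths": [600_000, 550_000, 500_000, 400_000],
            "n_genes": 200,
            "essential_fraction": 0.3,
            "n_colonies": 10,
            "pool_size": 5,
            "coverage": 300.0,
            "read_length": 150,
            "fragment_mean": 550,
            "error_rate": 0.001,
            "n_guides": 2,
            "class_probabilities": {
                "none": 0.2, "small-indel": 0.35, "large-indel": 0.15,
                "rearrangement": 0.15, "truncation": 0.1, "inversion": 0.05,
            },
            "telomere_motif": simulate_mod.TELOMERE_MOTIF,
            "n_base_variants": 30,
            "n_random_dnms_per_pool": 5,
        },
        "guides": {
            "spacer_length": 20,
            "pam_motif": "NGG",
            "cds_window": [0.0, 0.4],
            "min_region_length": 50_000,
            "max_allowed_secondary_sites": 0,
        },
        "offtarget": {
            "max_mismatches": 10,
            "pam_motifs": ["NGG", "NAG"],
            "window": 30,
            "seed_length": 5,
        },
        "triage": {
            "on_target_radius": 100,
            "sv_tolerance": 10,
            "min_experiments": 2,
            "require_distinct_guides": True,
        },
        "ontarget": {
            "flank": 1000,
            "max_mismatches_per_read": 4,
            "min_overlap": 5,
            "min_reads_minor": 5,
            "telomere_min_copies": 3,
            "mh_max_window": 25,
            "mh_max_mismatches": 2,
        },
    }

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
        for section, defaults in self._DEFAULTS.items():
            merged = dict(defaults)
            user = getattr(self, section)
            unknown = set(user) - set(defaults)
            if unknown:
                raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
            merged.update(user)
            setattr(self, section, merged)
        probs = self.simulate["class_probabilities"]
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError("simulate.class_probabilities must sum to 1")
        self._validate_experiments()

    def _validate_experiments(self) -> None:
        seen_ids: set[str] = set()
        n_guides = int(self.simulate["n_guides"])
        for exp in self.experiments:
            missing = {"experiment_id", "base_strain_id", "guide_ids",
                       "colony_mode"} - set(exp)
            if missing:
                raise ConfigError(f"experiment entry missing {sorted(missing)}")
            if exp["experiment_id"] in seen_ids:
                raise ConfigError(f"duplicate experiment id {exp['experiment_id']!r}")
            seen_ids.add(exp["experiment_id"])
            if exp["colony_mode"] not in ("single", "pooled-5"):
                raise ConfigError(f"bad colony_mode {exp['colony_mode']!r}")
            for ref in exp["guide_ids"]:
                if not (isinstance(ref, str) and ref.startswith("auto:")):
                    raise ConfigError(f"guide reference {ref!r} must be 'auto:K'")
                k = int(ref.split(":", 1)[1])
                if not 1 <= k <= n_guides:
                    raise ConfigError(
                        f"experiment {exp['experiment_id']!r} references "
                        f"undefined guide {ref!r} (only {n_guides} designed)"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def echo(self) -> dict:
        return {
            "seed": self.seed,
            "stages": self.stages,
            "simulate": self.simulate,
            "guides": self.guides,
            "offtarget": self.offtarget,
            "triage": self.triage,
            "ontarget": self.ontarget,
            "experiments": self.experiments,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    """In-memory artifacts of a run, alongside the files on disk."""

    outdir: Path
    genome: AnnotatedGenome | None = None
    target_guides: list[Guide] = field(default_factory=list)
    truths: list[simulate_mod.ColonyTruth] = field(default_factory=list)
    pool_calls: dict[str, list[VariantCall]] = field(default_factory=dict)
    base_calls: list[VariantCall] = field(default_factory=list)
    readsets: dict[str, simulate_mod.ReadSet] = field(default_factory=dict)
    binding_sites: dict[str, list] = field(default_factory=dict)
    site_hits: list = field(default_factory=list)
    ledger: triage_mod.DnmLedger | None = None
    support: dict[str, list[ontarget_mod.SupportTable]] = field(default_factory=dict)
    microhomology: list[ontarget_mod.MicrohomologyCall] = field(default_factory=list)
    truncations: list[ontarget_mod.TruncationCall] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute the configured stages in dependency order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult(outdir)
    files: dict[str, str] = {}
    log: dict[str, dict] = {}
    done: list[str] = []
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, result, files, log)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        done.append(stage)
    result.provenance = {
        "config": config.echo(),
        "stages_run": done,
        "stage_log": log,
        "files": {name: _sha256(outdir / name) for name in sorted(files)},
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
    return result


# ---------------------------------------------------------------------------
# in-memory end-to-end synthetic study

STUDY_CLASS_MIX = {
    "none": 0.2, "small-indel": 0.3, "large-indel": 0.2,
    "rearrangement": 0.15, "truncation": 0.1, "inversion": 0.05,
}


@dataclass
class StudyResult:
    """Everything a full in-memory synthetic study produces."""

    genome: AnnotatedGenome
    targets: list[Guide]
    truths: list[simulate_mod.ColonyTruth]
    base_calls: list[VariantCall]
    pool_calls: dict[str, list[VariantCall]]
    planted_dnm_ids: set[str]
    colony_genomes: dict[str, AnnotatedGenome]
    readsets: dict[str, simulate_mod.ReadSet]
    ledger: triage_mod.DnmLedger
    quantifications: dict[str, PoolQuantification]


def run_synthetic_study(
    seed: int,
    chromosome_lengths: tuple[int, ...] = (600_000, 550_000, 450_000, 400_000),
    n_genes: int = 200,
    essential_fraction: float = 0.3,
    n_colonies: int = 10,
    pool_size: int = 5,
    coverage: float = 300.0,
    error_rate: float = 0.001,
    class_probabilities: dict[str, float] | None = None,
    n_base_variants: int = 30,
    n_random_dnms_per_pool: int = 5,
    force_showcase_outcomes: bool = True,
    flank: int = 1000,
    telomere_motif: str = simulate_mod.TELOMERE_MOTIF,
) -> StudyResult:
    """One complete in-memory synthetic study at the default design scale:
    a ~2 Mb four-chromosome genome, two auto-designed targets, ten
    colonies sequenced in two pools of five at 300-fold coverage with
    150 bp paired reads from ~550 bp fragments.

    With ``force_showcase_outcomes`` the first colony carries a
    rearrangement between the two targets whose first derivative
    junction has an engineered 5 bp / 2-mismatch microhomology, and the
    second colony a telomere-capped truncation at the first target, so
    every junction-signature detector is exercised regardless of the
    random outcome draw.  All randomness derives from ``seed``.
    """
    master = np.random.default_rng(seed)
    subseeds = [int(s) for s in master.integers(0, 2**31 - 1, size=8)]
    genome = simulate_mod.generate_genome(
        len(chromosome_lengths), list(chromosome_lengths), n_genes,
        essential_fraction, subseeds[0],
    )
    targets = select_target_guides(genome, 2)
    genome = simulate_mod.plant_microhomology(
        genome, targets[0], targets[1], length=5, mismatches=2
    )
    truths = simulate_mod.plan_colony_outcomes(
        genome, targets, n_colonies, class_probabilities or STUDY_CLASS_MIX,
        seed=subseeds[1], pool_size=pool_size, telomere_motif=telomere_motif,
    )
    if force_showcase_outcomes and n_colonies >= 2:
        t1, t2 = targets[0], targets[1]
        truths[0] = simulate_mod.ColonyTruth(
            truths[0].colony_id, truths[0].pool_id,
            [simulate_mod.EditEvent(
                simulate_mod.EditClass.REARRANGEMENT, t1.chrom, t1.cut_locus,
                target_id=f"{t1.guide_id}+{t2.guide_id}",
                chrom2=t2.chrom, position2=t2.cut_locus,
            )],
        )
        tel = telomere_motif * 10
        truths[1] = simulate_mod.ColonyTruth(
            truths[1].colony_id, truths[1].pool_id,
            [
                simulate_mod.EditEvent(
                    simulate_mod.EditClass.TRUNCATION, t1.chrom, t1.cut_locus,
                    target_id=t1.guide_id, telomere_capped=True,
                    inserted_sequence=tel,
                    net_length_change=-(genome.chrom_length(t1.chrom) - t1.cut_locus) + len(tel),
                ),
                simulate_mod.EditEvent(
                    simulate_mod.EditClass.NONE, t2.chrom, t2.cut_locus,
                    target_id=t2.guide_id,
                ),
            ],
        )

    exclude = [(g.chrom, g.cut_locus - 2 * flank, g.cut_locus + 2 * flank)
               for g in targets]
    snv_rng = np.random.default_rng(subseeds[2])
    base_calls = simulate_mod.plant_background_snvs(
        genome, n_base_variants, snv_rng, exclude, "base", "base-strain"
    )

    pools: dict[str, list[simulate_mod.ColonyTruth]] = {}
    for t in truths:
        pools.setdefault(t.pool_id, []).append(t)

    pool_calls: dict[str, list[VariantCall]] = {}
    readsets: dict[str, simulate_mod.ReadSet] = {}
    colony_genomes: dict[str, AnnotatedGenome] = {}
    planted_dnm_ids: set[str] = set()
    for pi, (pool_id, pool_truths) in enumerate(sorted(pools.items())):
        edit_calls = simulate_mod.truth_to_calls(genome, pool_truths)
        for c in edit_calls:
            c.sample_id = pool_id
        dnms = simulate_mod.plant_background_snvs(
            genome, n_random_dnms_per_pool, snv_rng, exclude,
            f"{pool_id}_dnm", pool_id,
        )
        planted_dnm_ids.update(c.variant_id for c in dnms)
        base_copy = [
            VariantCall(b.variant_id, pool_id, b.chrom, b.pos, b.ref, b.alt,
                        b.var_type)
            for b in base_calls
        ]
        pool_calls[pool_id] = base_copy + edit_calls + dnms
        edited = []
        for t in pool_truths:
            g = simulate_mod.apply_edits(genome, t)
            colony_genomes[t.colony_id] = g
            edited.append(g)
        readsets[pool_id] = simulate_mod.simulate_pool_reads(
            edited, coverage, error_rate=error_rate, seed=subseeds[3] + pi,
            colony_ids=[t.colony_id for t in pool_truths],
        )

    guide_ids = {g.guide_id for g in targets}
    _, rec_log = triage_mod.drop_recurrent(
        pool_calls, 2, True, {p: guide_ids for p in pool_calls}
    )
    ledger = triage_mod.build_ledger(
        pool_calls, base_calls, genome,
        {p: targets for p in pool_calls}, recurrence_log=rec_log,
    )
    quantifications = {
        pool_id: quantify_pool(
            genome, targets, pool_calls[pool_id], readsets[pool_id],
            flank=flank, telomere_motif=telomere_motif, id_prefix=f"{pool_id}_",
        )
        for pool_id in sorted(pool_calls)
    }
    return StudyResult(
        genome, targets, truths, base_calls, pool_calls, planted_dnm_ids,
        colony_genomes, readsets, ledger, quantifications,
    )


# ---------------------------------------------------------------------------
# stages


def select_target_guides(
    genome: AnnotatedGenome,
    n_guides: int,
    spacer_length: int = 20,
    pam_motif: str = "NGG",
    cds_window: tuple[float, float] = (0.0, 0.4),
    max_allowed_secondary_sites: int = 0,
) -> list[Guide]:
    """Auto-design target guides on non-essential genes.

    Genes are visited in coordinate order, spreading targets across
    chromosomes; the first guide passing the early-CDS window and the
    verbatim genome-uniqueness check wins for each gene.
    """
    chosen: list[Guide] = []
    used_chroms: set[str] = set()
    candidates = sorted(
        (g for g in genome.genes if not g.essential),
        key=lambda g: (g.chrom, g.start),
    )
    for gene in candidates:
        if len(chosen) == n_guides:
            break
        if gene.chrom in used_chroms and len(used_chroms) < len(genome.chromosomes):
            continue
        cand = guides_mod.enumerate_protospacers(genome, gene, pam_motif, spacer_length)
        # window first, verbatim-uniqueness scan only for the survivors
        windowed = guides_mod.filter_guides(cand, cds_window)
        scan = {
            g.guide_id: offtarget_mod.find_binding_sites(
                genome, g, 0, frozenset({pam_motif})
            )
            for g in windowed
        }
        kept = guides_mod.filter_guides(
            windowed, cds_window, scan, max_allowed_secondary_sites
        )
        if kept:
            chosen.append(kept[0])
            used_chroms.add(gene.chrom)
    if len(chosen) < n_guides:
        raise ConfigError(f"could only design {len(chosen)} of {n_guides} target guides")
    return chosen


@dataclass
class PoolQuantification:
    """Per-pool on-target quantification results."""

    tables: list[ontarget_mod.SupportTable]
    models: list[ontarget_mod.GenotypeModel]
    microhomology: list[ontarget_mod.MicrohomologyCall]
    truncations: list[ontarget_mod.TruncationCall]


def quantify_pool(
    genome: AnnotatedGenome,
    targets: list[Guide],
    calls: list[VariantCall],
    readset: simulate_mod.ReadSet,
    flank: int = 1000,
    max_mismatches_per_read: int = 4,
    min_overlap: int = 5,
    min_reads_minor: int = 5,
    telomere_motif: str = simulate_mod.TELOMERE_MOTIF,
    telomere_min_copies: int = 3,
    mh_max_window: int = 25,
    mh_max_mismatches: int = 2,
    id_prefix: str = "",
) -> PoolQuantification:
    """Reconstruct genotypes at every target and quantify read support.

    A junction anchored at two targets (a rearrangement between them)
    reconstructs to the same local sequence at both; reads are assigned
    against the unique sequences and the counts shared back to every
    owning target, so the junction contributes to both loci's support.
    Junction signatures (microhomology, telomere-capped truncation) are
    detected from the pool's breakend calls.
    """
    from .dna import revcomp as _rc

    pool_models: list[ontarget_mod.GenotypeModel] = []
    for target in targets:
        near = _calls_near_target(calls, target, flank)
        models = ontarget_mod.reconstruct_genotype_sequences(genome, target, near, flank)
        if id_prefix:
            for m in models:
                m.genotype_id = f"{id_prefix}{m.genotype_id}"
        pool_models.extend(models)
    rep_of: dict[str, str] = {}
    unique: list[ontarget_mod.GenotypeModel] = []
    for m in pool_models:
        key = min(m.local_sequence, _rc(m.local_sequence))
        if key in rep_of:
            rep_of[m.genotype_id] = rep_of[key]
        else:
            rep_of[key] = rep_of[m.genotype_id] = m.genotype_id
            unique.append(m)
    assignment = ontarget_mod.assign_reads(
        readset, unique, max_mismatches_per_read, min_overlap
    )
    tables = []
    for target in targets:
        t_models = [m for m in pool_models if m.target_id == target.guide_id]
        sub = ontarget_mod.ReadAssignment(
            t_models,
            {m.genotype_id: assignment.counted[rep_of[m.genotype_id]] for m in t_models},
            {m.genotype_id: assignment.assigned[rep_of[m.genotype_id]] for m in t_models},
            assignment.n_ambiguous, assignment.n_unassigned, assignment.n_not_covering,
        )
        tables.append(ontarget_mod.support_table(sub, min_reads_minor))

    microhomology: list[ontarget_mod.MicrohomologyCall] = []
    truncations: list[ontarget_mod.TruncationCall] = []
    seen_junctions: set[tuple] = set()
    for c in calls:
        if c.breakend is not None and c.breakend.partner_linked:
            a, b = c.breakend.locus_a, c.breakend.locus_b
            jkey = tuple(sorted([(a.chrom, a.pos, a.orientation),
                                 (b.chrom, b.pos, b.orientation)]))
            if jkey in seen_junctions:
                continue  # one call per junction, not its mate
            seen_junctions.add(jkey)
            microhomology.append(
                ontarget_mod.detect_microhomology(
                    c.breakend, genome, mh_max_window, mh_max_mismatches,
                    junction_id=c.variant_id,
                )
            )
        elif c.breakend is not None and not c.breakend.partner_linked:
            call = ontarget_mod.detect_truncation(
                c.breakend, telomere_motif, telomere_min_copies
            )
            if call is not None:
                truncations.append(call)
    return PoolQuantification(tables, pool_models, microhomology, truncations)


def _stage_simulate(config: RunConfig, result: RunResult, files, log) -> None:
    scfg = config.simulate
    seed = config.seed
    genome = simulate_mod.generate_genome(
        scfg["n_chromosomes"], list(scfg["chromosome_lengths"]),
        scfg["n_genes"], scfg["essential_fraction"], seed,
    )
    result.genome = genome
    genome.write_fasta(result.outdir / "reference.fasta")
    genome.write_gff3(result.outdir / "reference.gff3")
    files["reference.fasta"] = files["reference.gff3"] = "simulate"

    gcfg = config.guides
    targets = select_target_guides(
        genome, scfg["n_guides"], gcfg["spacer_length"], gcfg["pam_motif"],
        tuple(gcfg["cds_window"]), gcfg["max_allowed_secondary_sites"],
    )
    result.target_guides = targets
    guides_mod.write_guides_tsv(targets, result.outdir / "target_guides.tsv")
    files["target_guides.tsv"] = "simulate"

    truths = simulate_mod.plan_colony_outcomes(
        genome, targets, scfg["n_colonies"], scfg["class_probabilities"],
        seed=seed + 1, pool_size=scfg["pool_size"],
        telomere_motif=scfg["telomere_motif"],
    )
    result.truths = truths
    simulate_mod.write_truth_manifest(truths, result.outdir / "truth_manifest.tsv")
    files["truth_manifest.tsv"] = "simulate"

    contigs = {c: genome.chrom_length(c) for c in genome.chromosomes}
    exclude = [
        (g.chrom, g.cut_locus - 2000, g.cut_locus + 2000) for g in targets
    ]
    rng = np.random.default_rng(seed + 2)
    base_calls = simulate_mod.plant_background_snvs(
        genome, scfg["n_base_variants"], rng, exclude, "base", "base-strain"
    )
    result.base_calls = base_calls
    write_vcf(base_calls, result.outdir / "base_strain.vcf", contigs)
    files["base_strain.vcf"] = "simulate"

    pools: dict[str, list[simulate_mod.ColonyTruth]] = {}
    for t in truths:
        pools.setdefault(t.pool_id, []).append(t)
    for pi, (pool_id, pool_truths) in enumerate(sorted(pools.items())):
        edit_calls = simulate_mod.truth_to_calls(genome, pool_truths)
        for c in edit_calls:
            c.sample_id = pool_id
        dnms = simulate_mod.plant_background_snvs(
            genome, scfg["n_random_dnms_per_pool"], rng, exclude,
            f"{pool_id}_dnm", pool_id,
        )
        base_copy = [
            VariantCall(
                b.variant_id, pool_id, b.chrom, b.pos, b.ref, b.alt, b.var_type
            )
            for b in base_calls
        ]
        pool_calls = base_copy + edit_calls + dnms
        result.pool_calls[pool_id] = pool_calls
        write_vcf(pool_calls, result.outdir / f"calls_{pool_id}.vcf", contigs)
        files[f"calls_{pool_id}.vcf"] = "simulate"

        edited = [simulate_mod.apply_edits(genome, t) for t in pool_truths]
        readset = simulate_mod.simulate_pool_reads(
            edited, scfg["coverage"], scfg["read_length"], scfg["fragment_mean"],
            error_rate=scfg["error_rate"], seed=seed + 10 + pi,
            colony_ids=[t.colony_id for t in pool_truths],
        )
        result.readsets[pool_id] = readset
        readset.write_fastq(
            result.outdir / f"reads_{pool_id}_R1.fastq.gz",
            result.outdir / f"reads_{pool_id}_R2.fastq.gz",
        )
        files[f"reads_{pool_id}_R1.fastq.gz"] = "simulate"
        files[f"reads_{pool_id}_R2.fastq.gz"] = "simulate"
    log["simulate"] = {
        "colonies": len(truths),
        "pools": len(pools),
        "read_pairs": {p: rs.n_pairs for p, rs in result.readsets.items()},
    }


def _stage_design_guides(config: RunConfig, result: RunResult, files, log) -> None:
    genome = _need_genome(result)
    gcfg = config.guides
    all_guides: list[Guide] = []
    kept: list[Guide] = []
    for gene in sorted(genome.genes, key=lambda g: (g.chrom, g.start)):
        cand = guides_mod.enumerate_protospacers(
            genome, gene, gcfg["pam_motif"], gcfg["spacer_length"]
        )
        all_guides.extend(cand)
        windowed = guides_mod.filter_guides(cand, tuple(gcfg["cds_window"]))
        scan = {
            g.guide_id: offtarget_mod.find_binding_sites(
                genome, g, 0, frozenset({gcfg["pam_motif"]})
            )
            for g in windowed
        }
        kept.extend(
            guides_mod.filter_guides(
                windowed, tuple(gcfg["cds_window"]), scan,
                gcfg["max_allowed_secondary_sites"],
            )
        )
    guides_mod.write_guides_tsv(kept, result.outdir / "designed_guides.tsv")
    files["designed_guides.tsv"] = "design-guides"
    regions = guides_mod.find_nonessential_regions(genome, gcfg["min_region_length"])
    guides_mod.write_regions_bed(regions, result.outdir / "nonessential_regions.bed")
    files["nonessential_regions.bed"] = "design-guides"
    log["design-guides"] = {
        "candidates": len(all_guides), "kept": len(kept), "ne_regions": len(regions),
    }


def _stage_scan_offtargets(config: RunConfig, result: RunResult, files, log) -> None:
    genome = _need_genome(result)
    ocfg = config.offtarget
    all_sites = []
    for g in result.target_guides:
        sites = offtarget_mod.find_binding_sites(
            genome, g, ocfg["max_mismatches"], frozenset(ocfg["pam_motifs"]),
            ocfg["seed_length"],
        )
        result.binding_sites[g.guide_id] = sites
        all_sites.extend(sites)
    offtarget_mod.write_sites_tsv(all_sites, result.outdir / "binding_sites.tsv")
    files["binding_sites.tsv"] = "scan-offtargets"
    variants = [c for calls in result.pool_calls.values() for c in calls]
    result.site_hits = offtarget_mod.sites_near_variants(
        all_sites, variants, ocfg["window"]
    )
    offtarget_mod.write_hits_tsv(result.site_hits, result.outdir / "site_variant_hits.tsv")
    files["site_variant_hits.tsv"] = "scan-offtargets"
    log["scan-offtargets"] = {
        "sites": len(all_sites), "variant_hits": len(result.site_hits),
    }


def _stage_triage(config: RunConfig, result: RunResult, files, log) -> None:
    genome = _need_genome(result)
    tcfg = config.triage
    guide_ids = {g.guide_id for g in result.target_guides}
    filtered, rec_log = triage_mod.drop_recurrent(
        result.pool_calls, tcfg["min_experiments"], tcfg["require_distinct_guides"],
        {pool: guide_ids for pool in result.pool_calls},
    )
    ledger = triage_mod.build_ledger(
        result.pool_calls, result.base_calls, genome,
        {pool: result.target_guides for pool in result.pool_calls},
        result.site_hits, on_target_radius=tcfg["on_target_radius"],
        sv_tolerance=tcfg["sv_tolerance"], recurrence_log=rec_log,
    )
    result.ledger = ledger
    ledger.write_tsv(result.outdir / "dnm_ledger.tsv")
    ledger.write_fate_log(result.outdir / "call_fates.tsv")
    files["dnm_ledger.tsv"] = files["call_fates.tsv"] = "triage"
    dnm_ids = {
        f["variant_id"] for f in ledger.fates
        if f["fate"] in (triage_mod.FATE_ON_TARGET, triage_mod.FATE_OFF_TARGET)
    }
    contigs = {c: genome.chrom_length(c) for c in genome.chromosomes}
    dnm_calls = [
        c for calls in result.pool_calls.values() for c in calls
        if c.variant_id in dnm_ids
    ]
    write_vcf(dnm_calls, result.outdir / "dnm_calls.vcf", contigs)
    files["dnm_calls.vcf"] = "triage"
    log["triage"] = {"dnms": len(dnm_calls), "recurrent_removed": len(rec_log)}


def _stage_quantify(config: RunConfig, result: RunResult, files, log) -> None:
    genome = _need_genome(result)
    ncfg = config.ontarget
    scfg = config.simulate
    all_models: list[ontarget_mod.GenotypeModel] = []
    for pool_id, calls in sorted(result.pool_calls.items()):
        quant = quantify_pool(
            genome, result.target_guides, calls, result.readsets[pool_id],
            flank=ncfg["flank"],
            max_mismatches_per_read=ncfg["max_mismatches_per_read"],
            min_overlap=ncfg["min_overlap"],
            min_reads_minor=ncfg["min_reads_minor"],
            telomere_motif=scfg["telomere_motif"],
            telomere_min_copies=ncfg["telomere_min_copies"],
            mh_max_window=ncfg["mh_max_window"],
            mh_max_mismatches=ncfg["mh_max_mismatches"],
            id_prefix=f"{pool_id}_",
        )
        result.support[pool_id] = quant.tables
        result.microhomology.extend(quant.microhomology)
        result.truncations.extend(quant.truncations)
        all_models.extend(quant.models)

    ontarget_mod.write_genotypes_fasta(all_models, result.outdir / "genotypes.fasta")
    tables_flat = [t for ts in result.support.values() for t in ts]
    ontarget_mod.write_support_tsv(tables_flat, result.outdir / "genotype_support.tsv")
    ontarget_mod.write_class_support_tsv(tables_flat, result.outdir / "class_support.tsv")
    ontarget_mod.write_microhomology_tsv(
        result.microhomology, result.outdir / "microhomology.tsv"
    )
    ontarget_mod.write_truncation_tsv(result.truncations, result.outdir / "truncations.tsv")
    for name in ("genotypes.fasta", "genotype_support.tsv", "class_support.tsv",
                 "microhomology.tsv", "truncations.tsv"):
        files[name] = "quantify"
    log["quantify"] = {
        "models": len(all_models),
        "truncations": len(result.truncations),
        "junctions_with_mh": sum(1 for m in result.microhomology if m.mh_length > 0),
    }


def _calls_near_target(calls: list[VariantCall], target: Guide, flank: int) -> list[VariantCall]:
    near = []
    for c in calls:
        if c.breakend is not None:
            a = c.breakend.locus_a
            b = c.breakend.locus_b
            if (a.chrom == target.chrom and abs(a.pos - target.cut_locus) <= flank) or (
                b is not None
                and b.chrom == target.chrom
                and abs(b.pos - target.cut_locus) <= flank
            ):
                near.append(c)
        elif c.chrom == target.chrom and abs(c.pos - target.cut_locus) <= flank:
            if c.var_type != VariantType.SNV or c.variant_id.startswith(
                ("colony",)
            ):
                near.append(c)
    return near


def _stage_report(config: RunConfig, result: RunResult, files, log) -> None:
    render_summary(result)
    files["summary_ledger.tsv"] = files["summary_class_support.tsv"] = "report"
    log["report"] = {"pools": len(result.support)}


def render_summary(result: RunResult) -> None:
    """Ledger-shaped and stacked-bar-shaped summary tables.

    The class-support table lists, per pool and target, the relative
    read support and the number of distinct genotypes per outcome
    class (the small-numbers-above-bars annotation).
    """
    if result.ledger is None or not result.support:
        missing = "triage" if result.ledger is None else "quantify"
        raise RuntimeError(f"render_summary: missing output of stage {missing!r}")
    result.ledger.write_tsv(result.outdir / "summary_ledger.tsv")
    with open(result.outdir / "summary_class_support.tsv", "w") as fh:
        fh.write("pool_id\ttarget_id\tn_colonies\tclass\trelative_support\t"
                 "distinct_genotypes\ttargeting_efficiency\n")
        for pool_id in sorted(result.support):
            n_col = sum(1 for t in result.truths if t.pool_id == pool_id)
            for table in result.support[pool_id]:
                eff = ("" if table.targeting_efficiency is None
                       else f"{table.targeting_efficiency:.6f}")
                counts = table.distinct_genotypes()
                for cls, frac in sorted(table.class_support().items()):
                    fh.write(
                        f"{pool_id}\t{table.target_id}\t{n_col}\t{cls}\t"
                        f"{frac:.6f}\t{counts.get(cls, 0)}\t{eff}\n"
                    )


def _need_genome(result: RunResult) -> AnnotatedGenome:
    if result.genome is None:
        raise RuntimeError("no genome available: run the simulate stage or load files")
    return result.genome


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "design-guides": _stage_design_guides,
    "scan-offtargets": _stage_scan_offtargets,
    "triage": _stage_triage,
    "quantify": _stage_quantify,
    "report": _stage_report,
}
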