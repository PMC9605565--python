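# Methods

## Setting and scope

The package analyses CRISPR/Cas9 editing experiments in compact fungal
genomes where colonies are resequenced with short reads, either singly
or pooled.  It consumes standard-format inputs (FASTA reference, GFF3
annotation with an `essential=` attribute, VCF 4.2 calls with SVs as
breakend or symbolic records, paired FASTQ) and performs guide design,
off-target site enumeration, de-novo-mutation (DNM) triage and
read-support-based on-target genotyping.  Variant calling itself is out
of scope: callers such as GATK or GRIDSS remain external, and the
bundled simulator supplies truth VCFs for validation.

## Coordinates and breakend conventions

All serialized coordinates are 1-based inclusive; BED output follows
the BED standard (0-based half-open).  Internally some arithmetic is
half-open but never leaks into files.  Indel alleles are VCF
left-anchored (first REF base preserved in ALT).  A breakend locus is
`(chromosome, position, orientation)` with orientation `right-open`
(retained sequence at or left of the position, break 3' of it) or
`left-open` (retained at or right of it).  A junction reads: segment of
locus A in its orientation, inserted sequence, segment of locus B.
Reciprocal translocations are written as two breakend pairs (four BND
records linked by MATEID); telomere-capped truncations as single
breakends whose ALT carries the appended sequence.

## Guide design

Protospacers are enumerated on both strands wherever a PAM (IUPAC
motif, default NGG) flanks a spacer-length window and the blunt cut —
3 bp PAM-proximal of the protospacer end, the canonical Cas9 cut —
falls inside the CDS.  `cut_locus` is the base immediately left (in
genomic coordinates) of the scissile bond.  The CDS fraction measures
the cut position 5'→3' on the gene strand; the default retention window
(0, 0.4) biases designs toward early frameshifts.  Uniqueness is a
verbatim genome scan (mismatch budget 0) by default: a guide is dropped
if its protospacer+PAM occurs anywhere beyond its design locus.  Genes
are modelled as single-exon CDSs, adequate for compact, largely
intron-free fungal genomes.

Non-essential regions are the maximal intervals containing no
essential-gene bases with length at or above a threshold (default
50 kb), bounded by essential genes and chromosome ends.  Curated
exclusions (e.g. a conditionally essential gene inside a region) are a
configuration matter, not inferred.

## Off-target scanning

The scanner enumerates, per strand, every window where the protospacer
matches with at most `max_mismatches` (default 10) mismatches and the
adjacent 3-mer matches one allowed PAM motif exactly — mismatches
inside the PAM are never tolerated, and no RNA/DNA bulges are modelled,
so the comparison is fixed-length Hamming.  The implementation is a
vectorised sliding comparison (with a string-search fast path at budget
0) and is required, by test, to equal a naive per-position scan.
Mismatch offsets count from the PAM-proximal protospacer base; the seed
region is the 5 PAM-proximal bases.  A genomic `N` never matches a
guide base.  Variant intersection reports `overlaps-site` when the
variant's reference span (insertions: anchor base only) intersects the
protospacer+PAM span, and `within-window` within ±30 bp (default).

## DNM triage

Every call receives exactly one fate: `pre-existing` (matched in the
base-strain call set — exact (chrom, pos, ref, alt) for small variants,
breakend loci within ±10 bp per end for SVs), `blacklisted` (inside a
reference-error BED), `recurrent`, `low-support`, `dnm-on-target` or
`dnm-off-target`.  Recurrence removes a variant seen in at least
`min_experiments` experiments among which a same-sized subset has
pairwise disjoint guide sets — recurrence explainable by a shared guide
is kept.  A call is on-target within 100 bp (default) of any cut locus,
or if either breakend partner is; the radius must contain NHEJ indel
scatter while excluding unlinked variants.  Coding effect is a minimal
annotation: coding iff the reference span intersects a CDS, frameshift
iff the net length change is not a multiple of 3.  For pooled samples
(5 colonies, caller ploidy 5) a read-support gate of ≥ 1/10 of local
depth — half one colony's expected share — is available as an explicit
filter; truth VCFs carry no depth, so it is not applied implicitly.

## On-target genotyping

Outcome classes follow the repair-spectrum taxonomy: indels under 50 bp
are `in-frame` or `frameshift` by net length mod 3; indels of at least
50 bp, duplications, inversions, translocations and any breakend
junction are `SV` (with a separate frame-preserved flag, so a 57 bp
in-frame deletion is an SV that conserves frame); on-target SNVs get
their own `substitution` class rather than being folded into in-frame.

Per target, one local model sequence is reconstructed per distinct
variant plus the wildtype window (default flank 1000 bp each side of
the cut, comfortably beyond read+fragment reach).  Deletions splice the
window; events reaching past it keep a full flank of context on each
side of the junction; breakend models concatenate the partner flanks in
junction orientation.  Sequence-identical models (including reverse
complements, which arise from a junction's two mate records) collapse.

Read assignment is deliberately not a BWA-MEM replica: the simulator
introduces substitution errors only, so gapless matching is exact for
its output.  Candidate alignments come from exact 20-mer seeding into
the model sequences (three probe offsets per read and orientation; the
chance that all probes of a true window read are hit by errors at 0.1%
per base is ~8e-6), scored by full-read Hamming distance with a budget
of 4 mismatches.  A read counts for the unique best-scoring model only
if it spans the model's variant position with at least 5 bases on each
side ("support counted at the exact position of the variant"); ties
across models are discarded as ambiguous, mirroring multimapped-read
removal.  Support fractions are computed over counted reads only, so
they sum to 1; targeting efficiency is 1 − WT support; genotypes under
5 reads are flagged minor, not dropped.  A junction joining two targets
(rearrangement) reconstructs identically at both; reads are assigned
against unique sequences and the counts shared to both loci, so the
rearrangement contributes to both targets' support — and its two
derivative junctions are two models, so a reciprocal translocation
carries twice a colony's per-locus read weight in a support table.

Microhomology at a junction is the longest window L ≤ 25 such that the
L reference bases continuing past the break on side A equal the first L
retained bases of side B with at most `max_mismatches` (default 2)
mismatches, both read in junction orientation — the annealing
relationship expected under MMEJ.  Because the mismatch count is
monotone in L, the longest prefix within budget is exact.  Truncation
calls require at least `min_copies` (default 3) tandem copies of the
telomere motif in the sequence appended at a one-sided junction; the
final copy may be partial, but a partial never starts a run.  The
telomere repeat unit is a configuration value shared by simulator and
detector (default `GGTGTAGT`, an arbitrary TG-rich 8-mer — the real
repeat's sequence is not part of the model).

## The synthetic study design

The simulator emulates the sequencing design the analysis targets:
multi-chromosome genomes (default four chromosomes, ~2 Mb total — a
scaled-down stand-in for the 9.4 Mb *K. phaffii* genome chosen to keep
a full study under two minutes on one CPU), genes 300–1500 bp with a
configurable essential fraction (default 0.3), pools of 5 colonies,
150 bp paired reads from Normal(550, 55) fragments at 100×/300×
targets, constant base qualities (the analysis never uses them) and
i.i.d. substitution errors (default 0.1%).  Repair outcomes are drawn
per colony and target from a configurable class distribution; a
rearrangement (two guides only) is drawn at colony level and replaces
both target outcomes with a reciprocal translocation.  Default size
models: small indels uniform 1–15 bp, large indels 50–2500 bp
(bracketing observed 57–2212 bp events), inversions 200–2000 bp,
deletions 80% of indels, telomere runs of 5–15 motif copies.  These
size models are free parameters of the generator, not claims about
repair biology.

Fragments are shared equally among pool members, so a colony's expected
read fraction is 0.2 regardless of genome size — which makes its
*local* coverage scale with 1/genome-length.  Recovery tests therefore
weight planted mixtures by 1/L per colony genome.  Truncation junctions
sit ~100 bp from the new chromosome end where fragment placement
depletes coverage; recovery tests check truncation support for presence
and position (±5 bp) and compare class fractions over the remaining
genotypes.  Background SNVs (base-strain set and per-pool random DNMs)
are planted at call level only, outside ±2 kb of any cut, and are not
applied to the simulated sequences — the triage path consumes calls,
not reads.  `plant_microhomology` rewrites the bases just 3' of the
second target's cut so a rearrangement junction carries an exact
5 bp / 2-mismatch microhomology (it also rewrites that guide's
PAM-proximal bases, so sequence-identity checks for that guide must run
before planting).

What passing these tests does *not* show about real data: no indel or
quality-decay error model, no GC or mappability bias, no repetitive
sequence (random genomes are far more mappable than real ones), no
caller noise (truth VCFs are exact), and no mitochondrial or plasmid
sequences.  The pipeline's behaviour on real caller output therefore
depends on upstream caller quality in ways these tests cannot certify.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the study runner derives per-stage
substreams from one master seed.  Gzip members are written with
`mtime=0` and no embedded filename so reruns are byte-identical; the
provenance log contains config echo and SHA-256 hashes but no
wall-clock data.  Class probabilities must sum to 1 within 1e-9;
support fractions sum to 1 by construction.  Degenerate inputs are
explicit: zero retained reads yields a no-coverage flag rather than a
division; overlapping edits are rejected naming both offenders; gene
placement failure after bounded retries raises rather than looping.
Test problem sizes (20 kb scan oracles, 2 Mb studies, 100-seed region
sweeps) were chosen so the full suite runs in a few minutes on one CPU.

## Known limitations

- Gapless read assignment misclassifies reads that contain true indel
  sequencing errors; with the simulator's substitution-only error model
  this is moot, on real data it would shave support near homopolymers.
- Edited genomes drop their gene annotation (coordinates are not lifted
  over); nothing downstream currently needs it.
- A rearrangement must be the only edit on its two chromosomes within a
  colony, avoiding coordinate remapping through prior edits.
- The on-target SNV class (`substitution`) never arises from the
  default outcome mix; it exists for completeness of the classifier.
- `ReadSet.from_fastq` loses truth origins; recovery metrics need the
  in-memory read sets or the truth manifest.
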