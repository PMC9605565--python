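"""Guide RNA enumeration/filtering and non-essential region discovery.

Guides are enumerated from CDS intervals on both strands, requiring an
adjacent PAM; the blunt Cas9 cut falls 3 bp PAM-proximal of the
protospacer end.  ``cut_locus`` is the 1-based genomic position of the
base immediately left (in genomic coordinates) of the scissile bond.

Candidate filtering applies the two design rules used for
frameshift-oriented knockouts: the cut must fall in a window early in
the coding sequence (default first 40%), and the guide must have no
secondary genomic binding site under the configured mismatch budget
(default 0, i.e. verbatim uniqueness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .dna import iupac_matches, revcomp
from .genome import AnnotatedGenome, GeneRecord


@dataclass
class Guide:
    """A protospacer+PAM at a designed genomic locus."""

    guide_id: str
    protospacer: str  # 5'->3' on the guide strand, 17-20 nt
    pam: str  # observed 3-mer at the genomic site (guide strand)
    chrom: str
    cut_locus: int  # 1-based; break between cut_locus and cut_locus+1
    strand: str  # '+' or '-'
    cds_fraction: float | None = None  # position of cut along CDS 5'->3'
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not 17 <= len(self.protospacer) <= 20:
            raise ValueError(f"{self.guide_id}: protospacer must be 17-20 nt")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError(f"{self.guide_id}: protospacer must be A/C/G/T")


@dataclass(frozen=True)
class NonEssentialRegion:
    """Maximal interval containing no essential-gene bases."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    contained_gene_ids: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def enumerate_protospacers(
    genome: AnnotatedGenome,
    gene: GeneRecord,
    pam_motif: str = "NGG",
    spacer_length: int = 20,
) -> list[Guide]:
    """All protospacer+PAM sites whose cut locus falls inside the CDS.

    Both strands are scanned.  The CDS fraction is measured 5'->3' on
    the gene strand, so a fraction of 0.1 means the cut lies one tenth
    into the coding sequence regardless of gene orientation.
    """
    if gene.length <= 0:
        warnings.warn(f"{gene.gene_id}: no CDS, no guides")
        return []
    seq = genome.chromosomes[gene.chrom]
    n = len(seq)
    L = spacer_length
    guides: list[Guide] = []
    counter = 0
    # plus strand: protospacer [p-L, p-1], PAM [p, p+2], cut after p-4
    for p in range(max(L + 1, gene.start - L), min(n - 2, gene.end + L) + 1):
        pam = seq[p - 1 : p + 2]
        cut = p - 4
        if not gene.start <= cut < gene.end:
            continue
        if len(pam) == 3 and iupac_matches(pam_motif, pam):
            proto = seq[p - 1 - L : p - 1]
            counter += 1
            guides.append(
                Guide(
                    f"{gene.gene_id}_g{counter}", proto, pam, gene.chrom, cut, "+",
                    cds_fraction=_cds_fraction(gene, cut), gene_id=gene.gene_id,
                )
            )
    # minus strand: protospacer genomic [s, s+L-1], PAM genomic [s-3, s-1]
    # (guide-strand sequence is the reverse complement); cut after s+2
    for s in range(max(4, gene.start - L), min(n - L + 1, gene.end + L) + 1):
        cut = s + 2
        if not gene.start <= cut < gene.end:
            continue
        pam_fwd = seq[s - 4 : s - 1]
        pam = revcomp(pam_fwd)
        if iupac_matches(pam_motif, pam):
            proto = revcomp(seq[s - 1 : s - 1 + L])
            counter += 1
            guides.append(
                Guide(
                    f"{gene.gene_id}_g{counter}", proto, pam, gene.chrom, cut, "-",
                    cds_fraction=_cds_fraction(gene, cut), gene_id=gene.gene_id,
                )
            )
    guides.sort(key=lambda g: (g.cut_locus, g.strand))
    return guides


def _cds_fraction(gene: GeneRecord, cut: int) -> float:
    # bases 5' of the cut bond on the gene strand (the bond sits between
    # genomic cut and cut+1, so minus-strand genes count end - cut bases)
    if gene.strand == "+":
        return (cut - gene.start + 1) / gene.length
    return (gene.end - cut) / gene.length


def filter_guides(
    candidates: list[Guide],
    cds_window: tuple[float, float] = (0.0, 0.4),
    uniqueness_scan: dict[str, list] | None = None,
    max_allowed_secondary_sites: int = 0,
) -> list[Guide]:
    """Keep guides cutting within the CDS window and genome-unique.

    ``uniqueness_scan`` maps guide id -> binding sites from the
    off-target scanner (any mismatch budget); a guide is kept when at
    most ``max_allowed_secondary_sites`` of those sites are not its own
    design locus.
    """
    low, high = cds_window
    if not low < high:
        raise ValueError("cds window low must be < high")
    kept = []
    for g in candidates:
        if g.cds_fraction is None or not low <= g.cds_fraction <= high:
            continue
        if uniqueness_scan is not None:
            sites = uniqueness_scan.get(g.guide_id, [])
            secondary = [s for s in sites if not _is_own_locus(g, s)]
            if len(secondary) > max_allowed_secondary_sites:
                continue
        kept.append(g)
    return kept


def _is_own_locus(guide: Guide, site) -> bool:
    return (
        site.chrom == guide.chrom
        and site.strand == guide.strand
        and site_cut_locus(site) == guide.cut_locus
    )


def site_cut_locus(site) -> int:
    """Blunt-cut position implied by a BindingSite span (see Guide)."""
    if site.strand == "+":
        return site.end - 6  # PAM occupies the last 3 bases of the span
    return site.start + 5


def find_nonessential_regions(
    genome: AnnotatedGenome, min_length: int = 50_000
) -> list[NonEssentialRegion]:
    """Maximal intervals free of essential-gene bases, >= ``min_length``.

    Regions are bounded by essential genes and chromosome ends; sorted
    by chromosome then start.  Contained gene ids list the (necessarily
    non-essential) genes lying fully inside each region.
    """
    regions: list[NonEssentialRegion] = []
    for chrom in sorted(genome.chromosomes):
        l_chrom = genome.chrom_length(chrom)
        blockers = sorted(
            (g.start, g.end) for g in genome.genes_on(chrom) if g.essential
        )
        merged: list[list[int]] = []
        for s, e in blockers:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps = []
        cursor = 1
        for s, e in merged:
            if s > cursor:
                gaps.append((cursor, s - 1))
            cursor = e + 1
        if cursor <= l_chrom:
            gaps.append((cursor, l_chrom))
        for s, e in gaps:
            if e - s + 1 >= min_length:
                contained = tuple(
                    g.gene_id
                    for g in sorted(genome.genes_on(chrom), key=lambda g: g.start)
                    if s <= g.start and g.end <= e
                )
                regions.append(NonEssentialRegion(chrom, s, e, contained))
    return regions


# ---------------------------------------------------------------------------
# I/O

_GUIDE_COLS = [
    "guide_id", "chrom", "cut_locus", "strand", "protospacer", "pam",
    "cds_fraction", "gene_id",
]


def write_guides_tsv(guides: list[Guide], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GUIDE_COLS) + "\n")
        for g in guides:
            frac = "" if g.cds_fraction is None else repr(g.cds_fraction)
            fh.write(
                f"{g.guide_id}\t{g.chrom}\t{g.cut_locus}\t{g.strand}\t"
                f"{g.protospacer}\t{g.pam}\t{frac}\t{g.gene_id or ''}\n"
            )


def read_guides_tsv(path: str | Path) -> list[Guide]:
    guides = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            guides.append(
                Guide(
                    row["guide_id"], row["protospacer"], row["pam"], row["chrom"],
                    int(row["cut_locus"]), row["strand"],
                    cds_fraction=float(row["cds_fraction"]) if row["cds_fraction"] else None,
                    gene_id=row.get("gene_id") or None,
                )
            )
    return guides


def write_regions_bed(regions: list[NonEssentialRegion], path: str | Path) -> None:
    """BED (0-based half-open, per the BED standard) of NE regions."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tNE_region_{i+1}\t{r.length}\t.\n")
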