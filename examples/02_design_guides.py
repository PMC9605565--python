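"""Design guides in early-CDS windows and find non-essential regions.

Enumerates every NGG-adjacent protospacer in one gene, keeps guides
whose blunt cut falls in the first 40% of the coding sequence and whose
protospacer is genome-unique, then lists the longest intervals free of
essential genes (knockout-safe regions).
"""

from edit_aftermath import (
    enumerate_protospacers,
    filter_guides,
    find_binding_sites,
    find_nonessential_regions,
    generate_genome,
)

genome = generate_genome(2, [150_000, 120_000], 40, 0.4, seed=7)
gene = next(g for g in genome.genes if not g.essential)
candidates = enumerate_protospacers(genome, gene, pam_motif="NGG", spacer_length=20)
print(f"{gene.gene_id} ({gene.chrom}:{gene.start}-{gene.end}, {gene.strand}): "
      f"{len(candidates)} candidate guides")

windowed = filter_guides(candidates, cds_window=(0.0, 0.4))
scan = {g.guide_id: find_binding_sites(genome, g, 0, {"NGG"}) for g in windowed}
kept = filter_guides(windowed, (0.0, 0.4), scan, max_allowed_secondary_sites=0)
print(f"{len(windowed)} cut within the first 40% of the CDS; "
      f"{len(kept)} are also genome-unique:")
for g in kept[:5]:
    print(f"  {g.guide_id}  cut {g.chrom}:{g.cut_locus}  "
          f"CDS fraction {g.cds_fraction:.2f}")

regions = find_nonessential_regions(genome, min_length=20_000)
print(f"\n{len(regions)} regions >= 20 kb without essential genes:")
for r in regions:
    print(f"  {r.chrom}:{r.start}-{r.end}  ({r.length/1000:.1f} kb, "
          f"{len(r.contained_gene_ids)} genes)")
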