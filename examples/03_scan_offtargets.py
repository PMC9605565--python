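"""Enumerate off-target binding sites under mismatch and PAM constraints.

Plants three degenerate copies of a guide (2, 4 and 8 mismatches) in a
random genome and scans with a 10-mismatch budget and NGG/NAG PAMs —
the exhaustive search used to ask whether a variant could stem from
unspecific nuclease activity.  Mismatches in the 5-base seed region
next to the PAM argue against real cleavage.
"""

import numpy as np

from edit_aftermath import find_binding_sites, sites_near_variants
from edit_aftermath.dna import random_dna
from edit_aftermath.genome import AnnotatedGenome
from edit_aftermath.guides import Guide
from edit_aftermath.variants import VariantCall, VariantType

rng = np.random.default_rng(5)
proto = random_dna(rng, 20)
seq = list(random_dna(rng, 50_000))
for pos, n_mm in ((10_000, 2), (20_000, 4), (30_000, 8)):
    copy = list(proto)
    for i in rng.choice(20, size=n_mm, replace=False):
        copy[i] = "ACGT"[("ACGT".index(copy[i]) + 1) % 4]
    seq[pos : pos + 23] = "".join(copy) + "TGG"
genome = AnnotatedGenome({"chr1": "".join(seq)}).validate()

guide = Guide("gX", proto, "TGG", "chr1", 100, "+")
sites = find_binding_sites(genome, guide, max_mismatches=10,
                           pam_motifs={"NGG", "NAG"}, seed_length=5)
close = [s for s in sites if s.mismatch_count < 9]
print(f"{len(sites)} binding sites with <= 10 mismatches (NGG or NAG PAM); "
      f"{len(close)} with fewer than 9 — the ones worth inspecting:")
for s in close:
    print(f"  {s.chrom}:{s.start}-{s.end} ({s.strand})  PAM {s.pam_observed}  "
          f"{s.mismatch_count} mismatches, {s.seed_mismatches} in the seed")

variant = VariantCall("dnm1", "s", "chr1", 20_035, "A", "T", VariantType.SNV)
hits = sites_near_variants(sites, [variant], window=30)
for h in hits:
    print(f"\nvariant {h.variant_id} is {h.relationship} of the site at "
          f"{h.site.chrom}:{h.site.start} ({h.site.mismatch_count} mismatches) "
          "- counted as a potential off-target association")
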