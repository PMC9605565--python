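"""Triage raw variant calls down to candidate de novo mutations.

Subtracts the base strain's pre-existing variants, removes an SNV
recurring across experiments with different guides (a shared artefact,
not an editing outcome), annotates coding effects, and splits the
survivors into on- and off-target mutations.
"""

from edit_aftermath import (
    build_ledger,
    drop_recurrent,
    generate_genome,
)
from edit_aftermath.guides import Guide
from edit_aftermath.pipeline import select_target_guides
from edit_aftermath.variants import VariantCall, VariantType

genome = generate_genome(2, [150_000, 120_000], 40, 0.3, seed=7)
(target,) = select_target_guides(genome, 1)


def snv(vid, chrom, pos, sample):
    ref = genome.fetch(chrom, pos, pos)
    alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    return VariantCall(vid, sample, chrom, pos, ref, alt, VariantType.SNV)


base = [snv("base1", "chr1", 50_000, "base"), snv("base2", "chr2", 60_000, "base")]
cut = target.cut_locus
ref = genome.fetch(target.chrom, cut, cut + 4)
on_target_del = VariantCall("del4", "exp1", target.chrom, cut, ref, ref[0],
                            VariantType.DEL, -4)
calls = {
    "exp1": [snv("base1", "chr1", 50_000, "exp1"),      # pre-existing
             snv("novel1", "chr1", 90_000, "exp1"),     # true DNM
             snv("artefact", "chr2", 30_000, "exp1"),   # recurs in exp2
             on_target_del],                            # the intended edit
    "exp2": [snv("artefact", "chr2", 30_000, "exp2")],
}

filtered, log = drop_recurrent(
    calls, min_experiments=2, require_distinct_guides=True,
    experiment_guides={"exp1": {"gA"}, "exp2": {"gB"}},
)
print(f"recurrent variants removed: {len(log)} "
      f"(seen in {log[0]['experiments']})" if log else "none removed")

ledger = build_ledger(
    calls, base, genome, {"exp1": [target], "exp2": []}, recurrence_log=log
)
print("\nper-call fates:")
for f in ledger.fates:
    print(f"  {f['sample_id']:5s} {f['variant_id']:9s} -> {f['fate']}"
          + (f" ({f['coding']}, {f['frame']})" if "coding" in f else ""))
print("\nledger totals:", ledger.totals())
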