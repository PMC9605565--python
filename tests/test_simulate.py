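"""Synthetic genome/outcome/read generator behaviour."""

import gzip
from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from edit_aftermath.dna import revcomp
from edit_aftermath.simulate import (
    ColonyTruth,
    EditClass,
    EditEvent,
    IndelSizeModel,
    ReadSet,
    SimulationError,
    apply_edits,
    generate_genome,
    plan_colony_outcomes,
    read_truth_manifest,
    simulate_pool_reads,
    write_truth_manifest,
)


def guide(gid, chrom, cut):
    return SimpleNamespace(guide_id=gid, chrom=chrom, cut_locus=cut)


# ---------------------------------------------------------------------------
# genome generation


def test_generate_genome_degenerate_gene_count():
    g = generate_genome(1, [50_000], 0, 0.0, seed=1)
    assert list(g.chromosomes) == ["chr1"]
    assert len(g.chromosomes["chr1"]) == 50_000
    assert g.genes == []


def test_generate_genome_deterministic_and_seed_sensitive():
    a = generate_genome(2, [30_000, 20_000], 25, 0.3, seed=7)
    b = generate_genome(2, [30_000, 20_000], 25, 0.3, seed=7)
    c = generate_genome(2, [30_000, 20_000], 25, 0.3, seed=8)
    assert a.chromosomes == b.chromosomes
    assert a.genes == b.genes
    assert a.chromosomes != c.chromosomes
    # essential count is an exact, reproducible draw for a fixed seed
    n_ess = sum(g.essential for g in a.genes)
    assert n_ess == sum(g.essential for g in b.genes)
    assert 0 < n_ess < 25


def test_generate_genome_rejects_bad_inputs():
    with pytest.raises(SimulationError):
        generate_genome(1, [5_000], 0, 0.0, seed=1)  # below 10 kb floor
    with pytest.raises(SimulationError):
        generate_genome(2, [15_000], 0, 0.0, seed=1)  # length list mismatch


def test_generate_genome_placement_failure():
    # 30 genes of >=300 bp cannot fit without overlap on 10 kb
    with pytest.raises(SimulationError):
        generate_genome(1, [10_000], 60, 0.0, seed=1)


# ---------------------------------------------------------------------------
# outcome planning


def test_point_mass_none_gives_wildtype_everywhere(small_genome):
    truths = plan_colony_outcomes(
        small_genome, [guide("g1", "chr1", 5000)], 20, {"none": 1.0}, seed=3
    )
    assert len(truths) == 20
    for t in truths:
        assert [e.edit_class for e in t.edits] == [EditClass.NONE]


def test_frame_preserving_fraction_matches_uniform_size_model(small_genome):
    # sizes uniform on 1..6 -> frame-preserving (3 or 6) with p = 1/3
    model = IndelSizeModel(small=(1, 6))
    truths = plan_colony_outcomes(
        small_genome, [guide("g1", "chr1", 5000)], 1000,
        {"small-indel": 1.0}, indel_size_model=model, seed=5,
    )
    nets = [t.edits[0].net_length_change for t in truths]
    assert all(1 <= abs(n) <= 6 for n in nets)
    frac = np.mean([n % 3 == 0 for n in nets])
    # 99% binomial CI around 1/3 at n=1000
    assert abs(frac - 1 / 3) <= 2.576 * np.sqrt((1 / 3) * (2 / 3) / 1000)


def test_forced_rearrangement_joins_both_cut_sites(small_genome):
    g1, g2 = guide("gA", "chr1", 4000), guide("gB", "chr2", 3000)
    truths = plan_colony_outcomes(
        small_genome, [g1, g2], 10, {"rearrangement": 1.0}, seed=9
    )
    for t in truths:
        (e,) = t.edits
        assert e.edit_class == EditClass.REARRANGEMENT
        assert (e.chrom, e.position) == ("chr1", 4000)
        assert (e.chrom2, e.position2) == ("chr2", 3000)


def test_rearrangement_requires_two_guides(small_genome):
    with pytest.raises(SimulationError, match="two guides"):
        plan_colony_outcomes(
            small_genome, [guide("g1", "chr1", 5000)], 5,
            {"rearrangement": 1.0}, seed=1,
        )


def test_class_probabilities_must_sum_to_one(small_genome):
    with pytest.raises(SimulationError, match="sum to 1"):
        plan_colony_outcomes(
            small_genome, [guide("g1", "chr1", 5000)], 5, {"none": 0.5}, seed=1
        )


def test_pool_assignment_groups_of_five(small_genome):
    truths = plan_colony_outcomes(
        small_genome, [guide("g1", "chr1", 5000)], 12, {"none": 1.0},
        seed=1, pool_size=5,
    )
    pools = [t.pool_id for t in truths]
    assert pools == ["pool1"] * 5 + ["pool2"] * 5 + ["pool3"] * 2


# ---------------------------------------------------------------------------
# genome surgery


def test_apply_empty_edit_list_is_identity(small_genome):
    out = apply_edits(small_genome, ColonyTruth("c", "p", []))
    assert out.chromosomes == small_genome.chromosomes


def test_apply_deletion_coordinate_arithmetic():
    g = generate_genome(1, [50_000], 0, 0.0, seed=2)
    seq = g.chromosomes["chr1"]
    p = 20_000
    ref = seq[p - 1 : p + 10]  # anchor + 10 deleted bases
    e = EditEvent(EditClass.SMALL_INDEL, "chr1", p, ref=ref, alt=ref[0],
                  net_length_change=-10)
    out = apply_edits(g, ColonyTruth("c", "p", [e])).chromosomes["chr1"]
    assert len(out) == 49_990
    assert out[:p] == seq[:p]  # up to and including the anchor base
    assert out[p:] == seq[p + 10 :]  # downstream shifted left by 10


def test_apply_insertion_and_substitution_alleles():
    g = generate_genome(1, [12_000], 0, 0.0, seed=3)
    seq = g.chromosomes["chr1"]
    p = 6_000
    e = EditEvent(EditClass.SMALL_INDEL, "chr1", p, ref=seq[p - 1],
                  alt=seq[p - 1] + "ACGTT", net_length_change=5)
    out = apply_edits(g, ColonyTruth("c", "p", [e])).chromosomes["chr1"]
    assert len(out) == 12_005
    assert out[p - 1 : p + 5] == seq[p - 1] + "ACGTT"
    assert out[p + 5 :] == seq[p:]


def test_apply_truncation_length_bookkeeping():
    g = generate_genome(1, [15_000], 0, 0.0, seed=4)
    t, motif, copies = 9_000, "GGTGTAGT", 10
    e = EditEvent(EditClass.TRUNCATION, "chr1", t, telomere_capped=True,
                  inserted_sequence=motif * copies,
                  net_length_change=-(15_000 - t) + copies * len(motif))
    out = apply_edits(g, ColonyTruth("c", "p", [e])).chromosomes["chr1"]
    assert len(out) == t + copies * len(motif)
    assert out.endswith(motif * copies)
    assert out[:t] == g.chromosomes["chr1"][:t]


def test_apply_inversion_reverse_complements_segment():
    g = generate_genome(1, [12_000], 0, 0.0, seed=5)
    seq = g.chromosomes["chr1"]
    e = EditEvent(EditClass.INVERSION, "chr1", 4_000, end=4_500)
    out = apply_edits(g, ColonyTruth("c", "p", [e])).chromosomes["chr1"]
    assert len(out) == len(seq)
    assert out[4_000:4_500] == revcomp(seq[4_000:4_500])
    assert out[:4_000] == seq[:4_000] and out[4_500:] == seq[4_500:]


def test_apply_rearrangement_is_reciprocal_translocation(small_genome):
    a, b = 4_000, 3_000
    e = EditEvent(EditClass.REARRANGEMENT, "chr1", a, chrom2="chr2", position2=b)
    out = apply_edits(small_genome, ColonyTruth("c", "p", [e]))
    c1, c2 = small_genome.chromosomes["chr1"], small_genome.chromosomes["chr2"]
    assert out.chromosomes["chr1"] == c1[:a] + c2[b:]
    assert out.chromosomes["chr2"] == c2[:b] + c1[a:]
    total_in = len(c1) + len(c2)
    assert sum(map(len, out.chromosomes.values())) == total_in


def test_overlapping_edits_rejected_naming_both():
    g = generate_genome(1, [12_000], 0, 0.0, seed=6)
    seq = g.chromosomes["chr1"]
    e1 = EditEvent(EditClass.SMALL_INDEL, "chr1", 5000, ref=seq[4999:5010],
                   alt=seq[4999], net_length_change=-10)
    e2 = EditEvent(EditClass.SMALL_INDEL, "chr1", 5005, ref=seq[5004:5010],
                   alt=seq[5004], net_length_change=-5)
    with pytest.raises(SimulationError) as err:
        apply_edits(g, ColonyTruth("c", "p", [e1, e2]))
    assert "5000" in str(err.value) and "5005" in str(err.value)


def test_length_conservation_over_planned_edits(small_genome):
    truths = plan_colony_outcomes(
        small_genome, [guide("g1", "chr1", 9000), guide("g2", "chr2", 8000)],
        30, {"none": 0.2, "small-indel": 0.4, "large-indel": 0.3, "inversion": 0.1},
        seed=13,
    )
    total_in = sum(map(len, small_genome.chromosomes.values()))
    for t in truths:
        out = apply_edits(small_genome, t)
        net = sum(e.net_length_change for e in t.edits)
        assert sum(map(len, out.chromosomes.values())) == total_in + net


def test_small_indel_net_change_bounds_enforced():
    with pytest.raises(SimulationError):
        EditEvent(EditClass.SMALL_INDEL, "c", 1, ref="A" * 51, alt="A",
                  net_length_change=-50)
    with pytest.raises(SimulationError):
        EditEvent(EditClass.LARGE_INDEL, "c", 1, ref="A" * 11, alt="A",
                  net_length_change=-10)
    with pytest.raises(SimulationError):
        EditEvent(EditClass.TRUNCATION, "c", 1, telomere_capped=False)


# ---------------------------------------------------------------------------
# read simulation


def test_error_free_reads_match_their_origin(small_genome):
    rs = simulate_pool_reads([small_genome], coverage=5, error_rate=0.0, seed=21)
    for i in range(0, rs.n_pairs, 37):
        colony, chrom, pos = rs.origin(i)
        seq = small_genome.chromosomes[chrom]
        _, m1, m2 = rs.pair(i)
        assert m1 == seq[pos - 1 : pos - 1 + rs.read_length]
        # mate2 reverse-complements the far fragment end
        neighbourhood = seq[pos - 1 : pos - 1 + 1200]
        assert revcomp(m2) in neighbourhood


def test_pool_share_is_equal_among_members(small_genome):
    genomes = [small_genome] * 5
    rs = simulate_pool_reads(genomes, coverage=300, error_rate=0.0, seed=22,
                             colony_ids=[f"c{i}" for i in range(5)])
    counts = np.bincount(rs.origin_colony, minlength=5)
    frac = counts / rs.n_pairs
    sd = np.sqrt(0.2 * 0.8 / rs.n_pairs)
    assert np.all(np.abs(frac - 0.2) <= 3 * sd)


def test_read_pair_count_follows_coverage_arithmetic(small_genome):
    rs = simulate_pool_reads([small_genome], coverage=100, seed=23)
    expected = 100 * 50_000 / (2 * 150)
    assert abs(rs.n_pairs - expected) <= 0.05 * expected


def test_error_rate_perturbs_expected_base_fraction(small_genome):
    rs0 = simulate_pool_reads([small_genome], coverage=20, error_rate=0.0, seed=24)
    rs1 = simulate_pool_reads([small_genome], coverage=20, error_rate=0.01, seed=24)
    diff = (rs0.mate1 != rs1.mate1).mean()
    assert 0.005 < diff < 0.015


def test_fragment_and_read_length_validation(small_genome):
    with pytest.raises(SimulationError):
        simulate_pool_reads([small_genome], 10, read_length=600, fragment_mean=550)
    with pytest.warns(UserWarning, match="inner mates overlap"):
        simulate_pool_reads([small_genome], 1, read_length=150, fragment_mean=200,
                            seed=1)
    with pytest.raises(SimulationError):
        simulate_pool_reads([small_genome] * 6, 10)
    with pytest.raises(SimulationError):
        simulate_pool_reads([small_genome], 0)


def test_fastq_round_trip_and_gzip_determinism(small_genome, tmp_path):
    rs = simulate_pool_reads([small_genome], coverage=2, error_rate=0.001, seed=25)
    p1a, p2a = tmp_path / "a_R1.fastq.gz", tmp_path / "a_R2.fastq.gz"
    p1b, p2b = tmp_path / "b_R1.fastq.gz", tmp_path / "b_R2.fastq.gz"
    rs.write_fastq(p1a, p2a)
    rs.write_fastq(p1b, p2b)
    assert p1a.read_bytes() == p1b.read_bytes()  # mtime pinned: byte-identical
    back = ReadSet.from_fastq(p1a, p2a)
    assert back.n_pairs == rs.n_pairs
    assert (back.mate1 == rs.mate1).all() and (back.mate2 == rs.mate2).all()
    with gzip.open(p1a, "rt") as fh:
        first = [next(fh) for _ in range(4)]
    assert first[0].startswith("@read") and first[3].strip() == "I" * 150


def test_identical_seed_reproduces_reads(small_genome):
    a = simulate_pool_reads([small_genome], 10, error_rate=0.001, seed=31)
    b = simulate_pool_reads([small_genome], 10, error_rate=0.001, seed=31)
    assert (a.mate1 == b.mate1).all() and (a.mate2 == b.mate2).all()
    assert (a.origin_pos == b.origin_pos).all()


def test_truth_manifest_round_trip(small_genome, tmp_path):
    truths = plan_colony_outcomes(
        small_genome, [guide("g1", "chr1", 9000), guide("g2", "chr2", 8000)],
        6, {"none": 0.3, "small-indel": 0.3, "truncation": 0.2, "inversion": 0.2},
        seed=17,
    )
    path = tmp_path / "truth.tsv"
    write_truth_manifest(truths, path)
    back = read_truth_manifest(path)
    assert [t.colony_id for t in back] == [t.colony_id for t in truths]
    for t_in, t_out in zip(truths, back):
        assert t_in.pool_id == t_out.pool_id
        assert t_in.edits == t_out.edits
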