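"""Synthetic-data generator: tiling, truth conservation, determinism."""

import numpy as np
import pandas as pd
import pytest

from satquant import io, simulate
from satquant.repeats import ConsensusRepeat


def test_satellite_array_is_exact_concatenation_without_mutation():
    cons = ConsensusRepeat("toy", (("m", "ACGT"),), "monomer")
    seq, intervals = simulate.simulate_satellite_array(cons, 3, 0.0, seed=1)
    assert seq == "ACGTACGTACGT"
    assert intervals == [(0, 4, "copy0"), (4, 8, "copy1"), (8, 12, "copy2")]


def test_satellite_array_zero_copies_is_empty():
    cons = ConsensusRepeat("toy", (("m", "ACGT"),), "monomer")
    seq, intervals = simulate.simulate_satellite_array(cons, 0, 0.0, seed=1)
    assert seq == "" and intervals == []


def test_dimer_array_alternates_left_right(rsp_consensus):
    seq, intervals = simulate.simulate_satellite_array(rsp_consensus, 2, 0.0, seed=1)
    left = rsp_consensus.units[0][1]
    right = rsp_consensus.units[1][1]
    assert seq == (left + right) * 2
    assert [iv[:2] for iv in intervals] == [(0, 240), (240, 480)]


def test_non_acgt_consensus_rejected():
    with pytest.raises(ValueError, match="non-ACGT"):
        ConsensusRepeat("bad", (("m", "ACGN"),), "monomer")
    with pytest.raises(ValueError, match="empty"):
        ConsensusRepeat("bad", (("m", ""),), "monomer")


def test_mutated_array_hamming_distance_matches_rate(mono_consensus):
    # 359-bp monomer x 1000 copies at 1% substitution: the Hamming
    # distance to the unmutated array is binomial(n, rate)
    n = 1000 * 359
    clean, _ = simulate.simulate_satellite_array(mono_consensus, 1000, 0.0, seed=5)
    noisy, _ = simulate.simulate_satellite_array(mono_consensus, 1000, 0.01, seed=5)
    dist = sum(a != b for a, b in zip(clean, noisy))
    assert abs(dist - 0.01 * n) < 3 * np.sqrt(n * 0.01 * 0.99)


def test_array_intervals_tile_exactly(mono_consensus):
    seq, intervals = simulate.simulate_satellite_array(mono_consensus, 7, 0.05, seed=2)
    assert intervals[0][0] == 0 and intervals[-1][1] == len(seq)
    assert all(a[1] == b[0] for a, b in zip(intervals, intervals[1:]))


# ------------------------------------------------------------------- genome


def test_genome_length_is_background_plus_arrays():
    locus = simulate.LocusSpec(
        name="sat1", family="1.688_359bp", feature_class="satDNA",
        compartment="heterochromatic", copies=10, abundance=1.0,
    )
    cfg = simulate.SimulationConfig(seed=3, background_length=5_000, loci=(locus,))
    sim = simulate.build_genome(cfg)
    assert len(sim.sequences["sim1"]) == 5_000 + 3_590
    sats = [f for f in sim.annotation if f.feature_class == "satDNA"]
    assert len(sats) == 1 and sats[0].compartment == "heterochromatic"
    assert sats[0].length == 3_590


def test_genome_with_no_loci_is_background_only():
    cfg = simulate.SimulationConfig(seed=3, background_length=4_000)
    sim = simulate.build_genome(cfg)
    assert len(sim.sequences["sim1"]) == 4_000
    assert len(sim.annotation) == 0


@pytest.mark.parametrize("copies", [200, 600, 1100, 2300, 4100])
def test_strain_locus_length_scales_linearly_with_copies(copies):
    locus = simulate.LocusSpec(
        name="Rsp_major", family="Rsp", feature_class="satDNA",
        compartment="heterochromatic", copies=copies, abundance=float(copies),
    )
    cfg = simulate.SimulationConfig(seed=9, background_length=10_000, loci=(locus,))
    sim = simulate.build_genome(cfg)
    feat = sim.annotation["Rsp_major"]
    assert feat.length == copies * 240  # Left+Right dimer per copy


def test_explicit_overlapping_placements_rejected():
    mk = lambda name, off: simulate.LocusSpec(
        name=name, family="gene", feature_class="gene", compartment="euchromatic",
        length=500, offset=off,
    )
    cfg = simulate.SimulationConfig(seed=1, background_length=5_000,
                                    loci=(mk("g1", 100), mk("g2", 400)))
    with pytest.raises(ValueError, match="g1.*overlaps.*g2"):
        simulate.build_genome(cfg)


def test_demo_genome_has_euchromatic_satellite_insertion(demo_sim):
    eu_sats = [
        f for f in demo_sim.annotation
        if f.feature_class == "satDNA" and f.compartment == "euchromatic"
    ]
    assert len(eu_sats) == 1 and eu_sats[0].family == "Rsp"


def test_gff_round_trip_preserves_fields(demo_sim, tmp_path):
    path = tmp_path / "ann.gff3"
    demo_sim.annotation.to_gff(path)
    back = type(demo_sim.annotation).from_gff(path)
    assert back.contig_lengths == demo_sim.annotation.contig_lengths
    assert back.features == demo_sim.annotation.features


# ---------------------------------------------------------------- small RNA


def test_small_rna_truth_record_per_read(demo_sim):
    reads = simulate.simulate_small_rna_reads(demo_sim, n_reads=500, seed=4)
    assert len(reads) == 500
    assert reads["read_id"].is_unique
    contig_len = demo_sim.annotation.contig_lengths["sim1"]
    assert (reads["start"] >= 0).all() and (reads["end"] <= contig_len).all()


def test_small_rna_zero_reads_empty(demo_sim):
    reads = simulate.simulate_small_rna_reads(demo_sim, n_reads=0, seed=4)
    assert len(reads) == 0


def test_responder_pairs_overlap_exactly_ten(demo_sim):
    reads = simulate.simulate_small_rna_reads(demo_sim, n_reads=4_000, seed=6)
    resp = reads[reads["category"] == "responder"]
    assert len(resp) > 100
    plus = np.where(resp["template_strand"] == "+",
                    resp["template_five_prime"].astype(float), resp["five_prime"])
    minus = np.where(resp["template_strand"] == "+",
                     resp["five_prime"], resp["template_five_prime"].astype(float))
    assert ((minus - plus + 1) == 10).all()


def test_all_responders_with_forced_u1_have_a_at_position_ten():
    cfg = simulate.single_locus_config(2, pingpong_fraction=1.0)
    sim = simulate.build_genome(cfg)
    model = simulate.PirnaModel(pingpong_fraction=1.0, u1_bias=1.0)
    reads = simulate.simulate_small_rna_reads(sim, model, n_reads=300, seed=2)
    assert (reads["category"] == "responder").all()
    assert (reads["sequence"].str[9] == "A").all()


def test_u1_fraction_recovers_configured_bias(demo_sim):
    b, n = 0.6, 5_000
    model = simulate.PirnaModel(pingpong_fraction=0.0, u1_bias=b)
    reads = simulate.simulate_small_rna_reads(demo_sim, model, n_reads=n, seed=8)
    observed = (reads["sequence"].str[0] == "T").mean()
    assert abs(observed - b) < 4 * np.sqrt(b * (1 - b) / n)


def test_read_lengths_respect_bounds(demo_sim):
    reads = simulate.simulate_small_rna_reads(demo_sim, n_reads=2_000, seed=9)
    lengths = reads["sequence"].str.len()
    assert lengths.between(23, 28).all()
    assert (lengths == reads["length"]).all()


def test_pingpong_without_dual_strand_locus_errors():
    locus = simulate.LocusSpec(
        name="uni", family="flamenco", feature_class="piRNA_cluster_uni",
        compartment="heterochromatic", length=2_000, abundance=1.0,
        strand_model="plus",
    )
    cfg = simulate.SimulationConfig(seed=1, background_length=4_000, loci=(locus,))
    sim = simulate.build_genome(cfg)
    with pytest.raises(ValueError, match="dual-strand"):
        simulate.simulate_small_rna_reads(
            sim, simulate.PirnaModel(pingpong_fraction=0.5), n_reads=100, seed=1
        )


def test_read_counts_track_abundance(demo_sim):
    reads = simulate.simulate_small_rna_reads(demo_sim, n_reads=40_000, seed=10)
    truth = demo_sim.locus_truth.set_index("locus_id")
    counts = reads["locus_id"].value_counts()
    weights = truth["abundance"] / truth["abundance"].sum()
    for locus in ("Rsp_het", "flamenco", "mir1"):
        expect = 40_000 * weights[locus]
        assert abs(counts[locus] - expect) < 4 * np.sqrt(expect)


# --------------------------------------------------------------------- ChIP


def test_chip_reads_conserve_truth_records(demo_sim):
    chip, inp = simulate.simulate_chip_reads(demo_sim, n_reads=2_000, seed=5)
    assert len(chip) == 2_000 and len(inp) == 2_000
    assert (chip["category"] == "chip").all() and (inp["category"] == "input").all()


def test_chip_zero_reads(demo_sim):
    chip, inp = simulate.simulate_chip_reads(demo_sim, n_reads=0, seed=5)
    assert len(chip) == 0 and len(inp) == 0
    with pytest.raises(ValueError):
        simulate.simulate_chip_reads(demo_sim, n_reads=-1, seed=5)


# ---------------------------------------------------------------- knockdown


def test_knockdown_identity_factor_leaves_config_unchanged():
    cfg = simulate.demo_config(1)
    kd = simulate.simulate_knockdown(cfg, {"rdc": 1.0})
    assert [l.abundance for l in kd.loci] == [l.abundance for l in cfg.loci]


def test_knockdown_scales_rdc_classes_only():
    cfg = simulate.demo_config(1)
    kd = simulate.simulate_knockdown(cfg, {"rdc": 0.05})
    for before, after in zip(cfg.loci, kd.loci):
        if before.feature_class in ("satDNA", "piRNA_cluster_dual"):
            assert after.abundance == pytest.approx(before.abundance * 0.05)
        else:
            assert after.abundance == before.abundance
    assert kd.knockdown_applied == {"rdc": 0.05}


def test_knockdown_rejects_unknown_class_and_bad_factor():
    cfg = simulate.demo_config(1)
    with pytest.raises(ValueError, match="unknown regulatory class"):
        simulate.simulate_knockdown(cfg, {"zucchini": 0.5})
    with pytest.raises(ValueError, match="factor"):
        simulate.simulate_knockdown(cfg, {"rdc": 0.0})


# --------------------------------------------------------------------- qPCR


def test_qpcr_quantity_ratio_maps_to_ct_difference():
    table = simulate.simulate_qpcr(
        {"a": {"Rsp": 4.0, "tRNA": 1.0}, "b": {"Rsp": 1.0, "tRNA": 1.0}},
        efficiency=1.0, noise_sd=0.0, replicates=2, seed=1,
    )
    ct = table.groupby(["sample", "target"])["ct"].mean()
    assert ct[("a", "Rsp")] - ct[("b", "Rsp")] == pytest.approx(-2.0)
    assert ct[("a", "tRNA")] == pytest.approx(ct[("b", "tRNA")])


def test_qpcr_rejects_nonpositive_quantity():
    with pytest.raises(ValueError, match="quantity"):
        simulate.simulate_qpcr({"a": {"Rsp": 0.0}}, seed=1)


# ------------------------------------------------------------- determinism


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    def render(sub):
        cfg = simulate.demo_config(77, background_length=60_000)
        sim = simulate.build_genome(cfg)
        reads = simulate.simulate_small_rna_reads(sim, n_reads=1_000, seed=77)
        d = tmp_path / sub
        d.mkdir()
        io.write_fasta(sim.sequences, d / "g.fasta")
        sim.annotation.to_gff(d / "a.gff3")
        io.write_fastq(zip(reads["read_id"], reads["sequence"]), d / "r.fastq")
        io.write_truth(reads.drop(columns=["sequence"]), d / "t.tsv")
        return d

    d1, d2 = render("one"), render("two")
    for name in ("g.fasta", "a.gff3", "r.fastq", "t.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_different_operation_streams_are_independent(demo_sim):
    # the same seed drives different operations through different streams
    a = simulate.simulate_small_rna_reads(demo_sim, n_reads=50, seed=3,
                                          stream_name="small_rna:x")
    b = simulate.simulate_small_rna_reads(demo_sim, n_reads=50, seed=3,
                                          stream_name="small_rna:y")
    assert not a["five_prime"].equals(b["five_prime"])
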