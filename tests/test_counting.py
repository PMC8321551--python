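"""Alignment ingestion, the brute-force mapper oracle, multimapper
policies, and feature/window counting."""

import numpy as np
import pytest

from satquant import counting, simulate
from satquant.annotation import Feature, RepeatAnnotation
from satquant.counting import Hit

from conftest import make_alignment


# ------------------------------------------------------------ brute mapper


def test_bruteforce_single_exact_hit():
    out = counting.map_reads_bruteforce([("r1", "ACGT")], {"g": "AAAACGTAAAA"})
    (aln,) = out
    assert aln.best_hits == [Hit("g", 3, "+", 0)]


def test_bruteforce_reports_all_best_positions():
    (aln,) = counting.map_reads_bruteforce([("r1", "ACGT")], {"g": "ACGTACGT"})
    assert [(h.contig, h.five_prime, h.strand) for h in aln.best_hits] == [
        ("g", 0, "+"),
        ("g", 4, "+"),
    ]


def test_bruteforce_minus_strand_hit():
    genome = "ACGGTTCAAT"
    read = "AACC"  # reverse complement of genome[2:6] == "GGTT"
    (aln,) = counting.map_reads_bruteforce([("r1", read)], {"g": genome})
    (hit,) = aln.best_hits
    # leftmost reference base 2; the read's 5' end is the rightmost base
    assert hit.strand == "-" and hit.five_prime == 5


def test_bruteforce_minimal_distance_only():
    # exact hit exists, so the 1-mismatch placement (AAAC at 8) is not reported
    (aln,) = counting.map_reads_bruteforce(
        [("r1", "AAAA")], {"g": "AAAACCCCAAAC"}, max_mismatch=1
    )
    assert [h.five_prime for h in aln.best_hits] == [0]
    assert all(h.mismatches == 0 for h in aln.best_hits)


def test_bruteforce_guard_rejects_large_input():
    with pytest.raises(ValueError, match="guard"):
        counting.map_reads_bruteforce([("r", "ACGT")], {"g": "A" * 20_000_000})


def test_sam_round_trip_preserves_best_hits(tmp_path):
    genome = {"g": "ACGTACGTTTTTTT"}
    reads = [("r1", "ACGTA"), ("r2", "GGGGG")]  # r2 unmapped at 0 mismatches
    sam = tmp_path / "toy.sam"
    direct = counting.map_reads_bruteforce(reads, genome, sam_out=sam)
    loaded, n_unmapped = counting.read_alignments(sam)
    assert n_unmapped == 1
    mapped = {a.read_id: a.best_hits for a in direct if a.best_hits}
    assert {a.read_id: a.best_hits for a in loaded} == mapped


def test_read_alignments_keeps_minimal_mismatch_hits(tmp_path):
    sam = tmp_path / "multi.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:100\n"
        "r1\t0\tc1\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\tNM:i:0\n"
        "r1\t256\tc1\t11\t255\t4M\t*\t0\t0\tACGT\tIIII\tNM:i:0\n"
        "r1\t256\tc1\t21\t255\t4M\t*\t0\t0\tACGT\tIIII\tNM:i:1\n"
        "r2\t0\tc1\t31\t255\t4M\t*\t0\t0\tACGT\tIIII\tNM:i:2\n"
    )
    alignments, n_unmapped = counting.read_alignments(sam)
    assert n_unmapped == 0
    by_id = {a.read_id: a for a in alignments}
    assert by_id["r1"].n_best == 2
    assert [h.five_prime for h in by_id["r1"].best_hits] == [0, 10]
    assert by_id["r2"].n_best == 1


# -------------------------------------------------------------- assignment


def test_fractional_assignment_splits_evenly():
    aln = make_alignment("r", [("c", 0, "+", 0), ("c", 5, "+", 0), ("c", 9, "-", 0)])
    (out,) = counting.assign_multimappers([aln], "fractional")
    assert [w for _, w in out.assigned] == pytest.approx([1 / 3] * 3)


def test_unique_assignment_drops_multimappers():
    multi = make_alignment("m", [("c", 0, "+", 0), ("c", 5, "+", 0)])
    single = make_alignment("s", [("c", 2, "+", 0)])
    out = counting.assign_multimappers([multi, single], "unique")
    weights = {a.read_id: a.weight_sum for a in out}
    assert weights == {"m": 0.0, "s": 1.0}


def test_random_assignment_is_reproducible():
    def run():
        alns = [
            make_alignment(f"r{i}", [("c", 0, "+", 0), ("c", 5, "+", 0)])
            for i in range(50)
        ]
        out = counting.assign_multimappers(alns, "random", seed=42)
        return [a.assigned[0][0].five_prime for a in out]

    assert run() == run()
    with pytest.raises(ValueError, match="seed"):
        counting.assign_multimappers([], "random")


# ---------------------------------------------------------------- counting


def test_counts_conserve_total_weight(toy_annotation):
    alns = [make_alignment(f"r{i}", [("chrT", 1500 + i, "+", 0)]) for i in range(10)]
    out = counting.assign_multimappers(alns, "fractional")
    matrix = counting.count_features(out, toy_annotation)
    assert matrix.counts.at["locusA", "sample"] == pytest.approx(10.0, abs=1e-12)
    assert matrix.totals.at["total_mapped", "sample"] == 10


def test_read_assigned_by_five_prime_only(toy_annotation):
    # 5' coordinate inside locusA even though the body crosses its end
    aln = make_alignment("r", [("chrT", 3999, "+", 0)], length=30)
    out = counting.assign_multimappers([aln], "fractional")
    matrix = counting.count_features(out, toy_annotation)
    assert matrix.counts.at["locusA", "sample"] == 1.0
    assert matrix.counts.at["locusB", "sample"] == 0.0


def test_hits_outside_features_counted_unannotated(toy_annotation):
    aln = make_alignment("r", [("chrT", 100, "+", 0)])
    out = counting.assign_multimappers([aln], "fractional")
    matrix = counting.count_features(out, toy_annotation)
    assert matrix.counts.at["unannotated", "sample"] == 1.0


def test_conservation_on_randomized_toy_inputs(random_toy_case):
    for seed in range(10):
        annotation, alignments = random_toy_case(seed)
        out = counting.assign_multimappers(alignments, "fractional")
        matrix = counting.count_features(out, annotation)
        assert matrix.primary_rows()["sample"].sum() == pytest.approx(
            matrix.totals.at["total_mapped", "sample"], abs=1e-9
        )


def test_combined_family_row_sums_subfamilies(demo_sim):
    reads = simulate.simulate_small_rna_reads(demo_sim, n_reads=3_000, seed=1)
    out = counting.assign_multimappers(
        counting.alignments_from_truth(reads), "fractional"
    )
    matrix = counting.count_features(out, demo_sim.annotation, group_by="family")
    assert "1.688" in matrix.derived_rows
    combined = matrix.counts.at["1.688", "sample"]
    parts = matrix.counts.loc[["1.688_260bp", "1.688_359bp"], "sample"].sum()
    assert combined == pytest.approx(parts)
    # derived rows excluded from the conservation sum
    assert matrix.primary_rows()["sample"].sum() == pytest.approx(3_000, abs=1e-9)


def test_random_policy_converges_to_fractional(toy_annotation):
    alns = [
        make_alignment(f"r{i}", [("chrT", 1500, "+", 0), ("chrT", 6000, "+", 0)])
        for i in range(200)
    ]
    frac = counting.count_features(
        counting.assign_multimappers(alns, "fractional"), toy_annotation
    ).counts.at["locusA", "sample"]
    draws = []
    for seed in range(50):
        for a in alns:
            a.assigned = []
        rand = counting.count_features(
            counting.assign_multimappers(alns, "random", seed=seed), toy_annotation
        )
        draws.append(rand.counts.at["locusA", "sample"])
    se = np.std(draws, ddof=1) / np.sqrt(len(draws))
    assert abs(np.mean(draws) - frac) < 3 * max(se, 1e-9)


def test_unique_counts_bounded_by_fractional(random_toy_case):
    annotation, alignments = random_toy_case(99)
    frac = counting.count_features(
        counting.assign_multimappers(alignments, "fractional"), annotation
    )
    for a in alignments:
        a.assigned = []
    uniq = counting.count_features(
        counting.assign_multimappers(alignments, "unique"), annotation
    )
    dropped = sum(1 for a in alignments if a.n_best > 1)
    for feature in frac.features:
        assert (
            uniq.counts.at[feature, "sample"]
            <= frac.counts.at[feature, "sample"] + dropped + 1e-9
        )


# ----------------------------------------------------------------- windows


def test_window_counts_tile_locus(toy_annotation):
    feature = toy_annotation["locusA"]  # [1000, 4000)
    alns = [
        make_alignment(f"r{i}", [("chrT", 1000 + off, "+", 0)])
        for i, off in enumerate((100, 1500, 2900))
    ]
    out = counting.assign_multimappers(alns, "fractional")
    windows = counting.count_windows(out, feature, 1000)
    assert windows.tolist() == [1.0, 1.0, 1.0]


def test_window_tiling_arithmetic(toy_annotation):
    feature = toy_annotation["locusB"]  # 2500 bp
    assert counting.count_windows([], feature, 1000).shape == (3,)
    assert counting.count_windows([], feature, 1000).sum() == 0.0


def test_oversized_window_warns_single_window(toy_annotation):
    feature = toy_annotation["locusB"]
    with pytest.warns(UserWarning, match="single window"):
        windows = counting.count_windows([], feature, 5000)
    assert windows.shape == (1,)


# ----------------------------------------------------------- normalisation


def test_rpm_normalisation(toy_annotation):
    alns = [make_alignment(f"r{i}", [("chrT", 1500, "+", 0)]) for i in range(50)]
    out = counting.assign_multimappers(alns, "fractional")
    matrix = counting.count_features(out, toy_annotation)
    matrix.totals.at["total_mapped", "sample"] = 2_000_000
    rpm = counting.normalize(matrix, "rpm_total")
    assert rpm.counts.at["locusA", "sample"] == pytest.approx(25.0)
    assert rpm.units == "rpm_total"


def test_reference_normalisation_and_zero_error(toy_annotation):
    alns = [make_alignment(f"r{i}", [("chrT", 1500, "+", 0)]) for i in range(50)]
    out = counting.assign_multimappers(alns, "fractional")
    matrix = counting.count_features(out, toy_annotation)
    matrix.totals.at["mirna_mapped", "sample"] = 25_000
    per_mirna = counting.normalize(matrix, "per_million_reference", "mirna")
    assert per_mirna.counts.at["locusA", "sample"] == pytest.approx(2_000.0)
    matrix.totals.at["flamenco_mapped", "sample"] = 0
    with pytest.raises(ValueError, match="sample"):
        counting.normalize(matrix, "per_million_reference", "flamenco")


def test_log2_ratios_invariant_to_normaliser_scale(toy_annotation):
    # the 1e6 scale cancels: ratios between samples are unchanged under
    # any fixed positive normaliser constant
    alns = [make_alignment(f"r{i}", [("chrT", 1500, "+", 0)]) for i in range(64)]
    out = counting.assign_multimappers(alns, "fractional")
    a = counting.count_features(out, toy_annotation, sample="a")
    b = counting.count_features(out, toy_annotation, sample="b")
    b.counts["b"] *= 2  # same library, doubled depth
    b.totals.loc["total_mapped", "b"] *= 2
    joined = a.join(b)
    rpm = counting.normalize(joined, "rpm_total")
    ratio = rpm.counts.at["locusA", "b"] / rpm.counts.at["locusA", "a"]
    assert np.log2(ratio) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------- summaries


def test_strand_ratio_balanced_and_infinite(toy_annotation):
    feature = toy_annotation["locusA"]
    alns = [
        make_alignment(f"p{i}", [("chrT", 1500, "+", 0)]) for i in range(5)
    ] + [make_alignment(f"m{i}", [("chrT", 1500, "-", 0)]) for i in range(5)]
    out = counting.assign_multimappers(alns, "fractional")
    ratio = counting.strand_ratio(out, feature)
    assert ratio.ratio == pytest.approx(1.0) and not ratio.infinite
    plus_only = counting.assign_multimappers(
        [make_alignment("p", [("chrT", 1500, "+", 0)])], "fractional"
    )
    assert counting.strand_ratio(plus_only, feature).infinite


def test_fraction_of_mapped(toy_annotation):
    alns = [make_alignment(f"r{i}", [("chrT", 1500, "+", 0)]) for i in range(9)]
    out = counting.assign_multimappers(alns, "fractional")
    matrix = counting.count_features(out, toy_annotation)
    matrix.totals.at["total_mapped", "sample"] = 1_000
    assert counting.fraction_of_mapped(matrix, "locusA")["sample"] == pytest.approx(0.9)
    assert counting.fraction_of_mapped(matrix, "locusB")["sample"] == 0.0


# --------------------------------------------------------------------- I/O


def test_count_matrix_tsv_round_trip(tmp_path, toy_annotation):
    alns = [make_alignment(f"r{i}", [("chrT", 1500 + i, "+", 0)]) for i in range(7)]
    out = counting.assign_multimappers(alns, "fractional")
    matrix = counting.count_features(out, toy_annotation, group_by="family")
    matrix.meta["policy"] = "fractional"
    path = tmp_path / "m.tsv"
    matrix.to_tsv(path)
    back = counting.CountMatrix.from_tsv(path)
    assert back.units == matrix.units
    assert back.meta["policy"] == "fractional"
    assert back.counts.equals(matrix.counts)
    assert back.totals.equals(matrix.totals.astype(back.totals.dtypes))
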