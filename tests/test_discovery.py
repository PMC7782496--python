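import numpy as np
import pandas as pd
import pytest

from pachyscan.discovery import (
    assign_strand,
    call_windows,
    classify_genic,
    compute_window_stats,
    discover_clusters,
    infer_introns,
    merge_windows,
    trim_boundaries,
)
from pachyscan.io_formats import GeneModel, GenomicInterval, SignalTrack


def _reads(rows):
    """rows: (chrom, start, length, n_map, nt1, nt10)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "length", "n_map_locations", "nt1", "nt10"])
    df["end"] = df["start"] + df["length"]
    df["strand"] = "+"
    df["weight"] = 1.0 / df["n_map_locations"]
    return df


def _uniform_reads(chrom, lo, hi, n, seed=0, n_map=1):
    rng = np.random.default_rng(seed)
    starts = rng.integers(lo, hi - 32, size=n)
    return _reads([(chrom, int(s), 30, n_map, "T", "A") for s in starts])


# -------------------------------------------------------------- window stats


def test_window_rpm_hand_counts():
    rows = [("c1", 1000 + i, 30, 1, "T", "A") for i in range(150)]
    stats = compute_window_stats(_reads(rows), 1e6, {"c1": 20_000}, window=20_000, step=20_000)
    assert len(stats) == 1
    assert stats.loc[0, "rpm"] == pytest.approx(150.0)
    assert stats.loc[0, "n_distinct"] == 150
    assert stats.loc[0, "frac_1u10a"] == 1.0


def test_window_rpm_apportions_multimappers():
    rows = [("c1", 1000 + i, 30, 1, "T", "A") for i in range(100)]
    rows += [("c1", 3000 + i, 28, 2, "T", "A") for i in range(10)]
    stats = compute_window_stats(_reads(rows), 1e6, {"c1": 20_000}, window=20_000, step=20_000)
    assert stats.loc[0, "rpm"] == pytest.approx(105.0)


def test_empty_window_zeroes():
    stats = compute_window_stats(
        _reads([("c2", 100, 30, 1, "T", "A")]), 1e6, {"c1": 20_000},
        window=20_000, step=20_000,
    )
    assert stats.loc[0, "rpm"] == 0.0
    assert stats.loc[0, "n_distinct"] == 0
    assert stats.loc[0, "frac_1u10a"] == 0.0


def test_zero_unique_total_rejected():
    with pytest.raises(ValueError, match="uniquely mapped"):
        compute_window_stats(_reads([]), 0, {"c1": 20_000})


def test_read_mass_conserved_at_non_overlapping_step(dataset):
    """At step == window each fully-interior read is counted exactly once, so
    window sums recover the total weighted read mass (reads straddling window
    edges are counted in both, bounded by the straddler count)."""
    reads = dataset.reads
    stats = compute_window_stats(
        reads, dataset.unique_total, dataset.chrom_lengths,
        window=20_000, step=20_000,
    )
    total_rpm = reads["weight"].sum() / dataset.unique_total * 1e6
    window_sum = stats["rpm"].sum()
    straddle_bound = len(reads) / dataset.unique_total * 1e6 * 0.01
    assert window_sum >= total_rpm - 1e-9
    assert window_sum <= total_rpm + straddle_bound + 1.0


def test_frac_1u10a_uses_weighted_union():
    rows = [
        ("c1", 100, 30, 1, "T", "C"),   # 1U only
        ("c1", 200, 30, 1, "A", "A"),   # 10A only
        ("c1", 300, 30, 1, "A", "C"),   # neither
        ("c1", 400, 30, 2, "T", "A"),   # both, weight 0.5
    ]
    stats = compute_window_stats(_reads(rows), 1e6, {"c1": 20_000}, window=20_000, step=20_000)
    assert stats.loc[0, "frac_1u10a"] == pytest.approx(2.5 / 3.5)


# -------------------------------------------------------------- calling & merging


@pytest.mark.parametrize(
    "rpm,distinct,frac,passes",
    [
        (150, 250, 0.6, True),
        (150, 150, 0.6, False),    # too few distinct species
        (150, 250, 0.45, False),   # insufficient 1U/10A bias
        (100, 250, 0.6, False),    # threshold is strict: > 100
        (100.1, 200, 0.5, True),   # distinct and frac bounds are inclusive
    ],
)
def test_call_windows_thresholds(rpm, distinct, frac, passes):
    stats = pd.DataFrame(
        [{"chrom": "c1", "start": 0, "end": 20_000, "rpm": rpm,
          "n_distinct": distinct, "frac_1u10a": frac}]
    )
    assert (len(call_windows(stats)) == 1) is passes


def test_merge_windows_union_and_separation():
    passing = pd.DataFrame(
        [
            {"chrom": "c1", "start": 0, "end": 20_000},
            {"chrom": "c1", "start": 1_000, "end": 21_000},
            {"chrom": "c1", "start": 50_000, "end": 70_000},
            {"chrom": "c2", "start": 0, "end": 20_000},
        ]
    )
    merged = merge_windows(passing)
    assert [(m.chrom, m.start, m.end) for m in merged] == [
        ("c1", 0, 21_000), ("c1", 50_000, 70_000), ("c2", 0, 20_000),
    ]


def test_merge_single_window_is_identity():
    passing = pd.DataFrame([{"chrom": "c1", "start": 3_000, "end": 23_000}])
    (m,) = merge_windows(passing)
    assert (m.start, m.end) == (3_000, 23_000)


# -------------------------------------------------------------- trimming


def brute_force_trim(candidate, reads, unique_total, window=100, min_rpm=2.0, max_gap=1000):
    """Direct scan: qualifying 100-bp windows; boundary = outer edge of the
    first/last consecutive qualifying pair closer than max_gap."""
    wins = []
    pos = candidate.start
    while pos < candidate.end:
        end = min(pos + window, candidate.end)
        w = reads[
            (reads["chrom"] == candidate.chrom)
            & (reads["start"] < end)
            & (reads["end"] > pos)
        ]["weight"].sum()
        wins.append((pos, end, w / unique_total * 1e6))
        pos += window
    qual = [(s, e) for s, e, r in wins if r > min_rpm]
    pairs = [
        i for i in range(len(qual) - 1) if qual[i + 1][0] - qual[i][1] < max_gap
    ]
    if not pairs:
        return None
    return qual[pairs[0]][0], qual[pairs[-1] + 1][1]


def test_trim_recovers_dense_core():
    cand = GenomicInterval("c1", 0, 21_000)
    reads = _uniform_reads("c1", 5_000, 15_000, 800, seed=3)
    refined, status = trim_boundaries(cand, reads, 1e6)
    assert status == "trimmed"
    assert abs(refined.start - 5_000) <= 100
    assert abs(refined.end - 15_000) <= 100


def test_trim_uniform_dense_keeps_candidate():
    cand = GenomicInterval("c1", 0, 21_000)
    reads = _uniform_reads("c1", 0, 21_000, 3_000, seed=4)
    refined, _ = trim_boundaries(cand, reads, 1e6)
    assert refined.start == 0
    assert refined.end == 21_000


def test_trim_skips_isolated_qualifying_window():
    # a lone dense 100-bp island 1.5 kb outside the core must not set the
    # boundary: the first qualifying *pair* within 1 kb governs
    cand = GenomicInterval("c1", 0, 21_000)
    core = _uniform_reads("c1", 6_000, 15_000, 800, seed=5)
    island = _reads([("c1", 4_400 + i % 60, 30, 1, "T", "A") for i in range(10)])
    reads = pd.concat([island, core], ignore_index=True)
    refined, _ = trim_boundaries(cand, reads, 1e6)
    assert refined.start >= 5_900


def test_trim_discard_reported_not_silent():
    cand = GenomicInterval("c1", 0, 21_000)
    refined, status = trim_boundaries(cand, _reads([("c1", 50, 30, 1, "T", "A")]), 1e6)
    assert refined is None
    assert status.startswith("discarded")


def test_trim_matches_brute_force_on_random_candidates():
    rng = np.random.default_rng(11)
    for trial in range(20):
        lo = int(rng.integers(0, 3_000))
        hi = lo + int(rng.integers(2_000, 15_000))
        n = int(rng.integers(5, 400))
        reads = _uniform_reads("c1", lo, hi, n, seed=100 + trial)
        cand = GenomicInterval("c1", 0, 21_000)
        expected = brute_force_trim(cand, reads, 1e6)
        got, _ = trim_boundaries(cand, reads, 1e6)
        if expected is None:
            assert got is None
        else:
            assert (got.start, got.end) == expected


# -------------------------------------------------------------- strand / introns / genic


def test_assign_strand_cases():
    plus = SignalTrack({"c1": (np.array([0]), np.array([100]), np.array([9.0]))})
    minus = SignalTrack({"c1": (np.array([0]), np.array([100]), np.array([1.0]))})
    empty = SignalTrack({})
    iv = GenomicInterval("c1", 0, 100)
    assert assign_strand(iv, plus, minus) == ("+", False)
    assert assign_strand(iv, minus, plus)[0] == "-"
    assert assign_strand(iv, empty, empty) == (".", True)


def _junctions(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "support"])


def test_infer_introns_no_junctions_single_exon():
    iv = GenomicInterval("c1", 0, 10_000)
    assert infer_introns(iv, "+", _junctions([])) == [(0, 10_000)]


def test_infer_introns_one_junction():
    iv = GenomicInterval("c1", 0, 10_000)
    exons = infer_introns(iv, "+", _junctions([("c1", 4_000, 6_000, "+", 5)]))
    assert exons == [(0, 4_000), (6_000, 10_000)]


def test_infer_introns_greedy_keeps_best_supported():
    iv = GenomicInterval("c1", 0, 10_000)
    exons = infer_introns(
        iv, "+",
        _junctions([("c1", 4_000, 6_000, "+", 10), ("c1", 5_000, 7_000, "+", 3)]),
    )
    assert exons == [(0, 4_000), (6_000, 10_000)]


def test_infer_introns_filters_low_support_and_wrong_strand():
    iv = GenomicInterval("c1", 0, 10_000)
    exons = infer_introns(
        iv, "+",
        _junctions([("c1", 2_000, 3_000, "+", 1), ("c1", 4_000, 6_000, "-", 50)]),
    )
    assert exons == [(0, 10_000)]


def test_classify_genic_majority_rule():
    genes = [GeneModel(id="g", chrom="c1", start=0, end=6_000, strand="+")]
    assert classify_genic(GenomicInterval("c1", 0, 10_000), genes) == "genic"     # 60%
    assert classify_genic(GenomicInterval("c1", 2_000, 10_000), genes) == "intergenic"  # 50% exactly
    assert classify_genic(GenomicInterval("c1", 20_000, 30_000), genes) == "intergenic"


# -------------------------------------------------------------- properties on synthetic data


def test_raising_min_rpm_never_adds_clusters(dataset):
    counts = []
    for min_rpm in (50.0, 100.0, 300.0, 1_000.0, 3_000.0):
        clusters, _ = discover_clusters(
            dataset.reads, dataset.unique_total, dataset.chrom_lengths,
            min_rpm=min_rpm,
        )
        counts.append(len(clusters))
    assert counts == sorted(counts, reverse=True)


def test_planted_clusters_recovered_with_tight_boundaries(result):
    rec = result.recovery
    assert rec["recovered"].all()
    assert rec["strand_ok"].all()
    assert rec[["start_error", "end_error"]].max().max() <= 1_000
    assert result.false_positives == []


def test_spliced_cluster_exons_recovered(result):
    truth_models = {m.id: m for m in result.dataset.truth.cluster_models}
    spliced = {cid for cid, m in truth_models.items() if m.is_spliced}
    assert spliced  # the plan plants spliced loci
    for cl in result.clusters:
        for cid in spliced:
            m = truth_models[cid]
            if m.chrom == cl.chrom and m.start < cl.end and cl.start < m.end:
                assert len(cl.exons) == len(m.exons)
                for (a, b), (c, d) in zip(cl.exons, m.exons):
                    assert abs(a - c) <= 1_000 and abs(b - d) <= 1_000
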