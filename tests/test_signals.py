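import numpy as np
import pandas as pd
import pytest

from pachyscan.io_formats import GeneModel, SignalTrack
from pachyscan.signals import (
    BinnedSignal,
    aggregate_signal,
    bin_signal,
    extension_index,
    metagene_profile,
    normalize_by_controls,
    select_control_genes,
)


def _track(rows):
    return SignalTrack.from_tuples(rows)


def _gene(strand="+", start=10_000, end=20_000, gid="g"):
    return GeneModel(id=gid, chrom="c1", start=start, end=end, strand=strand)


# -------------------------------------------------------------- controls


@pytest.mark.parametrize(
    "levels,expected",
    [
        ((1.0, 1.2, 0.9), True),     # max/min = 1.33, inside (0.66, 1.5)
        ((1.0, 2.0, 1.0), False),    # 2-fold change
        ((0.05, 0.05, 0.05), False), # max below 0.1 RPKM
        ((1.0, 1.5, 1.0), False),    # 1.5 exactly is excluded (open interval)
        ((0.0, 1.0, 1.0), False),    # a zero makes a ratio of 0
    ],
)
def test_select_control_genes(levels, expected):
    expr = pd.DataFrame([levels], index=["g1"], columns=["a", "b", "c"])
    assert ("g1" in select_control_genes(expr)) is expected


def test_normalize_by_controls_median_becomes_one():
    levels = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0, 4.0], "s2": [10.0, 20.0, 30.0, 40.0]},
        index=["c1", "c2", "c3", "g"],
    )
    scaled = normalize_by_controls(levels, ["c1", "c2", "c3"])
    assert scaled.loc[["c1", "c2", "c3"], "s1"].median() == pytest.approx(1.0)
    assert scaled.loc[["c1", "c2", "c3"], "s2"].median() == pytest.approx(1.0)
    assert scaled.loc["g", "s1"] == pytest.approx(4.0 / 2.0)


def test_normalize_requires_controls():
    levels = pd.DataFrame({"s1": [1.0]}, index=["g"])
    with pytest.raises(ValueError, match="control"):
        normalize_by_controls(levels, [])


# -------------------------------------------------------------- aggregation


def test_aggregate_uniform_track():
    t = _track([("c1", 0, 50_000, 3.0)])
    assert aggregate_signal(t, _gene(), "promoter") == pytest.approx(3.0)
    assert aggregate_signal(t, _gene(), "tss500") == pytest.approx(3.0)
    assert aggregate_signal(t, _gene(), "gene_body") == pytest.approx(3.0)


def test_aggregate_zero_fills_uncovered():
    g = _gene()  # promoter window [8000, 12000)
    t = _track([("c1", 8_000, 10_000, 4.0)])
    assert aggregate_signal(t, g, "promoter") == pytest.approx(2.0)


def test_aggregate_minus_strand_promoter_at_right_end():
    g = _gene(strand="-")  # TSS = 20000; promoter [18000, 22000)
    t = _track([("c1", 18_000, 22_000, 5.0)])
    assert aggregate_signal(t, g, "promoter") == pytest.approx(5.0)
    t_left = _track([("c1", 8_000, 12_000, 5.0)])
    assert aggregate_signal(t_left, g, "promoter") == 0.0


def test_gene_body_region_is_strand_aware():
    plus = _gene("+")   # body [12000, 20000)
    minus = _gene("-")  # body [10000, 18000)
    t = _track([("c1", 12_000, 20_000, 2.0)])
    assert aggregate_signal(t, plus, "gene_body") == pytest.approx(2.0)
    assert aggregate_signal(t, minus, "gene_body") == pytest.approx(2.0 * 6_000 / 8_000)


# -------------------------------------------------------------- binning


def test_bin_signal_orientation():
    tss_plus = _gene("+", 100_000, 150_000)
    tss_minus = _gene("-", 50_000, 100_000)
    t = _track([("c1", 100_000, 100_400, 2.0)])   # 400 bp downstream of +TSS
    t2 = _track([("c1", 99_600, 100_000, 2.0)])   # 400 bp downstream of -TSS
    b_plus = bin_signal(t, tss_plus)
    b_minus = bin_signal(t2, tss_minus)
    np.testing.assert_allclose(b_plus.values, b_minus.values)
    assert b_plus.values[b_plus.offsets == 0][0] == pytest.approx(2.0)
    assert b_plus.values[b_plus.offsets == 400][0] == 0.0


def test_bin_signal_truncates_at_chromosome_end():
    g = _gene("+", 0, 5_000)
    b = bin_signal(_track([("c1", 0, 5_000, 1.0)]), g, chrom_length=50_000)
    assert b.offsets.min() == 0          # upstream bins fall off the contig
    assert b.offsets.max() == 49_800


# -------------------------------------------------------------- extension index


def _binned(down_values, up=50, bin_size=200, gid="g"):
    """BinnedSignal spanning [-10 kb, +100 kb) with given downstream bins."""
    down = np.asarray(down_values, dtype=float)
    assert len(down) == 500
    offsets = np.arange(-up * bin_size, 500 * bin_size, bin_size, dtype=np.int64)
    values = np.concatenate([np.zeros(up), down])
    return BinnedSignal(gid, offsets, values, bin_size)


def brute_force_extension(down, threshold, max_gap=19, bin_size=200):
    """Independent enumeration: furthest enriched bin whose preceding
    sub-threshold runs are all <= max_gap."""
    furthest = -1
    run = 0
    for i, v in enumerate(down):
        if v > threshold:
            furthest = i
            run = 0
        else:
            run += 1
            if run > max_gap:
                break
    return (furthest + 1) * bin_size if furthest >= 0 else 0


def test_extension_simple_block():
    down = np.zeros(500)
    down[:100] = 5.0   # 0-20 kb enriched
    r = extension_index(_binned(down), first_unit_length=40_000)
    assert r.extension_index == 20_000
    assert r.relative_extension == pytest.approx(0.5)


def test_extension_no_enrichment_is_zero():
    r = extension_index(_binned(np.zeros(500)), first_unit_length=10_000)
    assert r.extension_index == 0
    assert r.relative_extension == 0.0


def test_extension_gap_rule_19_bridgeable_20_not():
    down = np.zeros(500)
    down[:25] = 5.0           # 0-5 kb
    down[25 + 20] = 5.0       # after a 20-bin (4000 bp) gap
    r = extension_index(_binned(down), first_unit_length=50_000)
    assert r.extension_index == 5_000
    down2 = np.zeros(500)
    down2[:25] = 5.0
    down2[25 + 19] = 5.0      # 19-bin (3800 bp) gap is bridged
    r2 = extension_index(_binned(down2), first_unit_length=50_000)
    assert r2.extension_index == (25 + 19 + 1) * 200


def test_relative_extension_capped_at_one():
    down = np.zeros(500)
    down[:250] = 5.0   # 50 kb
    r = extension_index(_binned(down), first_unit_length=40_000)
    assert r.relative_extension == 1.0


def test_extension_threshold_from_own_background():
    down = np.zeros(500)
    down[400:500] = 1.0     # background bins at 1.0
    down[:50] = 1.0         # signal equal to background: NOT above quantile
    r = extension_index(_binned(down), first_unit_length=10_000)
    assert r.extension_index == 0
    down[:50] = 1.01
    assert extension_index(_binned(down), 10_000).extension_index == 10_000


def test_extension_requires_background_bins():
    b = _binned(np.zeros(500))
    keep = b.offsets < 80_000
    clipped = BinnedSignal("g", b.offsets[keep], b.values[keep], 200)
    with pytest.raises(ValueError, match="background"):
        extension_index(clipped, 10_000)


def test_extension_matches_exhaustive_oracle():
    rng = np.random.default_rng(5)
    for _ in range(200):
        down = (rng.random(500) < 0.15) * rng.uniform(1, 5)
        down[400:] = rng.uniform(0, 0.5, 100) * (rng.random(100) < 0.3)
        b = _binned(down)
        threshold = float(np.quantile(down[400:], 0.95))
        expected = brute_force_extension(down, threshold)
        assert extension_index(b, 10_000).extension_index == expected


def test_extension_monotone_in_bin_values():
    rng = np.random.default_rng(6)
    down = (rng.random(500) < 0.1) * 3.0
    base = extension_index(_binned(down), 10_000).extension_index
    for idx in rng.integers(0, 400, size=20):
        bumped = down.copy()
        bumped[idx] += 5.0
        assert extension_index(_binned(bumped), 10_000).extension_index >= base


# -------------------------------------------------------------- metagene


def test_metagene_single_gene_is_own_profile():
    g = _gene("+", 50_000, 90_000)
    t = _track([("c1", 49_000, 52_000, 2.0)])
    prof = metagene_profile(t, [g])
    b = bin_signal(t, g, bin_size=10, span=(-2_000, 2_000))
    np.testing.assert_allclose(prof["mean"].to_numpy(), b.values)
    assert (prof["n"] == 1).all()


def test_metagene_mirrored_strands_average_symmetric_signal():
    gp = _gene("+", 50_000, 90_000, gid="gp")
    gm = _gene("-", 100_000, 140_000, gid="gm")
    # identical signal geometry relative to each TSS
    t = _track([("c1", 50_000, 50_500, 3.0), ("c1", 139_500, 140_000, 3.0)])
    prof = metagene_profile(t, [gp, gm])
    b = bin_signal(t, gp, bin_size=10, span=(-2_000, 2_000))
    np.testing.assert_allclose(prof["mean"].to_numpy(), b.values)


def test_metagene_constant_track_constant_profile():
    t = _track([("c1", 0, 200_000, 1.5)])
    prof = metagene_profile(t, [_gene("+", 50_000, 90_000), _gene("-", 100_000, 140_000)])
    np.testing.assert_allclose(prof["mean"].to_numpy(), 1.5)


# -------------------------------------------------------------- planted dichotomy


def test_broad_vs_narrow_extension_dichotomy(result):
    table = result.feature_table
    truth = result.dataset.truth.clusters
    long_ids = truth.index[truth["broad_domain"]]
    short_ids = truth.index[~truth["broad_domain"]]
    assert (table.loc[long_ids, "relative_extension"] >= 0.5).all()
    assert (table.loc[short_ids, "relative_extension"] < 0.2).all()
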