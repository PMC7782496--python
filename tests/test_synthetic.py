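import numpy as np
import pandas as pd
import pytest

from pachyscan.discovery import compute_window_stats
from pachyscan.promoters import classify_cg, compute_oe_cg
from pachyscan.synthetic import (
    SimulationConfig,
    simulate_all,
    simulate_genome,
    simulate_small_rna,
    simulate_signal_tracks,
)


def test_planted_cluster_count_conserved(dataset):
    truth = dataset.truth
    assert len(truth.clusters) == 8
    assert len(truth.cluster_models) == 8
    counts = truth.clusters["structural_type"].value_counts()
    assert counts["long_intronless"] == 3
    assert counts["long_first_exon"] == 2
    assert counts["short"] == 3
    # every planted cluster appears in every truth column
    assert truth.clusters.notna().all().all()


def test_same_seed_reproduces_identical_outputs(config):
    g1, m1, t1 = simulate_genome(config)
    g2, m2, t2 = simulate_genome(config)
    assert all(g1[c] == g2[c] for c in g1)
    pd.testing.assert_frame_equal(t1.clusters, t2.clusters)
    r1, u1 = simulate_small_rna(config, t1)
    r2, u2 = simulate_small_rna(config, t2)
    pd.testing.assert_frame_equal(r1, r2)
    assert u1 == u2


def test_different_seed_changes_genome():
    g1, _, _ = simulate_genome(SimulationConfig(seed=1))
    g2, _, _ = simulate_genome(SimulationConfig(seed=2))
    assert any(g1[c] != g2[c] for c in g1)


def test_planted_promoters_hit_their_oe_band(dataset):
    truth = dataset.truth.clusters
    for cid, row in truth.iterrows():
        flank = dataset.config.promoter_flank
        seq = dataset.genome.fetch(
            row["chrom"], int(row["tss"]) - flank, int(row["tss"]) + flank
        )
        oe = compute_oe_cg(seq)
        assert abs(oe - row["oe_target"]) <= dataset.config.oe_band_halfwidth + 1e-9
        assert classify_cg(oe) == row["cg_class"]


def test_cluster_read_abundance_near_target(dataset):
    """Weighted read mass over each planted cluster tracks its RPM within
    binomial sampling tolerance (background adds ~20 RPM per 20 kb)."""
    for cid, row in dataset.truth.clusters.iterrows():
        sel = dataset.reads[
            (dataset.reads["chrom"] == row["chrom"])
            & (dataset.reads["start"] < row["end"])
            & (dataset.reads["end"] > row["start"])
        ]
        rpm = sel["weight"].sum() / dataset.unique_total * 1e6
        assert rpm == pytest.approx(row["rpm"], rel=0.15)


def test_degenerate_1u_fraction():
    cfg = SimulationConfig(seed=2, frac_1u=1.0, background_reads_per_kb=0.0)
    _, _, truth = simulate_genome(cfg)
    reads, _ = simulate_small_rna(cfg, truth)
    row = truth.clusters.loc["pi01"]
    sel = reads[
        (reads["chrom"] == row["chrom"])
        & (reads["start"] >= row["start"])
        & (reads["end"] <= row["end"])
    ]
    assert (sel["nt1"] == "T").all()


def test_read_lengths_in_pirna_range(dataset):
    assert dataset.reads["length"].between(24, 32).all()
    assert (dataset.reads["end"] - dataset.reads["start"] == dataset.reads["length"]).all()


def test_background_windows_below_calling_threshold(dataset):
    """Away from planted loci and decoys, no 20-kb window reaches 100 RPM."""
    stats = compute_window_stats(
        dataset.reads, dataset.unique_total, dataset.chrom_lengths
    )
    planted = pd.concat(
        [
            dataset.truth.clusters[["chrom", "start", "end"]],
            dataset.truth.decoys[["chrom", "start", "end"]],
        ]
    )
    margin = 20_000
    clear = np.ones(len(stats), dtype=bool)
    for _, row in planted.iterrows():
        clear &= ~(
            (stats["chrom"] == row["chrom"])
            & (stats["start"] < row["end"] + margin)
            & (stats["end"] > row["start"] - margin)
        )
    assert clear.sum() > 1_000
    assert (stats.loc[clear, "rpm"] < 100).all()


def test_zero_noise_background_bins_exactly_baseline(dataset):
    """With the default noiseless config, far-downstream bins are exactly the
    baseline pedestal for every planted locus."""
    track = dataset.tracks["acyl"]
    cfg = dataset.config
    for cid, row in dataset.truth.clusters.iterrows():
        tss = int(row["tss"])
        sgn = 1 if row["strand"] == "+" else -1
        lo, hi = sorted((tss + sgn * 80_000, tss + sgn * 100_000))
        assert track.mean(row["chrom"], lo, hi) == pytest.approx(cfg.baseline)


def test_signal_tracks_realize_broad_vs_narrow(dataset):
    track = dataset.tracks["acyl"]
    cfg = dataset.config
    for cid, row in dataset.truth.clusters.iterrows():
        tss, fu = int(row["tss"]), int(row["first_unit_length"])
        sgn = 1 if row["strand"] == "+" else -1
        if row["broad_domain"]:
            lo, hi = sorted((tss, tss + sgn * fu))
            assert track.mean(row["chrom"], lo, hi) >= cfg.broad_level * 0.99
        else:
            far_lo, far_hi = sorted((tss + sgn * 2_000, tss + sgn * 4_000))
            assert track.mean(row["chrom"], far_lo, far_hi) == pytest.approx(cfg.baseline)


def test_tables_realize_truth_flags(dataset):
    truth = dataset.truth.clusters
    t = dataset.tables
    expr = t["expression"]
    somatic = expr.drop(columns=["testis"])
    for cid, row in truth.iterrows():
        if row["testis_category"] == "exclusive":
            assert somatic.loc[cid].max() < 0.1
        else:
            assert somatic.loc[cid].max() >= 0.1
    # BTBD18-dependent clusters drop >= 2-fold in both assays
    mh = t["mut_het"]
    dep = truth.index[truth["btbd18_dependent"]]
    assert (mh.loc[dep, "btbd18_expr_mut_het"] <= 0.5).all()
    assert (mh.loc[dep, "btbd18_pirna_mut_het"] <= 0.5).all()
    # eutherian-conserved clusters have >= 3 panel species within 5-fold
    ab = t["species_abundance"]
    for cid in truth.index[truth["conservation_class"] == "eutherian_conserved"]:
        m = truth.loc[cid, "rpm"]
        folds = ab.loc[cid, ["human", "rhesus", "marmoset", "rat", "cow"]] / m
        assert ((folds > 0.2) & (folds < 5)).sum() >= 3
    # four methylation replicates per site
    reps = t["methylation"].groupby(["chrom", "pos"])["replicate"].nunique()
    assert (reps == 4).all()


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(frac_1u=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(chrom_length=100_000)
    with pytest.raises(ValueError):
        SimulationConfig(total_unique_reads=0)
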