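"""End-to-end pipeline over a simulated dataset: discover clusters, assemble
the per-cluster feature table, classify, and correlate. The analysis drivers
and the acceptance checks both run through here."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import conservation as cons
from . import discovery, expression, promoters, regulatory, reporting, signals
from .io_formats import GenomicInterval
from .synthetic import SimulatedDataset, SimulationConfig, simulate_all

__all__ = ["PipelineResult", "run_discovery", "match_clusters",
           "build_feature_table", "run_pipeline", "FEATURES_FOR_CORRELATION"]

FEATURES_FOR_CORRELATION = [
    "first_exon_length",
    "oe_cg",
    "acyl_promoter",
    "h3k4me3_promoter",
    "fivehmc_tss500",
    "methylation",
]


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    clusters: list[discovery.PiRNACluster]
    discards: list[dict]
    recovery: pd.DataFrame
    false_positives: list[discovery.PiRNACluster]
    feature_table: pd.DataFrame
    correlations: pd.DataFrame


def run_discovery(ds: SimulatedDataset):
    return discovery.discover_clusters(
        ds.reads,
        ds.unique_total,
        ds.chrom_lengths,
        junctions=ds.tables["junctions"],
        plus_coverage=ds.tracks["rna_plus"],
        minus_coverage=ds.tracks["rna_minus"],
        protein_coding=[g for g in ds.models if g.biotype == "protein_coding"],
    )


def match_clusters(
    found: list[discovery.PiRNACluster], truth: pd.DataFrame
) -> tuple[pd.DataFrame, list[discovery.PiRNACluster]]:
    """Match each planted cluster to the discovered cluster that overlaps it.

    Returns the per-planted-cluster recovery table (boundary errors in bp;
    NaN when missed) and the list of discovered clusters overlapping no
    planted cluster (false positives).
    """
    rows = []
    matched_ids = set()
    for cid, row in truth.iterrows():
        planted = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        best, best_ov = None, 0
        for cl in found:
            ov = planted.overlap(GenomicInterval(cl.chrom, cl.start, cl.end))
            if ov > best_ov:
                best, best_ov = cl, ov
        if best is None:
            rows.append({"cluster_id": cid, "recovered": False,
                         "start_error": np.nan, "end_error": np.nan,
                         "strand_ok": False})
        else:
            matched_ids.add(best.id)
            rows.append(
                {
                    "cluster_id": cid,
                    "recovered": True,
                    "start_error": abs(best.start - planted.start),
                    "end_error": abs(best.end - planted.end),
                    "strand_ok": best.strand == row["strand"],
                }
            )
    false_pos = [cl for cl in found if cl.id not in matched_ids]
    return pd.DataFrame(rows).set_index("cluster_id"), false_pos


def build_feature_table(ds: SimulatedDataset) -> pd.DataFrame:
    """Per-cluster features from the annotated models and simulated assays."""
    models = ds.truth.cluster_models
    genes = {m.id: m for m in models}
    t = ds.tables

    fe = expression.first_exon_table(models)
    cg = promoters.promoter_cg_table(ds.genome, models)
    meth = promoters.methylation_table(t["methylation"], models)

    controls = signals.select_control_genes(t["expression_cell_types"])
    rows = []
    for m in models:
        abundance = expression.pirna_abundance(
            ds.reads, m.interval, ds.unique_total
        )
        spec = expression.classify_specificity(
            t["expression"].loc[m.id], "testis", kind="piRNA", gene_id=m.id
        )
        binned = signals.bin_signal(
            ds.tracks["acyl"], m, chrom_length=ds.chrom_lengths[m.chrom]
        )
        first_unit, _, _ = expression.first_exon_metrics(m)
        ext = signals.extension_index(binned, first_unit)
        mh = t["mut_het"].loc[m.id]
        amyb_flag, _ = regulatory.call_amyb(
            regulatory.AmybEvidence(
                peak_distance_bp=regulatory.tss_peak_distance(
                    m.tss, m.chrom, t["amyb_peaks"]
                ),
                promoter_enrichment=float(t["amyb_enrichment"].loc[m.id, "enrichment"]),
                mut_het_ratio_14=float(mh["amyb_mut_het_14"]),
                mut_het_ratio_17=float(mh["amyb_mut_het_17"]),
            )
        )
        btb_flag, _ = regulatory.call_btbd18(
            regulatory.Btbd18Evidence(
                expr_mut_over_het=float(mh["btbd18_expr_mut_het"]),
                pirna_mut_over_het=float(mh["btbd18_pirna_mut_het"]),
            )
        )
        conserv = cons.classify_conservation(
            abundance, t["species_abundance"].loc[m.id].to_dict(), m.id
        )
        rows.append(
            {
                "gene_id": m.id,
                "abundance_rpm": abundance,
                "ts_score": spec.ts_score,
                "specificity": spec.category,
                "acyl_promoter": signals.aggregate_signal(ds.tracks["acyl"], m, "promoter"),
                "h3k4me3_promoter": signals.aggregate_signal(ds.tracks["h3k4me3"], m, "promoter"),
                "fivehmc_tss500": signals.aggregate_signal(ds.tracks["fivehmc"], m, "tss500"),
                "extension_index": ext.extension_index,
                "relative_extension": ext.relative_extension,
                "amyb_regulated": amyb_flag,
                "btbd18_dependent": btb_flag,
                "conservation_class": conserv.conservation_class,
                "n_control_genes": len(controls),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    return pd.concat([table, fe, cg, meth], axis=1)


def run_pipeline(config: SimulationConfig | None = None) -> PipelineResult:
    ds = simulate_all(config or SimulationConfig())
    clusters, discards = run_discovery(ds)
    recovery, false_pos = match_clusters(clusters, ds.truth.clusters)
    table = build_feature_table(ds)
    correlations = reporting.correlate_with_abundance(
        table, FEATURES_FOR_CORRELATION
    )
    return PipelineResult(
        dataset=ds,
        clusters=clusters,
        discards=discards,
        recovery=recovery,
        false_positives=false_pos,
        feature_table=table,
        correlations=correlations,
    )
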