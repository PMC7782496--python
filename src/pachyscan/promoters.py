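"""Promoter CG-dinucleotide statistics and DNA-methylation aggregation.

The observed/expected CG ratio of a promoter sequence,

    O/E CG = f(CpG) / [(f(C) + f(G)) / 2]^2,

separates promoters into low (< 0.25), intermediate, and high (> 0.5) CG
classes; low-CG promoters are typically methylated and somatically silenced.
Methylation level is mCG/CG averaged over detected CG sites, then averaged
across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, GeneModel, GenomicInterval

__all__ = [
    "compute_oe_cg",
    "classify_cg",
    "promoter_cg_table",
    "promoter_methylation",
    "MethylationSummary",
    "CG_LOW_MAX",
    "CG_HIGH_MIN",
]

CG_LOW_MAX = 0.25
CG_HIGH_MIN = 0.5

#: default promoter window (bp each side of the TSS) for the O/E CG statistic
DEFAULT_CG_FLANK = 500


def compute_oe_cg(sequence: str) -> float:
    """Observed/expected CG-dinucleotide ratio of a sequence.

    Fractions use total length L (N bases count toward L but never toward C,
    G, or CG); the CpG fraction uses the L-1 dinucleotide positions. Returns 0
    for sequences with no C and no G.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < 2:
        raise ValueError(f"sequence too short for O/E CG (length {L})")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c + n_g == 0:
        return 0.0
    f_c = n_c / L
    f_g = n_g / L
    f_cpg = seq.count("CG") / (L - 1)
    expected = ((f_c + f_g) / 2.0) ** 2
    return f_cpg / expected


def classify_cg(oe_cg: float) -> str:
    """CG class from the O/E ratio: low < 0.25, high > 0.5, else intermediate.

    Exact boundary values fall in the intermediate bin.
    """
    if oe_cg < CG_LOW_MAX:
        return "low"
    if oe_cg > CG_HIGH_MIN:
        return "high"
    return "intermediate"


def promoter_cg_table(
    genome: GenomeSequence,
    genes: list[GeneModel],
    flank: int = DEFAULT_CG_FLANK,
) -> pd.DataFrame:
    """Per-gene promoter O/E CG and class over TSS +/- flank."""
    rows = []
    for g in genes:
        seq = genome.fetch(g.chrom, g.tss - flank, g.tss + flank)
        oe = compute_oe_cg(seq)
        rows.append(
            {"gene_id": g.id, "oe_cg": oe, "cg_class": classify_cg(oe), "flank": flank}
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class MethylationSummary:
    gene_id: str
    level: float            # mean of per-replicate means; NaN when undefined
    n_sites: int
    replicate_levels: dict[str, float]
    defined: bool


def promoter_methylation(
    sites: pd.DataFrame,
    region: GenomicInterval,
    gene_id: str = "",
) -> MethylationSummary:
    """Aggregate per-CG-site methylation calls over a region.

    ``sites`` columns: chrom, pos (0-based), meth_count, total_count,
    replicate. Per replicate the level is the unweighted mean over detected
    sites of meth/total; the final level averages the replicate means. Zero
    detected sites gives an undefined (flagged) summary.
    """
    sel = sites[
        (sites["chrom"] == region.chrom)
        & (sites["pos"] >= region.start)
        & (sites["pos"] < region.end)
        & (sites["total_count"] > 0)
    ]
    if sel.empty:
        return MethylationSummary(gene_id, float("nan"), 0, {}, defined=False)
    frac = sel["meth_count"] / sel["total_count"]
    rep_means = frac.groupby(sel["replicate"]).mean()
    return MethylationSummary(
        gene_id,
        float(rep_means.mean()),
        int(sel[["chrom", "pos"]].drop_duplicates().shape[0]),
        {str(k): float(v) for k, v in rep_means.items()},
        defined=True,
    )


def methylation_table(
    sites: pd.DataFrame, genes: list[GeneModel], flank: int = 2000
) -> pd.DataFrame:
    """Promoter (TSS +/- flank) methylation summaries for a gene list."""
    rows = []
    for g in genes:
        summ = promoter_methylation(sites, g.promoter(flank), g.id)
        rows.append(
            {
                "gene_id": g.id,
                "methylation": summ.level if summ.defined else np.nan,
                "n_cg_sites": summ.n_sites,
                "defined": summ.defined,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
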