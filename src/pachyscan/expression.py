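"""Expression and abundance metrics: RPKM/RPM, apportioned piRNA abundance,
the tissue-specificity score, testis-specificity calls, and first-exon
structural classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval

__all__ = [
    "compute_rpkm",
    "pirna_abundance",
    "ts_score",
    "classify_specificity",
    "first_exon_metrics",
    "SpecificityCall",
    "LONG_FIRST_UNIT_BP",
]

#: "long" first exon / intronless transcript boundary (bp, inclusive)
LONG_FIRST_UNIT_BP = 10_000

EXCLUSIVE_MAX_SOMATIC_RPKM = 0.1
TESTIS_SPECIFIC_FOLD = 4.0
CODING_TESTIS_MIN_RPKM = 10.0


def compute_rpkm(count: float, transcript_length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length_bp <= 0 or total_mapped <= 0:
        raise ValueError("transcript length and total mapped reads must be positive")
    return count / (transcript_length_bp / 1e3) / (total_mapped / 1e6)


def pirna_abundance(
    reads: pd.DataFrame,
    interval: GenomicInterval,
    unique_total: float,
    per_kb: bool = False,
) -> float:
    """Apportioned piRNA abundance of a locus, per million uniquely mapped reads.

    Each read overlapping the interval contributes 1/n_map_locations; a read
    overlapping several loci is counted in each with unchanged weight.
    With ``per_kb`` the RPM is further divided by the locus length in kb
    (an RPKM-style variant).
    """
    if unique_total <= 0:
        raise ValueError("no uniquely mapped reads")
    sel = reads[
        (reads["chrom"] == interval.chrom)
        & (reads["start"] < interval.end)
        & (reads["end"] > interval.start)
    ]
    rpm = float(sel["weight"].sum()) / unique_total * 1e6
    if per_kb:
        rpm /= len(interval) / 1e3
    return rpm


def ts_score(expr_row: pd.Series, testis_sample: str) -> float:
    """Tissue-specificity score: mean depletion relative to testis.

    score = sum_i (1 - Exp_i / Exp_ts) / (n - 1) over all n tissues
    (the testis term contributes 0), clamped to 0 if any tissue exceeds
    testis or if the testis itself is unexpressed.
    """
    if testis_sample not in expr_row.index:
        raise KeyError(f"no sample {testis_sample!r} in expression row")
    exp_ts = float(expr_row[testis_sample])
    values = expr_row.astype(float)
    if exp_ts <= 0:
        return 0.0
    if (values > exp_ts).any():
        return 0.0
    n = len(values)
    if n < 2:
        raise ValueError("ts-score needs at least two tissues")
    return float((1.0 - values / exp_ts).sum() / (n - 1))


@dataclass
class SpecificityCall:
    gene_id: str
    ts_score: float
    category: str          # exclusive | testis_specific | broad
    fold_over_somatic: float


def classify_specificity(
    expr_row: pd.Series,
    testis_sample: str,
    kind: str = "piRNA",
    gene_id: str = "",
) -> SpecificityCall:
    """Testis-specificity category of one gene from its tissue expression row.

    exclusive: every somatic tissue < 0.1 RPKM; testis_specific: testis at
    least 4-fold above the maximal somatic tissue (protein-coding genes must
    additionally reach 10 RPKM in testis); otherwise broad.
    """
    if kind not in {"piRNA", "coding"}:
        raise ValueError(f"unknown kind {kind!r}")
    testis = float(expr_row[testis_sample])
    somatic = expr_row.drop(labels=[testis_sample]).astype(float)
    max_som = float(somatic.max()) if len(somatic) else 0.0
    fold = testis / max_som if max_som > 0 else float("inf")
    if max_som < EXCLUSIVE_MAX_SOMATIC_RPKM:
        category = "exclusive"
    elif testis >= TESTIS_SPECIFIC_FOLD * max_som and (
        kind != "coding" or testis >= CODING_TESTIS_MIN_RPKM
    ):
        category = "testis_specific"
    else:
        category = "broad"
    return SpecificityCall(
        gene_id=gene_id or str(expr_row.name or ""),
        ts_score=ts_score(expr_row, testis_sample),
        category=category,
        fold_over_somatic=fold,
    )


def first_exon_metrics(gene: GeneModel) -> tuple[int, bool, str]:
    """(first-unit length, long flag, structural type) for one transcript.

    Spliced genes are measured by the 5'-most exon in transcription direction;
    intronless genes by the full transcript length. "Long" means >= 10 kb.
    Types: long_intronless, long_first_exon, short.
    """
    if gene.is_spliced:
        length = gene.first_exon_length
        long_flag = length >= LONG_FIRST_UNIT_BP
        structural = "long_first_exon" if long_flag else "short"
    else:
        length = gene.length
        long_flag = length >= LONG_FIRST_UNIT_BP
        structural = "long_intronless" if long_flag else "short"
    return length, long_flag, structural


def first_exon_table(genes: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        length, long_flag, structural = first_exon_metrics(g)
        rows.append(
            {
                "gene_id": g.id,
                "first_exon_length": length,
                "long": long_flag,
                "structural_type": structural,
                "spliced": g.is_spliced,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
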