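"""Rule-based regulatory calls: A-MYB-regulated genes and BTBD18-dependent
pachytene piRNA clusters.

A-MYB (MYBL1) drives transcription of pachytene piRNA precursors at meiosis
entry; BTBD18 licenses elongation across a subset of clusters. Both calls are
plain conjunctions of evidence thresholds, reproducible from the stored
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AmybEvidence", "Btbd18Evidence", "call_amyb", "call_btbd18",
           "tss_peak_distance"]

AMYB_MAX_TSS_DISTANCE = 500      # bp, TSS to nearest peak edge
AMYB_MIN_ENRICHMENT = 3.0        # IP/input over TSS +/- 500 bp
AMYB_MAX_MUT_HET_RATIO = 0.5     # >2-fold decrease, both 14.5 and 17.5 dpp
BTBD18_MAX_MUT_HET_RATIO = 0.5   # >=2-fold lower (inclusive), both tables


@dataclass
class AmybEvidence:
    peak_distance_bp: float
    promoter_enrichment: float
    mut_het_ratio_14: float | None
    mut_het_ratio_17: float | None


@dataclass
class Btbd18Evidence:
    expr_mut_over_het: float | None
    pirna_mut_over_het: float | None


def tss_peak_distance(tss: int, chrom: str, peaks: pd.DataFrame) -> float:
    """Distance from a TSS to the nearest peak edge (0 if the TSS is inside
    a peak; inf with no peak on the chromosome). Peak columns: chrom, start, end."""
    sel = peaks[peaks["chrom"] == chrom]
    if sel.empty:
        return float("inf")
    left = (sel["start"] - tss).clip(lower=0)
    right = (tss - sel["end"] + 1).clip(lower=0)
    return float((left + right).min())


def call_amyb(evidence: AmybEvidence) -> tuple[bool | None, str]:
    """A-MYB-regulated iff the TSS sits within 500 bp of a peak, promoter
    IP/input >= 3, and the mutant/het expression ratio is < 0.5 at both 14.5
    and 17.5 dpp. Returns (flag, reason); flag None means not assessable
    (missing ratio, e.g. het expression was zero)."""
    if evidence.mut_het_ratio_14 is None or evidence.mut_het_ratio_17 is None:
        return None, "not_assessable:het_zero"
    ok = (
        evidence.peak_distance_bp <= AMYB_MAX_TSS_DISTANCE
        and evidence.promoter_enrichment >= AMYB_MIN_ENRICHMENT
        and evidence.mut_het_ratio_14 < AMYB_MAX_MUT_HET_RATIO
        and evidence.mut_het_ratio_17 < AMYB_MAX_MUT_HET_RATIO
    )
    return ok, "pass" if ok else "fail"


def call_btbd18(evidence: Btbd18Evidence) -> tuple[bool | None, str]:
    """BTBD18-dependent iff both the precursor expression ratio and the piRNA
    abundance ratio (mutant over heterozygote) are <= 0.5 (>=2-fold lower,
    boundary inclusive)."""
    if evidence.expr_mut_over_het is None or evidence.pirna_mut_over_het is None:
        return None, "not_assessable:het_zero"
    ok = (
        evidence.expr_mut_over_het <= BTBD18_MAX_MUT_HET_RATIO
        and evidence.pirna_mut_over_het <= BTBD18_MAX_MUT_HET_RATIO
    )
    return ok, "pass" if ok else "fail"


def ratio_or_none(numerator: float, denominator: float) -> float | None:
    """Mutant/het ratio; None (not assessable) when the het value is zero."""
    if denominator == 0:
        return None
    return numerator / denominator
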