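"""De novo annotation of piRNA-producing loci from mapped small-RNA reads.

The algorithm scans 20-kb windows at 1-kb steps, calls windows with
> 100 apportioned reads per million uniquely mapped reads, >= 200 distinct
read species, and >= 50% of read weight carrying a 1U or 10A signature; merges
contiguous passing windows into candidates; trims candidate ends with 100-bp
windows (> 2 RPM, paired within 1 kb); then assigns strand from stranded
long-RNA coverage, introns from splice junctions, and genic/intergenic status
from protein-coding overlap.

Windows count reads of both strands (the genome scan is strand-agnostic);
transcriptional direction comes afterward from the long-RNA transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval, SignalTrack

__all__ = [
    "WindowStat",
    "PiRNACluster",
    "compute_window_stats",
    "call_windows",
    "merge_windows",
    "trim_boundaries",
    "assign_strand",
    "infer_introns",
    "classify_genic",
    "discover_clusters",
]

WINDOW_BP = 20_000
STEP_BP = 1_000
MIN_WINDOW_RPM = 100.0
MIN_DISTINCT = 200
MIN_FRAC_1U10A = 0.5
TRIM_WINDOW_BP = 100
TRIM_MIN_RPM = 2.0
TRIM_MAX_GAP_BP = 1_000
GENIC_MIN_OVERLAP = 0.5
MIN_JUNCTION_SUPPORT = 2


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    rpm: float
    n_distinct: int
    frac_1u10a: float


@dataclass
class PiRNACluster:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    genic_type: str
    abundance_rpm: float
    provenance: dict = field(default_factory=dict)

    @property
    def interval(self) -> GenomicInterval:
        strand = self.strand if self.strand in {"+", "-"} else "."
        return GenomicInterval(self.chrom, self.start, self.end, strand)

    def to_gene_model(self) -> GeneModel:
        strand = self.strand if self.strand in {"+", "-"} else "+"
        return GeneModel(
            id=self.id, chrom=self.chrom, start=self.start, end=self.end,
            strand=strand, exons=self.exons, biotype="piRNA_cluster",
        )


# --------------------------------------------------------------------------
# window scan
# --------------------------------------------------------------------------


def _window_weighted_counts(
    starts: np.ndarray, ends: np.ndarray, weights: np.ndarray,
    win_starts: np.ndarray, win_ends: np.ndarray,
) -> np.ndarray:
    """Sum of weights of reads overlapping each window.

    A read [s, e) overlaps window [ws, we) iff s < we and e > ws; with reads
    sorted by start (resp. end) the two prefix sums give the count in O(log n)
    per window.
    """
    o_start = np.argsort(starts, kind="stable")
    o_end = np.argsort(ends, kind="stable")
    s_sorted = starts[o_start]
    e_sorted = ends[o_end]
    cw_by_start = np.concatenate([[0.0], np.cumsum(weights[o_start])])
    cw_by_end = np.concatenate([[0.0], np.cumsum(weights[o_end])])
    n_start_lt = np.searchsorted(s_sorted, win_ends, side="left")
    n_end_le = np.searchsorted(e_sorted, win_starts, side="right")
    return cw_by_start[n_start_lt] - cw_by_end[n_end_le]


def _window_positions(chrom_length: int, window: int, step: int) -> np.ndarray:
    if chrom_length <= window:
        return np.array([0], dtype=np.int64)
    n = (chrom_length - window) // step + 1
    return np.arange(n, dtype=np.int64) * step


def compute_window_stats(
    reads: pd.DataFrame,
    unique_total: float,
    chrom_lengths: dict[str, int],
    window: int = WINDOW_BP,
    step: int = STEP_BP,
) -> pd.DataFrame:
    """Sliding-window read statistics per chromosome.

    Columns: chrom, start, end, rpm, n_distinct, frac_1u10a. ``rpm`` is the
    apportioned read weight overlapping the window per million uniquely mapped
    reads (``unique_total``); ``n_distinct`` counts distinct read species
    (chrom, start, length, strand); ``frac_1u10a`` is the weight fraction with
    first-nucleotide U or tenth-nucleotide A.
    """
    if unique_total <= 0:
        raise ValueError("no uniquely mapped reads")
    frames = []
    for chrom, length in chrom_lengths.items():
        ws = _window_positions(length, window, step)
        we = np.minimum(ws + window, length)
        sub = reads[reads["chrom"] == chrom]
        if sub.empty:
            counts = np.zeros(len(ws))
            sig = np.zeros(len(ws))
            distinct = np.zeros(len(ws))
        else:
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            weights = sub["weight"].to_numpy(float)
            counts = _window_weighted_counts(starts, ends, weights, ws, we)
            is_sig = (
                sub["nt1"].isin(["U", "T"]) | (sub["nt10"] == "A")
            ).to_numpy(bool)
            sig = _window_weighted_counts(
                starts, ends, weights * is_sig, ws, we
            )
            species = sub.drop_duplicates(subset=["start", "length", "strand"])
            distinct = _window_weighted_counts(
                species["start"].to_numpy(np.int64),
                species["end"].to_numpy(np.int64),
                np.ones(len(species)),
                ws, we,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(counts > 0, sig / counts, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": ws,
                    "end": we,
                    "rpm": counts / unique_total * 1e6,
                    "n_distinct": np.rint(distinct).astype(int),
                    "frac_1u10a": frac,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_windows(
    stats: pd.DataFrame,
    min_rpm: float = MIN_WINDOW_RPM,
    min_distinct: int = MIN_DISTINCT,
    min_frac: float = MIN_FRAC_1U10A,
) -> pd.DataFrame:
    """Windows passing all three filters: rpm strictly above ``min_rpm``,
    at least ``min_distinct`` species, and 1U/10A fraction >= ``min_frac``."""
    keep = (
        (stats["rpm"] > min_rpm)
        & (stats["n_distinct"] >= min_distinct)
        & (stats["frac_1u10a"] >= min_frac)
    )
    return stats.loc[keep].reset_index(drop=True)


def merge_windows(passing: pd.DataFrame) -> list[GenomicInterval]:
    """Union of overlapping-or-bookended passing windows per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom, sub in passing.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return merged


# --------------------------------------------------------------------------
# boundary trimming
# --------------------------------------------------------------------------


def trim_boundaries(
    candidate: GenomicInterval,
    reads: pd.DataFrame,
    unique_total: float,
    window: int = TRIM_WINDOW_BP,
    min_rpm: float = TRIM_MIN_RPM,
    max_gap: int = TRIM_MAX_GAP_BP,
) -> tuple[GenomicInterval | None, str]:
    """Refine candidate ends by scanning adjacent 100-bp windows.

    A window qualifies with > ``min_rpm`` reads per million unique mappers.
    From each end moving inward, the boundary is the outer edge of the first
    qualifying window that is followed (resp. preceded) by another qualifying
    window less than ``max_gap`` bp away. Candidates with no qualifying pair
    are discarded with a reason (never silently dropped).
    """
    n_win = (len(candidate) + window - 1) // window
    if n_win < 2:
        return None, "discarded:too_short"
    ws = candidate.start + np.arange(n_win, dtype=np.int64) * window
    we = np.minimum(ws + window, candidate.end)
    sub = reads[reads["chrom"] == candidate.chrom]
    if sub.empty:
        return None, "discarded:no_reads"
    counts = _window_weighted_counts(
        sub["start"].to_numpy(np.int64),
        sub["end"].to_numpy(np.int64),
        sub["weight"].to_numpy(float),
        ws, we,
    )
    rpm = counts / unique_total * 1e6
    qual = np.flatnonzero(rpm > min_rpm)
    if len(qual) < 2:
        return None, "discarded:no_qualifying_pair"
    # gap between consecutive qualifying windows, in bp between their edges
    gaps = ws[qual[1:]] - we[qual[:-1]]
    near = np.flatnonzero(gaps < max_gap)
    if len(near) == 0:
        return None, "discarded:no_qualifying_pair"
    five_prime = int(ws[qual[near[0]]])
    three_prime = int(we[qual[near[-1] + 1]])
    if three_prime <= five_prime:
        return None, "discarded:degenerate_after_trim"
    return GenomicInterval(candidate.chrom, five_prime, three_prime), "trimmed"


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------


def assign_strand(
    candidate: GenomicInterval,
    plus_coverage: SignalTrack,
    minus_coverage: SignalTrack,
) -> tuple[str, bool]:
    """Strand of the dominant long-RNA transcript over the interval.

    Returns (strand, flagged); flagged is True for the degenerate tie /
    no-coverage case, where the strand is '.'.
    """
    plus = plus_coverage.integral(candidate.chrom, candidate.start, candidate.end)
    minus = minus_coverage.integral(candidate.chrom, candidate.start, candidate.end)
    if plus > minus:
        return "+", False
    if minus > plus:
        return "-", False
    return ".", True


def infer_introns(
    candidate: GenomicInterval,
    strand: str,
    junctions: pd.DataFrame,
    min_support: int = MIN_JUNCTION_SUPPORT,
) -> list[tuple[int, int]]:
    """Exon blocks from splice junctions inside the candidate.

    Junctions (columns chrom, start, end, strand, support) wholly inside the
    interval on its strand with support >= ``min_support`` are accepted
    greedily by descending support (ties: leftmost) into a non-overlapping
    chain; exons are the complementary blocks. No junctions: one exon.
    """
    sel = junctions[
        (junctions["chrom"] == candidate.chrom)
        & (junctions["start"] >= candidate.start)
        & (junctions["end"] <= candidate.end)
        & (junctions["support"] >= min_support)
    ]
    if strand in {"+", "-"} and "strand" in sel.columns:
        sel = sel[sel["strand"].isin([strand, "."])]
    chosen: list[tuple[int, int]] = []
    for _, row in sel.sort_values(
        ["support", "start"], ascending=[False, True]
    ).iterrows():
        s, e = int(row["start"]), int(row["end"])
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    chosen.sort()
    exons = []
    pos = candidate.start
    for s, e in chosen:
        if s > pos:
            exons.append((pos, s))
        pos = max(pos, e)
    if pos < candidate.end:
        exons.append((pos, candidate.end))
    return exons or [(candidate.start, candidate.end)]


def classify_genic(
    cluster: GenomicInterval, protein_coding: list[GeneModel]
) -> str:
    """genic iff > 50% of cluster bp overlap protein-coding gene spans
    (strand-agnostic; spans merged before counting)."""
    spans = sorted(
        (g.start, g.end) for g in protein_coding if g.chrom == cluster.chrom
    )
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    covered = sum(
        max(0, min(e, cluster.end) - max(s, cluster.start)) for s, e in merged
    )
    return "genic" if covered / len(cluster) > GENIC_MIN_OVERLAP else "intergenic"


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def discover_clusters(
    reads: pd.DataFrame,
    unique_total: float,
    chrom_lengths: dict[str, int],
    junctions: pd.DataFrame | None = None,
    plus_coverage: SignalTrack | None = None,
    minus_coverage: SignalTrack | None = None,
    protein_coding: list[GeneModel] | None = None,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    min_rpm: float = MIN_WINDOW_RPM,
    min_distinct: int = MIN_DISTINCT,
    min_frac: float = MIN_FRAC_1U10A,
) -> tuple[list[PiRNACluster], list[dict]]:
    """Full discovery pass: scan, filter, merge, trim, annotate.

    Returns (clusters, discard_log); the discard log records every candidate
    dropped at trimming with its reason.
    """
    from .expression import pirna_abundance

    stats = compute_window_stats(reads, unique_total, chrom_lengths, window, step)
    passing = call_windows(stats, min_rpm, min_distinct, min_frac)
    candidates = merge_windows(passing)
    clusters: list[PiRNACluster] = []
    discards: list[dict] = []
    for i, cand in enumerate(candidates):
        refined, status = trim_boundaries(cand, reads, unique_total)
        if refined is None:
            discards.append(
                {"chrom": cand.chrom, "start": cand.start, "end": cand.end,
                 "reason": status}
            )
            continue
        if plus_coverage is not None and minus_coverage is not None:
            strand, flagged = assign_strand(refined, plus_coverage, minus_coverage)
        else:
            strand, flagged = ".", True
        if junctions is not None:
            exons = infer_introns(refined, strand, junctions)
        else:
            exons = [(refined.start, refined.end)]
        genic = classify_genic(refined, protein_coding or [])
        rpm = pirna_abundance(reads, refined, unique_total)
        clusters.append(
            PiRNACluster(
                id=f"cluster_{refined.chrom}_{refined.start}",
                chrom=refined.chrom,
                start=refined.start,
                end=refined.end,
                strand=strand,
                exons=exons,
                genic_type=genic,
                abundance_rpm=rpm,
                provenance={
                    "candidate": (cand.start, cand.end),
                    "trim_status": status,
                    "strand_flagged": flagged,
                },
            )
        )
    return clusters, discards
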