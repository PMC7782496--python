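"""Epigenomic signal aggregation: control-gene normalization, promoter and
gene-body means, strand-oriented binning, metagene profiles, and the
extension-index statistic for broad signal domains.

The extension index asks how far a mark extends downstream of a TSS: the
genome is cut into 200-bp bins, bins beyond the 95th percentile of the gene's
own far-downstream background (TSS + 80..100 kb) count as enriched, and a
downstream walk from the TSS may bridge gaps of up to 19 consecutive
sub-threshold bins (3800 bp) before stopping. The relative index divides by
the first-exon length (gene length for intronless genes), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SignalTrack

__all__ = [
    "BinnedSignal",
    "ExtensionResult",
    "select_control_genes",
    "normalize_by_controls",
    "aggregate_signal",
    "bin_signal",
    "extension_index",
    "metagene_profile",
]

BIN_BP = 200
SPAN_UP_BP = 10_000
SPAN_DOWN_BP = 100_000
BACKGROUND_START_BP = 80_000
BACKGROUND_END_BP = 100_000
BACKGROUND_QUANTILE = 0.95
MAX_GAP_BINS = 19
MIN_BACKGROUND_BINS = 25

CONTROL_RATIO_LOW = 0.66
CONTROL_RATIO_HIGH = 1.5
CONTROL_MIN_RPKM = 0.1


# --------------------------------------------------------------------------
# control-gene normalization
# --------------------------------------------------------------------------


def select_control_genes(expr: pd.DataFrame) -> pd.Index:
    """Genes with stable expression across cell types, for scaling signals.

    ``expr`` is gene x cell-type RPKM (>= 2 columns). A gene qualifies iff
    every pairwise expression ratio lies in (0.66, 1.5) and its maximal
    expression exceeds 0.1 RPKM.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two cell types")
    vals = expr.to_numpy(float)
    mx = vals.max(axis=1)
    mn = vals.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mn > 0, mx / mn, np.inf)
    ok = (
        (mx > CONTROL_MIN_RPKM)
        & (ratio < CONTROL_RATIO_HIGH)
        & (1.0 / ratio > CONTROL_RATIO_LOW)
    )
    return expr.index[ok]


def normalize_by_controls(levels: pd.DataFrame, controls: pd.Index | list) -> pd.DataFrame:
    """Divide each sample's per-gene levels by that sample's median over the
    control genes, so the control median is 1 after scaling."""
    controls = pd.Index(controls)
    present = controls.intersection(levels.index)
    if len(present) == 0:
        raise ValueError("empty control set")
    medians = levels.loc[present].median(axis=0)
    if (medians <= 0).any():
        bad = medians.index[medians <= 0].tolist()
        raise ValueError(f"non-positive control median for samples {bad}")
    return levels / medians


# --------------------------------------------------------------------------
# aggregation and binning
# --------------------------------------------------------------------------


def aggregate_signal(track: SignalTrack, gene: GeneModel, region: str = "promoter") -> float:
    """Length-weighted mean signal over a standard gene region.

    Regions: ``promoter`` = TSS +/- 2 kb; ``gene_body`` = TSS + 2 kb (in
    transcription direction) to the 3' end; ``tss500`` = TSS +/- 500 bp
    (the 5hmC window). Uncovered bases contribute 0.
    """
    tss = gene.tss
    if region == "promoter":
        start, end = tss - 2000, tss + 2000
    elif region == "tss500":
        start, end = tss - 500, tss + 500
    elif region == "gene_body":
        if gene.strand == "+":
            start, end = tss + 2000, gene.end
        else:
            start, end = gene.start, tss - 2000
        if end <= start:
            raise ValueError(f"gene {gene.id} shorter than 2 kb: no gene body")
    else:
        raise ValueError(f"unknown region {region!r}")
    start = max(0, start)
    return track.mean(gene.chrom, start, end)


@dataclass
class BinnedSignal:
    """Strand-oriented bin means around a TSS.

    ``offsets`` are bin-start offsets from the TSS in transcription direction
    (negative = upstream); ``values[i]`` is the mean signal over
    [offset_i, offset_i + bin_size)."""

    gene_id: str
    offsets: np.ndarray
    values: np.ndarray
    bin_size: int

    def downstream(self) -> np.ndarray:
        return self.values[self.offsets >= 0]


def bin_signal(
    track: SignalTrack,
    gene: GeneModel,
    bin_size: int = BIN_BP,
    span: tuple[int, int] = (-SPAN_UP_BP, SPAN_DOWN_BP),
    chrom_length: int | None = None,
) -> BinnedSignal:
    """Mean signal per bin over TSS + span, oriented along transcription.

    Bins beyond the chromosome end (when ``chrom_length`` is given) are
    truncated away rather than zero-filled.
    """
    lo, hi = span
    offsets = np.arange(lo, hi, bin_size, dtype=np.int64)
    tss = gene.tss
    if gene.strand == "+":
        starts = tss + offsets
        ends = starts + bin_size
    else:
        ends = tss - offsets
        starts = ends - bin_size
    keep = starts >= 0
    if chrom_length is not None:
        keep &= ends <= chrom_length
    offsets = offsets[keep]
    starts = starts[keep]
    ends = ends[keep]
    sums = track.integral(gene.chrom, starts, ends)
    return BinnedSignal(gene.id, offsets, np.asarray(sums) / bin_size, bin_size)


# --------------------------------------------------------------------------
# extension index
# --------------------------------------------------------------------------


@dataclass
class ExtensionResult:
    gene_id: str
    extension_index: int          # bp from TSS; multiple of bin size
    relative_extension: float     # capped at 1
    threshold: float
    background_quantile: float
    n_background_bins: int


def extension_index(
    binned: BinnedSignal,
    first_unit_length: int,
    background_span: tuple[int, int] = (BACKGROUND_START_BP, BACKGROUND_END_BP),
    quantile: float = BACKGROUND_QUANTILE,
    max_gap_bins: int = MAX_GAP_BINS,
    min_background_bins: int = MIN_BACKGROUND_BINS,
) -> ExtensionResult:
    """Distance from the TSS to the furthest enriched bin reachable while
    bridging gaps of at most ``max_gap_bins`` sub-threshold bins.

    Enriched means strictly above the ``quantile`` of the gene's own
    background bins (offsets in ``background_span``). ``first_unit_length``
    is the first-exon length for spliced genes, the gene length for
    intronless ones.
    """
    if first_unit_length <= 0:
        raise ValueError("first_unit_length must be positive")
    bg_lo, bg_hi = background_span
    bg_mask = (binned.offsets >= bg_lo) & (binned.offsets < bg_hi)
    n_bg = int(bg_mask.sum())
    if n_bg < min_background_bins:
        raise ValueError(
            f"gene {binned.gene_id}: only {n_bg} background bins "
            f"(need >= {min_background_bins})"
        )
    threshold = float(np.quantile(binned.values[bg_mask], quantile))
    down_mask = binned.offsets >= 0
    offsets = binned.offsets[down_mask]
    enriched = binned.values[down_mask] > threshold
    furthest = -1
    gap = 0
    for i, flag in enumerate(enriched):
        if flag:
            furthest = i
            gap = 0
        else:
            gap += 1
            if gap > max_gap_bins:
                break
    ext = int(offsets[furthest] + binned.bin_size) if furthest >= 0 else 0
    return ExtensionResult(
        gene_id=binned.gene_id,
        extension_index=ext,
        relative_extension=min(1.0, ext / first_unit_length),
        threshold=threshold,
        background_quantile=quantile,
        n_background_bins=n_bg,
    )


# --------------------------------------------------------------------------
# metagene
# --------------------------------------------------------------------------


def metagene_profile(
    track: SignalTrack,
    genes: list[GeneModel],
    span: tuple[int, int] = (-2000, 2000),
    bin_size: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-bin mean across genes of strand-oriented binned signal.

    Returns a DataFrame (bin_offset, mean, n) where n is the number of genes
    contributing to the bin (bins truncated at chromosome ends drop out).
    """
    if not genes:
        raise ValueError("no genes")
    lo, hi = span
    offsets = np.arange(lo, hi, bin_size, dtype=np.int64)
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=int)
    for g in genes:
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        b = bin_signal(track, g, bin_size=bin_size, span=span, chrom_length=clen)
        idx = np.searchsorted(offsets, b.offsets)
        total[idx] += b.values
        count[idx] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame({"bin_offset": offsets, "mean": mean, "n": count})
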