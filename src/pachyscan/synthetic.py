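"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a toy
two-chromosome genome carrying eight planted piRNA-producing loci of three
structural types (long intronless, long first exon + short second exon,
short intronless), with promoter sequences engineered into low / intermediate
/ high O/E CG bands, 1U-biased 24-32-nt reads at per-locus abundances,
broad acylation domains over long loci vs narrow TSS peaks at short loci,
tissue-restricted expression, mutant/heterozygote fold-changes, per-CG-site
methylation calls, and a multi-species synteny/abundance panel. Three decoy
read pile-ups each violate exactly one cluster-calling filter.

Planted abundance increases with first-unit length while promoter O/E CG
decreases with it, mirroring the covariation seen at real pachytene piRNA
clusters, so correlation-sign recovery is testable downstream.

All generators are pure functions of the config (which carries the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeSequence, GenomicInterval, SignalTrack
from .promoters import compute_oe_cg

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_small_rna",
    "simulate_signal_tracks",
    "simulate_tables",
    "simulate_all",
]

TISSUES = [
    "testis", "forebrain", "heart", "liver", "kidney",
    "lung", "spleen", "muscle", "thymus",
]
CELL_TYPES = ["spermatogonia", "spermatocytes", "spermatids"]
SPECIES = ["human", "rhesus", "marmoset", "rat", "cow", "opossum", "platypus"]


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    total_unique_reads: float = 1_000_000.0  # normalization denominator (read-equivalents)
    frac_1u: float = 0.7
    frac_nt10a: float = 0.3
    frac_multimappers: float = 0.1           # n_map_locations = 2
    background_reads_per_kb: float = 1.0
    # promoter O/E CG sampling half-width around each locus target; the
    # per-locus targets are spaced so the bands are disjoint, preserving the
    # planted O/E CG ordering across clusters
    oe_band_halfwidth: float = 0.02
    promoter_flank: int = 2_000
    # signal tracks
    baseline: float = 0.1
    broad_level: float = 5.0
    narrow_level: float = 5.0
    narrow_halfwidth: int = 600
    noise_sd: float = 0.0
    # tables
    somatic_exclusive_max_rpkm: float = 0.05
    amyb_regulated_ratio: float = 0.30
    amyb_unregulated_ratio: float = 0.95
    btbd18_dependent_ratios: tuple[float, float] = (0.40, 0.35)
    btbd18_independent_ratios: tuple[float, float] = (0.90, 1.05)
    methylation_coverage: int = 20
    n_methylation_replicates: int = 4
    n_control_genes: int = 30

    def __post_init__(self):
        for frac in (self.frac_1u, self.frac_nt10a, self.frac_multimappers):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.total_unique_reads <= 0:
            raise ValueError("total_unique_reads must be positive")
        # each chromosome hosts 4 planted loci spaced 450 kb apart, each
        # needing 100 kb of clear downstream track
        if self.chrom_length < 1_750_000:
            raise ValueError("chromosome too small to host the planted loci")


# Planted locus plan: (id, structural_type, first-unit bp, extra blocks,
# O/E CG target, abundance RPM). Abundance is monotone in first-unit length;
# O/E CG is anti-monotone.
_CLUSTER_PLAN = [
    # id, type, first_unit, (intron, exon2), oe_target, rpm
    ("pi01", "long_intronless", 50_000, None, 0.08, 2500.0),
    ("pi02", "long_intronless", 40_000, None, 0.18, 2000.0),
    ("pi03", "long_intronless", 30_000, None, 0.28, 1500.0),
    ("pi04", "long_first_exon", 45_000, (8_000, 4_000), 0.13, 2250.0),
    ("pi05", "long_first_exon", 25_000, (6_000, 4_000), 0.38, 1250.0),
    ("pi06", "short", 9_000, None, 0.46, 500.0),
    ("pi07", "short", 7_000, None, 0.60, 350.0),
    ("pi08", "short", 5_000, None, 0.80, 250.0),
]

_CLUSTER_SITES = [  # (chrom index, start, strand)
    (0, 200_000, "+"), (0, 650_000, "-"), (0, 1_100_000, "+"), (0, 1_550_000, "-"),
    (1, 200_000, "+"), (1, 650_000, "-"), (1, 1_100_000, "+"), (1, 1_550_000, "-"),
]

_DECOY_PLAN = [
    # id, chrom index, start, length, violated filter
    ("decoy_low_rpm", 1, 400_000, 10_000, "rpm"),
    ("decoy_few_distinct", 1, 850_000, 10_000, "distinct"),
    ("decoy_low_1u", 1, 1_300_000, 10_000, "frac_1u10a"),
]

_CONSERVATION_PLAN = {
    "pi01": "eutherian_conserved", "pi02": "eutherian_conserved",
    "pi03": "murine_conserved", "pi04": "eutherian_conserved",
    "pi05": "murine_conserved", "pi06": "mouse_specific",
    "pi07": "mouse_specific", "pi08": "eutherian_conserved",
}

_AMYB_REGULATED = {"pi01", "pi02", "pi03", "pi04", "pi05", "pi06"}
_BTBD18_DEPENDENT = {"pi01", "pi02", "pi03", "pi04", "pi05"}
_BROAD_EXPRESSION = {"pi06"}  # all others are testis-exclusive

_METHYLATION_BY_CG = {"low": 0.85, "intermediate": 0.45, "high": 0.05}
_FIVEHMC_BY_CG = {"low": 3.0, "intermediate": 1.0, "high": 0.2}


@dataclass
class GroundTruth:
    clusters: pd.DataFrame              # one row per planted cluster
    decoys: pd.DataFrame
    cluster_models: list[GeneModel]
    coding_models: list[GeneModel]
    control_models: list[GeneModel]

    def model(self, cluster_id: str) -> GeneModel:
        for m in self.cluster_models:
            if m.id == cluster_id:
                return m
        raise KeyError(cluster_id)


# --------------------------------------------------------------------------
# sequence construction
# --------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _measure_oe(arr: np.ndarray) -> float:
    L = len(arr)
    n_c = int((arr == b"C").sum())
    n_g = int((arr == b"G").sum())
    if n_c + n_g == 0:
        return 0.0
    n_cg = int(((arr[:-1] == b"C") & (arr[1:] == b"G")).sum())
    return (n_cg / (L - 1)) / (((n_c + n_g) / (2 * L)) ** 2)


def _adjust_oe(
    rng: np.random.Generator,
    arr: np.ndarray,
    lo: int,
    hi: int,
    target: float,
    halfwidth: float,
    protect: tuple[int, int] | None = None,
    max_iter: int = 400,
) -> None:
    """Drive the O/E CG of ``arr[lo:hi]`` into the target band in place.

    Breaks or plants CG dinucleotides, never touching positions inside
    ``protect`` (a [start, end) slice of ``arr``).
    """
    def mutable(pos: np.ndarray) -> np.ndarray:
        if protect is None:
            return pos
        ps, pe = protect
        return pos[(pos + 1 < ps) | (pos >= pe)]  # both pos and pos+1 free

    for _ in range(max_iter):
        sl = arr[lo:hi]
        oe = _measure_oe(sl)
        if abs(oe - target) <= halfwidth:
            return
        cg_pos = lo + np.flatnonzero((sl[:-1] == b"C") & (sl[1:] == b"G"))
        n_c = int((sl == b"C").sum())
        n_g = int((sl == b"G").sum())
        L = hi - lo
        want = target * (((n_c + n_g) / (2 * L)) ** 2) * (L - 1)
        if oe > target:
            kill = mutable(cg_pos)
            n_kill = min(max(1, int(round(len(cg_pos) - want))), len(kill))
            if n_kill == 0:
                break
            kill = rng.choice(kill, size=n_kill, replace=False)
            # replace the G to break the dinucleotide; draw from {A,T,C} to
            # roughly conserve C+G content
            arr[kill + 1] = rng.choice(np.frombuffer(b"ATC", dtype="S1"), size=n_kill)
        else:
            deficit = max(1, int(round(want - len(cg_pos))))
            pos = mutable(rng.integers(lo, hi - 1, size=4 * deficit))[:deficit]
            if len(pos) == 0:
                break
            arr[pos] = b"C"
            arr[pos + 1] = b"G"
    raise RuntimeError(
        f"could not reach O/E CG band {target}+/-{halfwidth} over [{lo},{hi})"
    )


def _promoter_seq(
    rng: np.random.Generator, length: int, target: float, halfwidth: float,
    core_halfwidth: int = 500,
) -> np.ndarray:
    """Sequence whose O/E CG lands in the target band, both over its full
    length and over the central TSS-proximal core (+/- ``core_halfwidth``),
    so any promoter-window choice sees the planted band.

    Starts from an iid ACGT sequence (O/E ~ 1), drives the core into the
    band first, then the full sequence with the core protected.
    """
    arr = _random_seq(rng, length)
    mid = length // 2
    core = (mid - core_halfwidth, mid + core_halfwidth)
    _adjust_oe(rng, arr, core[0], core[1], target, halfwidth)
    _adjust_oe(rng, arr, 0, length, target, halfwidth, protect=core)
    return arr


def _build_models(config: SimulationConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    models = []
    rows = []
    for (cid, stype, first_unit, blocks, oe_target, rpm), (ci, start, strand) in zip(
        _CLUSTER_PLAN, _CLUSTER_SITES
    ):
        chrom = f"chr{ci + 1}"
        if blocks is None:
            end = start + first_unit
            exons = [(start, end)]
        else:
            intron, exon2 = blocks
            end = start + first_unit + intron + exon2
            if strand == "+":
                exons = [(start, start + first_unit), (start + first_unit + intron, end)]
            else:
                exons = [(start, start + exon2), (start + exon2 + intron, end)]
        model = GeneModel(
            id=cid, chrom=chrom, start=start, end=end, strand=strand,
            exons=exons, biotype="piRNA_cluster", class_label="pachytene",
        )
        models.append(model)
        cg_class = "low" if oe_target < 0.25 else ("high" if oe_target > 0.5 else "intermediate")
        rows.append(
            {
                "cluster_id": cid,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": model.tss,
                "structural_type": stype,
                "first_unit_length": first_unit,
                "oe_target": oe_target,
                "cg_class": cg_class,
                "rpm": rpm,
                "testis_category": "broad" if cid in _BROAD_EXPRESSION else "exclusive",
                "amyb_regulated": cid in _AMYB_REGULATED,
                "btbd18_dependent": cid in _BTBD18_DEPENDENT,
                "conservation_class": _CONSERVATION_PLAN[cid],
                "methylation_level": _METHYLATION_BY_CG[cg_class],
                "broad_domain": stype != "short",
                "extension_extent": first_unit if stype != "short" else config.narrow_halfwidth,
            }
        )
    return models, pd.DataFrame(rows).set_index("cluster_id")


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Toy genome with planted loci; promoters hit their target O/E CG band.

    Returns the genome, all gene models (clusters + protein-coding host +
    control genes), and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    chrom_arrays = {
        f"chr{i + 1}": _random_seq(rng, config.chrom_length)
        for i in range(config.n_chromosomes)
    }
    cluster_models, clusters = _build_models(config)

    measured, measured_core = {}, {}
    for cid, row in clusters.iterrows():
        tss = int(row["tss"])
        flank = config.promoter_flank
        seq = _promoter_seq(
            rng, 2 * flank, float(row["oe_target"]), config.oe_band_halfwidth
        )
        chrom_arrays[row["chrom"]][tss - flank : tss + flank] = seq
        measured[cid] = _measure_oe(seq)
        measured_core[cid] = _measure_oe(seq[flank - 500 : flank + 500])
    clusters["oe_measured"] = pd.Series(measured)
    clusters["oe_measured_core"] = pd.Series(measured_core)

    # protein-coding host overlapping pi03 by > 50%, making it genic
    host = GeneModel(
        id="Host1", chrom="chr1", start=1_098_000, end=1_126_000,
        strand="+", biotype="protein_coding",
    )
    controls = []
    for i in range(config.n_control_genes):
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        start = 20_000 + (i // config.n_chromosomes) * 4_000
        controls.append(
            GeneModel(
                id=f"ctrl{i:02d}", chrom=chrom, start=start, end=start + 3_000,
                strand="+" if i % 2 == 0 else "-", biotype="protein_coding",
            )
        )

    genome = GenomeSequence(
        {name: arr.tobytes().decode("ascii") for name, arr in chrom_arrays.items()}
    )
    truth = GroundTruth(
        clusters=clusters,
        decoys=pd.DataFrame(
            [
                {"decoy_id": did, "chrom": f"chr{ci + 1}", "start": s,
                 "end": s + ln, "violates": filt}
                for did, ci, s, ln, filt in _DECOY_PLAN
            ]
        ).set_index("decoy_id"),
        cluster_models=cluster_models,
        coding_models=[host],
        control_models=controls,
    )
    return genome, cluster_models + [host] + controls, truth


# --------------------------------------------------------------------------
# small-RNA reads
# --------------------------------------------------------------------------


def _draw_reads(
    rng: np.random.Generator,
    chrom: str,
    lo: int,
    hi: int,
    n: int,
    strand: str,
    frac_1u: float,
    frac_nt10a: float,
    frac_multi: float,
    n_map_multi: int = 2,
    n_distinct_positions: int | None = None,
) -> pd.DataFrame:
    if n_distinct_positions is not None:
        pool_starts = rng.integers(lo, hi - 32, size=n_distinct_positions)
        pool_lens = rng.integers(24, 33, size=n_distinct_positions)
        pick = rng.integers(0, n_distinct_positions, size=n)
        starts = pool_starts[pick]
        lengths = pool_lens[pick]
    else:
        starts = rng.integers(lo, hi - 32, size=n)
        lengths = rng.integers(24, 33, size=n)
    nt1 = np.where(
        rng.random(n) < frac_1u, "T",
        rng.choice(np.array(["A", "C", "G"]), size=n),
    )
    nt10 = np.where(
        rng.random(n) < frac_nt10a, "A",
        rng.choice(np.array(["C", "G", "T"]), size=n),
    )
    n_map = np.where(rng.random(n) < frac_multi, n_map_multi, 1)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": strand,
            "length": lengths,
            "nt1": nt1,
            "nt10": nt10,
            "n_map_locations": n_map,
        }
    )


def simulate_small_rna(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, float]:
    """Mapped 24-32-nt reads: planted clusters at their target RPM, decoys,
    and sparse background. Returns (reads, unique_total)."""
    rng = np.random.default_rng(config.seed + 1)
    frames = []
    mean_weight = 1.0 - config.frac_multimappers / 2.0
    for cid, row in truth.clusters.iterrows():
        n = int(round(row["rpm"] / mean_weight * config.total_unique_reads / 1e6))
        frames.append(
            _draw_reads(
                rng, row["chrom"], int(row["start"]), int(row["end"]), n,
                row["strand"], config.frac_1u, config.frac_nt10a,
                config.frac_multimappers,
            )
        )
    for did, row in truth.decoys.iterrows():
        lo, hi = int(row["start"]), int(row["end"])
        if row["violates"] == "rpm":
            # abundant species, but every read maps to 8 locations: weighted
            # RPM 37.5 stays below 100 even on top of background, while
            # distinct species stay above 200
            frames.append(
                _draw_reads(rng, row["chrom"], lo, hi, 300, "+",
                            config.frac_1u, config.frac_nt10a, 1.0, n_map_multi=8)
            )
        elif row["violates"] == "distinct":
            frames.append(
                _draw_reads(rng, row["chrom"], lo, hi, 300, "+",
                            config.frac_1u, config.frac_nt10a,
                            config.frac_multimappers,
                            n_distinct_positions=50)
            )
        else:  # frac_1u10a
            frames.append(
                _draw_reads(rng, row["chrom"], lo, hi, 300, "+",
                            0.2, 0.1, config.frac_multimappers)
            )
    n_bg = int(config.background_reads_per_kb * config.n_chromosomes
               * config.chrom_length / 1000)
    for i in range(config.n_chromosomes):
        frames.append(
            _draw_reads(
                rng, f"chr{i + 1}", 0, config.chrom_length,
                n_bg // config.n_chromosomes,
                "+", 0.25, 0.25, config.frac_multimappers,
            )
        )
    reads = pd.concat(frames, ignore_index=True)
    reads["weight"] = 1.0 / reads["n_map_locations"]
    return reads, config.total_unique_reads


# --------------------------------------------------------------------------
# signal tracks
# --------------------------------------------------------------------------


def _paint_track(
    config: SimulationConfig,
    features: list[tuple[str, int, int, float]],
    baseline: float,
    rng: np.random.Generator | None = None,
) -> SignalTrack:
    """Track = flat baseline pedestal with non-overlapping feature intervals.

    With ``noise_sd`` > 0 the baseline is perturbed per 200-bp bin; the
    default is a deterministic pedestal (see the methods note on why iid
    background noise defeats a quantile-over-background rule).
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    for chrom, s, e, v in features:
        by_chrom.setdefault(chrom, []).append((s, e, v))
    rows = []
    L = config.chrom_length
    for chrom, feats in by_chrom.items():
        feats.sort()
        for (s, e), (s2, e2) in zip(
            [(f[0], f[1]) for f in feats], [(f[0], f[1]) for f in feats[1:]]
        ):
            if s2 < e:
                raise ValueError(f"overlapping planted features on {chrom}")
        pos = 0
        for s, e, v in feats:
            if s > pos:
                rows.extend(_baseline_rows(config, chrom, pos, s, baseline, rng))
            rows.append((chrom, s, e, v))
            pos = e
        if pos < L:
            rows.extend(_baseline_rows(config, chrom, pos, L, baseline, rng))
    return SignalTrack.from_tuples(rows)


def _baseline_rows(config, chrom, start, end, baseline, rng):
    if config.noise_sd <= 0 or rng is None:
        return [(chrom, start, end, baseline)] if baseline > 0 else []
    edges = list(range(start, end, 200)) + [end]
    vals = np.clip(
        baseline + rng.normal(0.0, config.noise_sd, size=len(edges) - 1), 0.0, None
    )
    return [
        (chrom, a, b, float(v)) for a, b, v in zip(edges[:-1], edges[1:], vals)
    ]


def simulate_signal_tracks(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, SignalTrack]:
    """Acylation (broad at long loci, narrow at short), H3K4me3 (narrow
    everywhere), 5hmC (promoter level tied to CG class), and stranded
    long-RNA coverage."""
    rng = np.random.default_rng(config.seed + 2)
    acyl, h3k4, hmc, rna_plus, rna_minus = [], [], [], [], []
    for cid, row in truth.clusters.iterrows():
        chrom, tss, strand = row["chrom"], int(row["tss"]), row["strand"]
        fu = int(row["first_unit_length"])
        hw = config.narrow_halfwidth
        if row["broad_domain"]:
            lo, hi = (tss, tss + fu) if strand == "+" else (tss - fu, tss)
        else:
            lo, hi = tss - hw, tss + hw
        acyl.append((chrom, lo, hi, config.broad_level))
        h3k4.append((chrom, tss - hw, tss + hw, 4.0))
        hmc.append((chrom, tss - 500, tss + 500,
                    _FIVEHMC_BY_CG[row["cg_class"]] + config.baseline))
        cov = (chrom, int(row["start"]), int(row["end"]), float(row["rpm"]) / 100.0)
        (rna_plus if strand == "+" else rna_minus).append(cov)
    return {
        "acyl": _paint_track(config, acyl, config.baseline, rng),
        "h3k4me3": _paint_track(config, h3k4, config.baseline, rng),
        "fivehmc": _paint_track(config, hmc, config.baseline, rng),
        "rna_plus": _paint_track(config, rna_plus, 0.0, None),
        "rna_minus": _paint_track(config, rna_minus, 0.0, None),
    }


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------


def simulate_tables(
    config: SimulationConfig, truth: GroundTruth, genome: GenomeSequence
) -> dict[str, pd.DataFrame]:
    """Expression matrices, mutant/het ratios, methylation calls, splice
    junctions, A-MYB peaks, and the multi-species synteny/abundance panel."""
    rng = np.random.default_rng(config.seed + 3)
    clusters = truth.clusters

    # tissue expression (RPKM): testis tied to piRNA output; somatic levels
    # realize the planted testis category
    rows = {}
    for cid, row in clusters.iterrows():
        testis = row["rpm"] / 100.0
        if row["testis_category"] == "exclusive":
            som = rng.uniform(0.0, config.somatic_exclusive_max_rpkm, len(TISSUES) - 1)
        else:
            som = rng.uniform(1.0, 2.0, len(TISSUES) - 1)
        rows[cid] = [testis] + list(som)
    for g in truth.coding_models:
        rows[g.id] = [50.0] + list(rng.uniform(20.0, 40.0, len(TISSUES) - 1))
    for g in truth.control_models:
        base = rng.uniform(2.0, 10.0)
        rows[g.id] = list(base * rng.uniform(0.8, 1.2, len(TISSUES)))
    expression = pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES)
    expression.index.name = "gene_id"

    # three-cell-type expression for control-gene selection: controls stable,
    # clusters strongly stage-dependent
    rows3 = {}
    for g in truth.control_models:
        base = rng.uniform(1.0, 8.0)
        rows3[g.id] = list(base * rng.uniform(0.9, 1.1, 3))
    for cid, row in clusters.iterrows():
        base = row["rpm"] / 100.0
        rows3[cid] = [base * 0.05, base, base * 0.3]
    for g in truth.coding_models:
        rows3[g.id] = [5.0, 25.0, 10.0]
    expr3 = pd.DataFrame.from_dict(rows3, orient="index", columns=CELL_TYPES)
    expr3.index.name = "gene_id"

    # mutant / heterozygote ratios
    mh = []
    for cid, row in clusters.iterrows():
        if row["amyb_regulated"]:
            r14 = config.amyb_regulated_ratio * rng.uniform(0.8, 1.2)
            r17 = config.amyb_regulated_ratio * rng.uniform(0.8, 1.2)
        else:
            r14 = config.amyb_unregulated_ratio * rng.uniform(0.9, 1.2)
            r17 = config.amyb_unregulated_ratio * rng.uniform(0.9, 1.2)
        if row["btbd18_dependent"]:
            be, bp = config.btbd18_dependent_ratios
        else:
            be, bp = config.btbd18_independent_ratios
        mh.append(
            {
                "gene_id": cid,
                "amyb_mut_het_14": r14,
                "amyb_mut_het_17": r17,
                "btbd18_expr_mut_het": be * rng.uniform(0.9, 1.1),
                "btbd18_pirna_mut_het": bp * rng.uniform(0.9, 1.1),
            }
        )
    mut_het = pd.DataFrame(mh).set_index("gene_id")

    # A-MYB ChIP peaks and promoter enrichment
    peaks, enrich = [], []
    for cid, row in clusters.iterrows():
        if row["amyb_regulated"]:
            tss = int(row["tss"])
            peaks.append({"chrom": row["chrom"], "start": tss - 200, "end": tss + 200})
            enrich.append({"gene_id": cid, "enrichment": rng.uniform(3.5, 6.0)})
        else:
            enrich.append({"gene_id": cid, "enrichment": rng.uniform(0.8, 1.5)})
    amyb_peaks = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
    amyb_enrichment = pd.DataFrame(enrich).set_index("gene_id")

    # per-CG-site methylation calls, 4 replicates, at true CG positions
    meth_rows = []
    for cid, row in clusters.iterrows():
        tss, flank = int(row["tss"]), config.promoter_flank
        seq = genome.fetch(row["chrom"], tss - flank, tss + flank)
        cg_local = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        level = row["methylation_level"]
        for pos in cg_local:
            for rep in range(1, config.n_methylation_replicates + 1):
                total = config.methylation_coverage
                meth_rows.append(
                    {
                        "chrom": row["chrom"],
                        "pos": tss - flank + pos,
                        "meth_count": int(rng.binomial(total, level)),
                        "total_count": total,
                        "replicate": f"rep{rep}",
                    }
                )
    methylation = pd.DataFrame(
        meth_rows, columns=["chrom", "pos", "meth_count", "total_count", "replicate"]
    )

    # splice junctions (introns of spliced clusters, support 10; one junk)
    j_rows = []
    for m in truth.cluster_models:
        if m.is_spliced:
            for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
                j_rows.append(
                    {"chrom": m.chrom, "start": e1, "end": s2,
                     "strand": m.strand, "support": 10}
                )
    j_rows.append({"chrom": "chr1", "start": 10_000, "end": 11_000,
                   "strand": "+", "support": 1})
    junctions = pd.DataFrame(j_rows)

    # synteny map + per-species abundances realizing the conservation classes
    syn_rows, ab_rows = [], []
    for cid, row in clusters.iterrows():
        mouse_rpm = row["rpm"]
        cls = row["conservation_class"]
        if cls == "eutherian_conserved":
            similar = set(rng.choice(
                ["human", "rhesus", "marmoset", "rat", "cow"], size=3, replace=False
            ))
        elif cls == "murine_conserved":
            similar = {"rat"}
        else:
            similar = set()
        ab = {"gene_id": cid}
        for k, sp in enumerate(SPECIES):
            syn_rows.append(
                {
                    "gene_id": cid, "species": sp,
                    "chrom": f"{sp}_chr1",
                    "start": 1_000_000 + k * 200_000,
                    "end": 1_000_000 + k * 200_000 + int(row["end"] - row["start"]),
                    "strand": row["strand"],
                }
            )
            if sp in similar:
                ab[sp] = mouse_rpm * rng.uniform(0.5, 2.0)
            elif sp in ("opossum", "platypus"):
                ab[sp] = 0.0
            else:
                ab[sp] = mouse_rpm / rng.uniform(8.0, 20.0)
        ab_rows.append(ab)
    synteny = pd.DataFrame(syn_rows)
    species_abundance = pd.DataFrame(ab_rows).set_index("gene_id")

    return {
        "expression": expression,
        "expression_cell_types": expr3,
        "mut_het": mut_het,
        "amyb_peaks": amyb_peaks,
        "amyb_enrichment": amyb_enrichment,
        "methylation": methylation,
        "junctions": junctions,
        "synteny": synteny,
        "species_abundance": species_abundance,
    }


# --------------------------------------------------------------------------
# bundle
# --------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    models: list[GeneModel]
    truth: GroundTruth
    reads: pd.DataFrame
    unique_total: float
    tracks: dict[str, SignalTrack]
    tables: dict[str, pd.DataFrame]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.genome.lengths


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage; pure function of the config."""
    genome, models, truth = simulate_genome(config)
    reads, unique_total = simulate_small_rna(config, truth)
    tracks = simulate_signal_tracks(config, truth)
    tables = simulate_tables(config, truth, genome)
    return SimulatedDataset(
        config=config, genome=genome, models=models, truth=truth,
        reads=reads, unique_total=unique_total, tracks=tracks, tables=tables,
    )
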