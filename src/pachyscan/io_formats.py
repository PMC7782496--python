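"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate conventions
----------------------
Everything in memory is 0-based, half-open (BED/bedGraph semantics). The only
conversion happens at the GTF boundary, where exons arrive 1-based and closed.

Mapped small-RNA reads are consumed as pre-aligned intervals (a BED-like TSV
with sequence attributes), not BAM: alignment is upstream of this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomeSequence",
    "GenomicInterval",
    "GeneModel",
    "SignalTrack",
    "SmallRNARead",
    "SMALL_RNA_COLUMNS",
    "read_genome",
    "write_genome",
    "read_gene_models",
    "write_gene_models_bed12",
    "read_small_rna",
    "write_small_rna",
    "read_signal_track",
    "write_signal_track",
]


class FormatError(ValueError):
    """A file violated the format contract (message names the offending record)."""


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------

_VALID_BASES = set("ACGTN")


class GenomeSequence(Mapping[str, str]):
    """Uppercase chromosome sequences over {A,C,G,T,N} with unique names."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if len(seq) == 0:
                raise FormatError(f"empty sequence for record {name!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"record {name!r} contains invalid bases {sorted(bad)}"
                )
            if name in seqs:
                raise FormatError(f"duplicate record {name!r}")
            seqs[name] = seq
        self._seqs = seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence [start, end), clipped to the chromosome."""
        seq = self._seqs[chrom]
        return seq[max(0, start) : min(len(seq), end)]


def read_genome(path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Lowercase bases are uppercased; duplicate record names are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate record {rec.id!r}")
        if len(rec.seq) == 0:
            raise FormatError(f"empty sequence for record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# intervals and gene models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A transcript model: interval, strand and ordered exon blocks.

    The TSS is ``start`` on "+" and ``end`` on "-"; the first exon is the
    5'-most block in transcription direction.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str | None = None
    class_label: str | None = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.id}: exon ({s},{e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.id}: overlapping exons")
            prev_end = e

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) > 1

    @property
    def first_exon(self) -> tuple[int, int]:
        """5'-most exon in transcription direction."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def first_exon_length(self) -> int:
        s, e = self.first_exon
        return e - s

    def promoter(self, flank: int = 2000) -> GenomicInterval:
        """TSS +/- flank, clipped at zero."""
        return GenomicInterval(
            self.chrom, max(0, self.tss - flank), self.tss + flank, self.strand
        )


def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise FormatError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise FormatError(
            f"line {lineno}: blockCount {n_blocks} inconsistent with "
            f"{len(sizes)} sizes / {len(starts)} starts"
        )
    exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
    if exons[-1][1] != end:
        raise FormatError(f"line {lineno}: blocks do not reach chromEnd")
    return GeneModel(id=name, chrom=chrom, start=start, end=end, strand=strand, exons=exons)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _parse_gtf(lines: Iterable[str]) -> list[GeneModel]:
    # Collect exon lines per transcript; GTF is 1-based closed.
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str | None]] = {}
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise FormatError(f"line {lineno}: GTF needs 9 fields")
        if f[2] != "exon":
            continue
        attrs = dict(_GTF_ATTR.findall(f[8]))
        tid = attrs.get("transcript_id")
        if tid is None:
            raise FormatError(f"line {lineno}: exon without transcript_id")
        start1, end1 = int(f[3]), int(f[4])
        exons.setdefault(tid, []).append((start1 - 1, end1))  # to 0-based half-open
        meta.setdefault(tid, (f[0], f[6], attrs.get("gene_biotype")))
    models = []
    for tid, blocks in exons.items():
        chrom, strand, biotype = meta[tid]
        blocks = sorted(blocks)
        models.append(
            GeneModel(
                id=tid,
                chrom=chrom,
                start=blocks[0][0],
                end=blocks[-1][1],
                strand=strand,
                exons=blocks,
                biotype=biotype,
            )
        )
    return models


def read_gene_models(path, dialect: str = "bed12") -> list[GeneModel]:
    """Parse transcript models from BED12 or GTF.

    BED12 is read as 0-based half-open; GTF is converted from 1-based closed.
    """
    dialect = dialect.lower()
    with open(path) as fh:
        if dialect == "bed12":
            models = []
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                models.append(_parse_bed12_line(line, lineno))
            return models
        if dialect == "gtf":
            return _parse_gtf(fh)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gene_models_bed12(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in models:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.start, g.end, g.id, 0, g.strand,
                        g.start, g.end, "0,0,0", len(g.exons), sizes, starts,
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# small-RNA reads
# --------------------------------------------------------------------------

SMALL_RNA_COLUMNS = [
    "chrom", "start", "end", "strand", "length", "nt1", "nt10", "n_map_locations",
]

MIN_PIRNA_NT = 24
MAX_PIRNA_NT = 32


@dataclass(frozen=True)
class SmallRNARead:
    """One mapped 24-32-nt read; collections travel as DataFrames with the
    :data:`SMALL_RNA_COLUMNS` schema, this record validates a single row."""

    chrom: str
    start: int
    end: int
    strand: str
    length: int
    nt1: str
    nt10: str
    n_map_locations: int

    def __post_init__(self):
        if not MIN_PIRNA_NT <= self.length <= MAX_PIRNA_NT:
            raise ValueError(f"read length {self.length} outside piRNA range")
        if self.end - self.start != self.length:
            raise ValueError("interval span disagrees with read length")
        if self.n_map_locations < 1:
            raise ValueError("n_map_locations must be >= 1")
        for nt in (self.nt1, self.nt10):
            if nt not in {"A", "C", "G", "T", "U", "N"}:
                raise ValueError(f"invalid nucleotide {nt!r}")

    @property
    def weight(self) -> float:
        """Apportioned contribution of a (multi)mapped read."""
        return 1.0 / self.n_map_locations

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in SMALL_RNA_COLUMNS}


def read_small_rna(
    path,
    min_len: int = MIN_PIRNA_NT,
    max_len: int = MAX_PIRNA_NT,
) -> tuple[pd.DataFrame, int]:
    """Load mapped small-RNA reads, retaining only the piRNA size range.

    Returns ``(reads, n_dropped)`` where reads outside [min_len, max_len] nt
    have been removed. The ``weight`` column apportions multimappers as
    1 / n_map_locations.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SMALL_RNA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"small-RNA TSV missing columns {missing}")
    if (df["n_map_locations"] < 1).any():
        bad = df.index[df["n_map_locations"] < 1][0]
        raise FormatError(f"record {bad}: n_map_locations < 1")
    keep = df["length"].between(min_len, max_len)
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True).copy()
    df["weight"] = 1.0 / df["n_map_locations"]
    return df, n_dropped


def write_small_rna(reads: pd.DataFrame, path) -> None:
    reads[SMALL_RNA_COLUMNS].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# signal tracks (bedGraph semantics)
# --------------------------------------------------------------------------


class SignalTrack:
    """Per-interval signal over a genome; uncovered positions read as 0.

    Stored per chromosome as sorted, non-overlapping (starts, ends, values)
    arrays, with a precomputed cumulative integral so interval means are O(log n).
    """

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise FormatError(f"{chrom}: empty or inverted interval")
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise FormatError(
                    f"{chrom}: overlapping intervals at {starts[i + 1]} < {ends[i]}"
                )
            if not np.all(np.isfinite(values)):
                raise FormatError(f"{chrom}: non-finite value")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._data[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_tuples(cls, rows: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in rows:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        return cls(
            {
                chrom: (
                    np.array([r[0] for r in rows_]),
                    np.array([r[1] for r in rows_]),
                    np.array([r[2] for r in rows_]),
                )
                for chrom, rows_ in by_chrom.items()
            }
        )

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def iter_intervals(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom, (starts, ends, values, _) in self._data.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def _cumulative(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, pos) for an array of positions."""
        if chrom not in self._data:
            return np.zeros(len(pos), dtype=float)
        starts, ends, values, cum = self._data[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        # Intervals entirely left of pos contribute fully.
        idx = np.searchsorted(ends, pos, side="right")
        total = cum[idx]
        # The interval straddling pos (if any) contributes a partial piece.
        j = np.searchsorted(starts, pos, side="right") - 1
        valid = (j >= 0) & (j >= idx)
        jj = j[valid]
        total[valid] += values[jj] * (pos[valid] - starts[jj])
        return total

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self._cumulative(chrom, np.array([pos + 1]))[0]
                     - self._cumulative(chrom, np.array([pos]))[0])

    def integral(self, chrom: str, start, end) -> np.ndarray | float:
        """Sum of value x covered-length over [start, end); scalar for scalars."""
        scalar = np.isscalar(start) and np.isscalar(end)
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        start = np.maximum(start, 0)
        end = np.maximum(end, start)
        out = self._cumulative(chrom, end) - self._cumulative(chrom, start)
        return float(out[0]) if scalar else out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty region")
        return self.integral(chrom, start, end) / (end - start)

    def canonicalized(self) -> "SignalTrack":
        """Merge adjacent equal-value intervals; drop zero-value intervals."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values, _) in self._data.items():
            ms, me, mv = [], [], []
            for s, e, v in zip(starts, ends, values):
                if v == 0:
                    continue
                if mv and mv[-1] == v and ms and me[-1] == s:
                    me[-1] = e
                else:
                    ms.append(s); me.append(e); mv.append(v)
            if ms:
                out[chrom] = (np.array(ms), np.array(me), np.array(mv))
        return SignalTrack(out)


def read_signal_track(path) -> SignalTrack:
    """Read a 4-column bedGraph; overlapping intervals are a format error."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) != 4:
                raise FormatError(f"line {lineno}: bedGraph needs 4 columns")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return SignalTrack.from_tuples(rows)


def write_signal_track(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_intervals():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
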