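"""Genome coordinate model and flat-text I/O.

Everything downstream works in 0-based half-open coordinates (BED
convention). The two core containers are :class:`ChromSizes` (an ordered
chromosome table with an autosome/sex-chromosome partition) and
:class:`BinTable` (a fixed-width tiling of the genome used to index binned
contact matrices). Intervals (ATAC peaks, TSSs, CTCF motifs) are plain
records; overlap and nearest-distance queries are vectorised with numpy and
validated against brute force in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEX_NAMES = {"chrx", "chry", "x", "y"}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )


class ChromSizes:
    """Ordered chromosome table.

    Parameters
    ----------
    items
        Iterable of ``(name, length)`` pairs.
    sex_names
        Chromosome names (case-insensitive) treated as sex chromosomes;
        defaults to chrX/chrY/X/Y.
    """

    def __init__(
        self,
        items: Iterable[tuple[str, int]],
        sex_names: set[str] | None = None,
    ) -> None:
        sex = {s.lower() for s in (sex_names or _SEX_NAMES)}
        self.names: list[str] = []
        self.lengths: dict[str, int] = {}
        self.is_sex: dict[str, bool] = {}
        for name, length in items:
            if name in self.lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self.names.append(name)
            self.lengths[name] = length
            self.is_sex[name] = name.lower() in sex
        if not self.names:
            raise ValueError("no chromosomes")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    def autosomes(self) -> list[str]:
        return [n for n in self.names if not self.is_sex[n]]

    def sex_chromosomes(self) -> list[str]:
        return [n for n in self.names if self.is_sex[n]]


def read_chromsizes(path: str | Path) -> ChromSizes:
    """Read a two-column ``name length`` chrom.sizes file."""
    items: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 'name length'")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer length {parts[1]!r}"
                ) from exc
            items.append((parts[0], length))
    if not items:
        raise ParseError(f"{path}: no chromosomes")
    return ChromSizes(items)


class BinTable:
    """Fixed-width genomic bins tiling each chromosome.

    Bins are contiguous, sorted and non-overlapping within a chromosome;
    the last bin of a chromosome may be short. Bin ids are global (0-based
    across the concatenated genome) and the id <-> interval mapping is a
    bijection.
    """

    def __init__(self, sizes: ChromSizes, bin_size: int) -> None:
        if bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {bin_size}")
        self.sizes = sizes
        self.bin_size = int(bin_size)
        self._n_per_chrom: dict[str, int] = {}
        self._offset: dict[str, int] = {}
        off = 0
        for name in sizes.names:
            n = -(-sizes[name] // bin_size)  # ceil division
            self._n_per_chrom[name] = n
            self._offset[name] = off
            off += n
        self.n_bins = off
        # flat per-bin arrays
        chroms: list[str] = []
        starts = np.empty(self.n_bins, dtype=np.int64)
        ends = np.empty(self.n_bins, dtype=np.int64)
        for name in sizes.names:
            o, n = self._offset[name], self._n_per_chrom[name]
            chroms.extend([name] * n)
            s = np.arange(n, dtype=np.int64) * bin_size
            starts[o : o + n] = s
            ends[o : o + n] = np.minimum(s + bin_size, sizes[name])
        self.chrom = np.asarray(chroms, dtype=object)
        self.start = starts
        self.end = ends

    def n_bins_of(self, chrom: str) -> int:
        return self._n_per_chrom[chrom]

    def offset(self, chrom: str) -> int:
        return self._offset[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        o = self._offset[chrom]
        return slice(o, o + self._n_per_chrom[chrom])

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global bin id containing position ``pos`` on ``chrom``."""
        if chrom not in self.sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.sizes[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offset[chrom] + pos // self.bin_size

    def bin_interval(self, bin_id: int) -> Interval:
        if not (0 <= bin_id < self.n_bins):
            raise IndexError(f"bin id {bin_id} out of range")
        return Interval(
            str(self.chrom[bin_id]), int(self.start[bin_id]), int(self.end[bin_id])
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end}
        )

    def same_bins(self, other: "BinTable") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.sizes.names == other.sizes.names
            and all(self.sizes[n] == other.sizes[n] for n in self.sizes.names)
        )


def make_bins(sizes: ChromSizes, bin_size: int) -> BinTable:
    """Tile ``sizes`` into fixed ``bin_size`` bins (ceil per chromosome)."""
    return BinTable(sizes, bin_size)


# ---------------------------------------------------------------------------
# BED / BEDPE / bedGraph I/O
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    sizes: ChromSizes | None = None,
    strict: bool = False,
) -> list[Interval]:
    """Read BED3/BED6 into Interval records.

    With ``sizes`` given, records on unknown chromosomes are dropped with a
    logged count (default) or raise in ``strict`` mode.
    """
    out: list[Interval] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: need >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from exc
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            if sizes is not None and chrom not in sizes:
                if strict:
                    raise ParseError(
                        f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                    )
                dropped += 1
                continue
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append(Interval(chrom, start, end, name, strand, score))
    if dropped:
        logger.warning("read_bed(%s): dropped %d records on unknown chromosomes", path, dropped)
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def write_bedpe(records: pd.DataFrame, path: str | Path) -> None:
    """Write a BEDPE table; first six columns must be the paired anchors."""
    required = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"BEDPE frame missing columns {missing}")
    cols = required + [c for c in records.columns if c not in required]
    records[cols].to_csv(path, sep="\t", index=False)


def write_bedgraph(
    bins: BinTable, values: np.ndarray, path: str | Path, drop_nan: bool = True
) -> None:
    """Write a per-bin track (eigenvector, insulation) as bedGraph."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != bins.n_bins:
        raise ValueError("track length does not match bin table")
    with open(path, "w") as fh:
        for i in range(bins.n_bins):
            v = values[i]
            if drop_nan and not np.isfinite(v):
                continue
            fh.write(f"{bins.chrom[i]}\t{bins.start[i]}\t{bins.end[i]}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def intervals_per_bin(intervals: Sequence[Interval], bins: BinTable) -> np.ndarray:
    """Count intervals overlapping each bin (an interval may hit several)."""
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    for iv in intervals:
        if iv.chrom not in bins.sizes:
            continue
        o = bins.offset(iv.chrom)
        n = bins.n_bins_of(iv.chrom)
        first = iv.start // bins.bin_size
        last = (iv.end - 1) // bins.bin_size
        counts[o + first : o + min(last, n - 1) + 1] += 1
    return counts


def point_distance_to_nearest(
    intervals: Sequence[Interval], points: Sequence[tuple[str, int]]
) -> np.ndarray:
    """Closest-edge distance from each interval to the nearest point.

    Distance is 0 when a point falls inside the interval; otherwise the gap
    between the point and the interval's closest edge. Intervals on
    chromosomes with no point get +inf.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in points:
        by_chrom.setdefault(chrom, []).append(pos)
    sorted_pts = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}
    out = np.full(len(intervals), np.inf)
    for k, iv in enumerate(intervals):
        pts = sorted_pts.get(iv.chrom)
        if pts is None or pts.size == 0:
            continue
        # nearest point to the interval [start, end)
        idx = np.searchsorted(pts, iv.start)
        cand = pts[max(idx - 1, 0) : idx + 2]
        d = np.where(
            (cand >= iv.start) & (cand < iv.end),
            0,
            np.minimum(np.abs(cand - iv.start), np.abs(cand - (iv.end - 1))),
        )
        out[k] = d.min()
    return out


def overlaps_any(
    queries: Sequence[Interval], subjects: Sequence[Interval]
) -> np.ndarray:
    """Boolean per query: does it overlap any subject interval?"""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in subjects:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s < ce:
                ce = max(ce, e)
            else:
                starts.append(cs)
                ends.append(ce)
                cs, ce = s, e
        starts.append(cs)
        ends.append(ce)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    out = np.zeros(len(queries), dtype=bool)
    for k, q in enumerate(queries):
        if q.chrom not in merged:
            continue
        starts, ends = merged[q.chrom]
        i = np.searchsorted(ends, q.start, side="right")
        out[k] = i < len(starts) and starts[i] < q.end
    return out


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a TSV of per-group TPM values, genes as the first column."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    if (df.values < 0).any():
        raise ValueError("negative TPM values in expression table")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
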