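"""Depth-of-coverage: turn alignments into per-window read counts.

The quantification follows the standard MFA recipe: keep mapped reads with
mapping quality >= 10, divide the genome into a fixed number of windows
(10,000 by default, ~500 bp each on an E. coli chromosome), and count the
reads whose leftmost mapped coordinate falls in each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

DEFAULT_GRID_N = 10_000
DEFAULT_MIN_MAPQ = 10

CONDITIONS = ("log", "spc", "stationary_control")


class SamParseError(ValueError):
    """An alignment line could not be parsed; message carries the line number."""


@dataclass(frozen=True)
class AlignedRead:
    """One alignment record: 1-based leftmost position, MAPQ, mapped flag."""

    position: int
    mapq: int
    mapped: bool


@dataclass
class CoverageTrack:
    """Per-window read counts on the standard genome grid.

    ``bounds`` has ``grid_n + 1`` entries; window ``i`` is the half-open bp
    interval ``[bounds[i], bounds[i+1])`` and the windows partition
    ``[0, length)``.
    """

    bounds: np.ndarray
    counts: np.ndarray
    condition: str = "log"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bounds) - 1:
            raise ValueError("counts length must equal number of windows")
        if (self.counts < 0).any():
            raise ValueError("negative window count")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @property
    def grid_n(self) -> int:
        return len(self.counts)

    @property
    def length(self) -> int:
        return int(self.bounds[-1])

    @property
    def centers(self) -> np.ndarray:
        return (self.bounds[:-1] + self.bounds[1:]) / 2.0

    def same_grid(self, other: "CoverageTrack") -> bool:
        return len(self.bounds) == len(other.bounds) and bool(
            np.array_equal(self.bounds, other.bounds)
        )


def build_grid(length: int, grid_n: int = DEFAULT_GRID_N) -> np.ndarray:
    """Window boundaries: ``grid_n`` contiguous windows covering ``[0, length)``.

    Base width is ``length // grid_n``; the first ``length % grid_n`` windows
    are one bp wider, absorbing the remainder at the start of the grid.
    """
    if not 0 < grid_n <= length:
        raise ValueError(f"grid_n must be in (0, length]; got grid_n={grid_n}, length={length}")
    w, r = divmod(length, grid_n)
    widths = np.full(grid_n, w, dtype=np.int64)
    widths[:r] += 1
    return np.concatenate(([0], np.cumsum(widths)))


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream alignment records from a SAM text file.

    Header lines (starting with '@') are skipped.  Each alignment line must
    have at least the 11 mandatory tab-separated SAM fields; the FLAG 0x4 bit
    marks a read unmapped.  Malformed lines raise :class:`SamParseError`
    naming the offending line number.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SamParseError(
                    f"{path}: line {lineno}: {len(fields)} fields, SAM requires 11"
                )
            try:
                flag = int(fields[1])
                pos = int(fields[3])
                mapq = int(fields[4])
            except ValueError as exc:
                raise SamParseError(f"{path}: line {lineno}: non-integer FLAG/POS/MAPQ") from exc
            yield AlignedRead(position=pos, mapq=mapq, mapped=not flag & 0x4)


def filter_mapq(
    reads: Iterable[AlignedRead], min_mapq: int = DEFAULT_MIN_MAPQ
) -> Iterator[AlignedRead]:
    """Keep mapped reads with mapping quality >= ``min_mapq`` (inclusive)."""
    for read in reads:
        if read.mapped and read.mapq >= min_mapq:
            yield read


def bin_reads(
    reads: Iterable[AlignedRead],
    bounds: np.ndarray,
    condition: str = "log",
    sample_id: str = "",
) -> CoverageTrack:
    """Count reads per window by leftmost mapped coordinate.

    SAM positions are 1-based; the read at POS p lands in the window holding
    0-based coordinate p - 1.  A position at or past the chromosome end is an
    error (alignments never wrap the origin in this representation).  The
    total of the counts equals the number of input reads.
    """
    bounds = np.asarray(bounds, dtype=np.int64)
    length = int(bounds[-1])
    positions = np.fromiter((r.position - 1 for r in reads), dtype=np.int64)
    if positions.size and (positions.min() < 0 or positions.max() >= length):
        bad = positions[(positions < 0) | (positions >= length)][0]
        raise ValueError(f"read position {bad + 1} (1-based) outside chromosome [1, {length}]")
    idx = np.searchsorted(bounds, positions, side="right") - 1
    counts = np.bincount(idx, minlength=len(bounds) - 1)
    return CoverageTrack(bounds=bounds, counts=counts, condition=condition, sample_id=sample_id)


def coverage_from_sam(
    path: str | Path,
    length: int,
    grid_n: int = DEFAULT_GRID_N,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    condition: str = "log",
    sample_id: str = "",
) -> CoverageTrack:
    """read_sam -> filter_mapq -> bin_reads, the full depth computation."""
    bounds = build_grid(length, grid_n)
    return bin_reads(
        filter_mapq(read_sam(path), min_mapq), bounds, condition=condition, sample_id=sample_id
    )


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

def write_track_tsv(track: CoverageTrack, path: str | Path) -> None:
    """Write window counts as TSV: window_start, window_end, count."""
    with open(path, "w") as fh:
        fh.write("window_start\twindow_end\tcount\n")
        for start, end, count in zip(track.bounds[:-1], track.bounds[1:], track.counts):
            fh.write(f"{start}\t{end}\t{count}\n")


def read_track_tsv(
    path: str | Path, condition: str = "log", sample_id: str = ""
) -> CoverageTrack:
    """Read a pre-binned count table written by :func:`write_track_tsv`."""
    starts: list[int] = []
    ends: list[int] = []
    counts: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "window_start")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            starts.append(int(parts[0]))
            ends.append(int(parts[1]))
            counts.append(int(parts[2]))
    bounds = np.array(starts + [ends[-1]], dtype=np.int64)
    if not np.array_equal(bounds[1:-1], np.array(ends[:-1])):
        raise ValueError(f"{path}: windows are not contiguous")
    return CoverageTrack(
        bounds=bounds, counts=np.array(counts), condition=condition, sample_id=sample_id
    )


def write_bedgraph(
    track: CoverageTrack, path: str | Path, chrom_name: str = "chromosome"
) -> None:
    """Write counts as bedGraph (0-based, half-open intervals)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample_id or "coverage"}"\n')
        for start, end, count in zip(track.bounds[:-1], track.bounds[1:], track.counts):
            fh.write(f"{chrom_name}\t{start}\t{end}\t{count}\n")
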