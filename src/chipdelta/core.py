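"""Genomic interval and coverage primitives.

All coordinates are 0-based, half-open (BED convention). Intervals are
``[start, end)``; abutting intervals do not overlap. Coverage is stored on a
fixed bin grid per chromosome; a bin value is the mean per-base fragment depth
over the bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

RAW_COUNT = "raw_count"
RPKM = "RPKM"


class ParseError(ValueError):
    """Raised when an on-disk record violates its format contract."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_overlap`` bases."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    return a.overlap_length(b) >= min_overlap


@dataclass(frozen=True)
class Peak:
    """A called enrichment peak with its summit and calling evidence."""

    interval: GenomicInterval
    summit_offset: int
    score: float
    p_value: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < self.interval.length):
            raise ValueError(
                f"summit offset {self.summit_offset} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit(self) -> int:
        """Absolute summit position."""
        return self.interval.start + self.summit_offset


def summit_window(
    peak: Peak,
    flank: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Fixed-width window ``[summit - flank, summit + flank)`` clipped to bounds."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    s = peak.summit
    start = max(0, s - flank)
    end = s + flank
    if chrom_sizes is not None:
        size = chrom_sizes.get(peak.chrom)
        if size is not None:
            end = min(end, size)
    return GenomicInterval(peak.chrom, start, end)


@dataclass
class CoverageTrack:
    """Binned per-chromosome signal on a fixed grid.

    ``values[chrom]`` has ``ceil(chrom_length / bin_width)`` entries; the last
    bin may cover fewer than ``bin_width`` bases.
    """

    bin_width: int
    values: dict[str, np.ndarray]
    normalization: str = RAW_COUNT
    total_mapped: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.normalization not in (RAW_COUNT, RPKM):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for chrom, v in self.values.items():
            if np.any(v < 0):
                raise ValueError(f"negative coverage on {chrom}")

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def _bin_length(self, chrom: str, bin_index: int) -> int:
        size = self.chrom_sizes.get(chrom)
        start = bin_index * self.bin_width
        if size is None:
            return self.bin_width
        return min(self.bin_width, size - start)


def coverage_from_fragments(
    fragments: Iterable[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_width: int = 100,
) -> CoverageTrack:
    """Binned mean per-base fragment depth.

    Additive over fragment lists: the track of a concatenation is the sum of
    the tracks.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # per-base depth via difference arrays, then bin means
    by_chrom: dict[str, tuple[list[int], list[int]]] = {
        c: ([], []) for c in chrom_sizes
    }
    n = 0
    for frag in fragments:
        entry = by_chrom.get(frag.chrom)
        if entry is None:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom!r}")
        entry[0].append(frag.start)
        entry[1].append(frag.end)
        n += 1
    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        starts_list, ends_list = by_chrom[chrom]
        starts_arr = np.asarray(starts_list, dtype=np.int64)
        ends_arr = np.asarray(ends_list, dtype=np.int64)
        if len(starts_arr) and (starts_arr.min() < 0 or ends_arr.max() > size):
            raise ValueError(
                f"fragment outside chromosome {chrom!r} of length {size}"
            )
        diff = np.zeros(size + 1)
        np.add.at(diff, starts_arr, 1.0)
        np.add.at(diff, ends_arr, -1.0)
        depth = np.cumsum(diff[:-1])
        n_bins = -(-size // bin_width)
        bin_starts = np.arange(n_bins) * bin_width
        sums = np.add.reduceat(depth, bin_starts)
        lengths = np.minimum(bin_width, size - bin_starts)
        values[chrom] = sums / lengths
    return CoverageTrack(
        bin_width=bin_width,
        values=values,
        normalization=RAW_COUNT,
        total_mapped=n,
        chrom_sizes=dict(chrom_sizes),
    )


def rpkm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale each bin by ``(1000 / bin_width) * (1e6 / total_mapped)``."""
    if track.normalization != RAW_COUNT:
        raise ValueError("track is already normalized")
    if track.total_mapped <= 0:
        raise ValueError("total_mapped must be > 0 for RPKM normalization")
    scale = (1000.0 / track.bin_width) * (1e6 / track.total_mapped)
    return replace(
        track,
        values={c: v * scale for c, v in track.values.items()},
        normalization=RPKM,
    )


def mean_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean of bin values over ``interval``.

    Bins beyond the stored grid contribute zero signal but full length, so a
    window hanging off the chromosome end is zero-padded.
    """
    if interval.end <= interval.start:
        raise ValueError("zero-length interval")
    if interval.chrom not in track.values:
        raise ValueError(f"chromosome {interval.chrom!r} absent from track")
    v = track.values[interval.chrom]
    bw = track.bin_width
    b0 = interval.start // bw
    b1 = (interval.end - 1) // bw
    total = 0.0
    for b in range(b0, min(b1, len(v) - 1) + 1):
        lo = max(interval.start, b * bw)
        hi = min(interval.end, (b + 1) * bw)
        total += v[b] * (hi - lo)
    return total / interval.length


# ---------------------------------------------------------------------------
# Standard-format I/O (BED3+, narrowPeak, BedGraph, chrom.sizes)
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = ("#", "track", "browser")


def _data_lines(path: str):
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_HEADER_PREFIXES):
                continue
            yield i, line


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for i, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError("expected 'name<TAB>length'", path, i)
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"bad chromosome length {fields[1]!r}", path, i) from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3+ intervals, preserving file order."""
    out: list[GenomicInterval] = []
    for i, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"expected >= 3 columns, got {len(fields)}", path, i)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates in {line!r}", path, i) from exc
        try:
            out.append(GenomicInterval(fields[0], start, end))
        except ValueError as exc:
            raise ParseError(str(exc), path, i) from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(path: str) -> list[Peak]:
    """Read ENCODE narrowPeak (BED6+4).

    Column 7 carries the float score, column 8 the -log10 p-value and column
    10 the summit offset. A summit of -1 is mapped to the interval midpoint
    with a logged warning.
    """
    peaks: list[Peak] = []
    for i, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 10:
            raise ParseError(f"expected 10 columns, got {len(fields)}", path, i)
        chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
        try:
            interval = GenomicInterval(chrom, int(start), int(end))
            score = float(fields[6])
            neglog_p = float(fields[7])
            summit = int(fields[9])
        except ValueError as exc:
            raise ParseError(str(exc), path, i) from exc
        if summit == -1:
            summit = interval.length // 2
            logger.warning(
                "%s:%d: summit -1, falling back to interval midpoint", path, i
            )
        if not (0 <= summit < interval.length):
            raise ParseError(
                f"summit offset {summit} outside {interval.length} bp interval",
                path,
                i,
            )
        p_value = 10.0 ** (-neglog_p)
        peaks.append(
            Peak(interval, summit, score, min(p_value, 1.0), name=name)
        )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for k, p in enumerate(peaks):
            name = p.name or f"peak_{k + 1}"
            display = min(1000, max(0, int(round(p.score * 10))))
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        name,
                        str(display),
                        ".",
                        f"{p.score:.17g}",
                        f"{-math.log10(p.p_value):.17g}",
                        "-1",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


def read_bedgraph(
    path: str,
    bin_width: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Resample BedGraph records onto a fixed bin grid.

    Records must be sorted and non-overlapping per chromosome. Each bin gets
    the length-weighted mean of record values over the bin (uncovered bases
    count as zero).
    """
    sums: dict[str, dict[int, float]] = {}
    max_end: dict[str, int] = {}
    last_end: dict[str, int] = {}
    for i, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"expected 4 columns, got {len(fields)}", path, i)
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(str(exc), path, i) from exc
        if start >= end:
            raise ParseError(f"empty or inverted record {start}-{end}", path, i)
        if start < last_end.get(chrom, 0):
            raise ParseError(
                f"overlapping or unsorted record at {chrom}:{start}", path, i
            )
        last_end[chrom] = end
        max_end[chrom] = max(max_end.get(chrom, 0), end)
        acc = sums.setdefault(chrom, {})
        b0, b1 = start // bin_width, (end - 1) // bin_width
        for b in range(b0, b1 + 1):
            lo = max(start, b * bin_width)
            hi = min(end, (b + 1) * bin_width)
            acc[b] = acc.get(b, 0.0) + value * (hi - lo)
    if chrom_sizes:
        sizes = dict(chrom_sizes)
    else:
        # unknown chromosome lengths: round up to whole bins
        sizes = {c: -(-e // bin_width) * bin_width for c, e in max_end.items()}
    values: dict[str, np.ndarray] = {}
    for chrom, size in sizes.items():
        n_bins = -(-size // bin_width)
        arr = np.zeros(n_bins)
        starts = np.arange(n_bins) * bin_width
        lengths = np.minimum(bin_width, size - starts)
        for b, s in sums.get(chrom, {}).items():
            if b < n_bins:
                arr[b] = s / lengths[b]
        values[chrom] = arr
    return CoverageTrack(
        bin_width=bin_width, values=values, normalization=RAW_COUNT,
        chrom_sizes=sizes,
    )


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Emit run-length-merged BedGraph records (zero runs included)."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.values:
            v = track.values[chrom]
            size = track.chrom_sizes.get(chrom, len(v) * bw)
            i = 0
            while i < len(v):
                j = i + 1
                while j < len(v) and v[j] == v[i]:
                    j += 1
                start = i * bw
                end = min(j * bw, size)
                fh.write(f"{chrom}\t{start}\t{end}\t{v[i]:.17g}\n")
                i = j
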