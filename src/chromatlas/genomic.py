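"""Interval arithmetic, genome layout, and readers/writers for BED/bedGraph.

Coordinates are 0-based half-open throughout (BED convention).  Sorting
order is chromosome by layout order, then start, then end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An interval or track violates a structural invariant."""


class ParseError(ValueError):
    """A text input line could not be parsed."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("names and lengths differ in count")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(lengths.values()))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    @classmethod
    def read(cls, path) -> "GenomeLayout":
        """Read a two-column TSV (chrom, length)."""
        names, lengths = [], []
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected 2 columns")
            names.append(parts[0])
            lengths.append(int(parts[1]))
        return cls(tuple(names), tuple(lengths))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for n, l in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{n}\t{l}\n")


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A 0-based half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def sort_intervals(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout | None = None
) -> list[GenomicInterval]:
    """Sort by chromosome (layout order when given, else lexicographic),
    then start, then end."""
    if layout is not None:
        order = {c: i for i, c in enumerate(layout.chrom_names)}
        key = lambda iv: (order[iv.chrom], iv.start, iv.end)
    else:
        key = lambda iv: (iv.chrom, iv.start, iv.end)
    return sorted(intervals, key=key)


def validate_intervals(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout
) -> None:
    for iv in intervals:
        if iv.end > layout.length_of(iv.chrom):
            raise ValidationError(
                f"{iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length"
            )


# ---------------------------------------------------------------------------
# BED / bedGraph I/O


def read_bed(path, layout: GenomeLayout | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6.  Intervals running past a chromosome edge are clipped
    with a logged warning; start >= end is an error."""
    out: list[GenomicInterval] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{i}: expected >=3 tab-separated columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
        if start >= end:
            raise ValidationError(f"{path}:{i}: start >= end")
        if layout is not None:
            clen = layout.length_of(chrom)
            if end > clen or start < 0:
                logger.warning("%s:%d: clipping %s:%d-%d to chromosome",
                               path, i, chrom, start, end)
                start, end = max(start, 0), min(end, clen)
                if start >= end:
                    continue
        name = parts[3] if len(parts) > 3 and parts[3] != "" else None
        score = None
        if len(parts) > 4 and parts[4] not in ("", "."):
            score = float(parts[4])
        strand = parts[5] if len(parts) > 5 and parts[5] != "" else None
        out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write BED; emits 6 columns when any interval carries name/score/strand,
    otherwise BED3."""
    six = any(iv.name is not None or iv.score is not None or iv.strand is not None
              for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{iv.name or '.'}\t{score}\t{iv.strand or '.'}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


class ScoredTrack:
    """Per-chromosome sorted, non-overlapping (interval, value) pairs —
    the carrier for bedGraph coverage and conservation scores."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # data: chrom -> (starts, ends, values), each a 1-D array
        for chrom, (s, e, v) in data.items():
            if not (len(s) == len(e) == len(v)):
                raise ValidationError(f"{chrom}: ragged track arrays")
            if np.any(s[1:] < e[:-1]):
                raise ValidationError(f"{chrom}: overlapping/unsorted segments")
            if np.any(s >= e):
                raise ValidationError(f"{chrom}: empty segment")
        self.data = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64),
                np.asarray(v, dtype=float))
            for c, (s, e, v) in data.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    @classmethod
    def read_bedgraph(cls, path) -> "ScoredTrack":
        rows: dict[str, list[tuple[int, int, float]]] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{i}: expected 4 columns")
            rows.setdefault(parts[0], []).append(
                (int(parts[1]), int(parts[2]), float(parts[3]))
            )
        data = {}
        for chrom, segs in rows.items():
            segs.sort()
            s, e, v = (np.array(x) for x in zip(*segs))
            data[chrom] = (s, e, v)
        return cls(data)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (s, e, v) in self.data.items():
                for a, b, x in zip(s, e, v):
                    fh.write(f"{chrom}\t{a}\t{b}\t{x:g}\n")

    def mean_over(self, interval: GenomicInterval) -> float:
        """Mean value over covered bases within the interval (uncovered
        bases are absent from the average); NaN when nothing is covered."""
        if interval.chrom not in self.data:
            return float("nan")
        s, e, v = self.data[interval.chrom]
        lo = np.searchsorted(e, interval.start, side="right")
        hi = np.searchsorted(s, interval.end, side="left")
        if lo >= hi:
            return float("nan")
        ov = np.minimum(e[lo:hi], interval.end) - np.maximum(s[lo:hi], interval.start)
        ov = np.clip(ov, 0, None)
        tot = ov.sum()
        if tot == 0:
            return float("nan")
        return float((v[lo:hi] * ov).sum() / tot)


# ---------------------------------------------------------------------------
# Interval operations


class _IndexedSet:
    """Subject intervals merged per chromosome for O(log n) any-overlap
    queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            merged = _merge_sorted(sorted((iv.start, iv.end) for iv in ivs),
                                   touching=False)
            s = np.array([m[0] for m in merged], dtype=np.int64)
            e = np.array([m[1] for m in merged], dtype=np.int64)
            self.by_chrom[chrom] = (s, e)

    def overlaps(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self.by_chrom:
            return False
        s, e = self.by_chrom[iv.chrom]
        k = np.searchsorted(s, iv.end, side="left")  # candidates with start < end
        return k > 0 and e[k - 1] > iv.start


def intersect_any(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    layout: GenomeLayout | None = None,
) -> np.ndarray:
    """True per query interval iff it shares >=1 bp with any subject."""
    if layout is not None:
        validate_intervals(query, layout)
        validate_intervals(subject, layout)
    idx = _IndexedSet(subject)
    return np.array([idx.overlaps(q) for q in query], dtype=bool)


def _merge_sorted(pairs: list[tuple[int, int]], touching: bool = True):
    out: list[list[int]] = []
    for s, e in pairs:
        if out and (s < out[-1][1] or (touching and s == out[-1][1])):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def merge_intervals(
    intervals: Sequence[GenomicInterval], layout: GenomeLayout | None = None
) -> list[GenomicInterval]:
    """Union of covered bases, re-segmented into sorted disjoint intervals.
    Touching intervals (end == start) are merged."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    chroms = (
        [c for c in layout.chrom_names if c in by_chrom]
        if layout is not None
        else sorted(by_chrom)
    )
    out = []
    for chrom in chroms:
        for s, e in _merge_sorted(sorted(by_chrom[chrom])):
            out.append(GenomicInterval(chrom, s, e))
    return out


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    layout: GenomeLayout,
    seed: int | np.random.Generator,
) -> list[GenomicInterval]:
    """Random re-placement preserving the multiset of lengths; each interval
    lands uniformly over all valid positions genome-wide."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.array(layout.chrom_lengths, dtype=np.int64)
    out = []
    for iv in intervals:
        n = len(iv)
        valid = np.clip(lengths - n + 1, 0, None)
        total = valid.sum()
        if total <= 0:
            raise ValidationError(
                f"interval of length {n} exceeds every chromosome"
            )
        pos = int(rng.integers(total))
        ci = int(np.searchsorted(np.cumsum(valid), pos, side="right"))
        start = pos - int(np.cumsum(valid)[ci - 1]) if ci > 0 else pos
        out.append(GenomicInterval(layout.chrom_names[ci], start, start + n,
                                   name=iv.name))
    return out


def closest_tss_distance(
    interval: GenomicInterval, positions: np.ndarray
) -> tuple[int, int]:
    """Index of the nearest position (point annotation) and its distance
    to the interval: 0 when the point lies inside [start, end), otherwise
    the signed gap magnitude (start - p for upstream, p - end for
    downstream).  Ties go to the smaller coordinate."""
    positions = np.asarray(positions)
    d = np.where(
        (positions >= interval.start) & (positions < interval.end),
        0,
        np.where(positions < interval.start,
                 interval.start - positions, positions - interval.end),
    )
    i = int(np.argmin(d))  # argmin takes the first (smaller coordinate) on ties
    return i, int(d[i])
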