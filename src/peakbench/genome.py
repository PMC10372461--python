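"""Genomic interval algebra on BED-style half-open coordinates.

All coordinates are 0-based half-open (start inclusive, end exclusive),
matching the BED convention. Chromosome names are matched by exact string
equality; the :class:`GenomeLayout` read from a chrom.sizes file fixes the
canonical chromosome order used for sorting and all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomeLayout",
    "Interval",
    "PeakSet",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "merge_adjacent",
    "complement",
    "intersect_fraction",
]

DEFAULT_MERGE_GAP = 150
DEFAULT_MIN_FRACTION = 0.20


class IntervalError(ValueError):
    """Raised on malformed coordinates, files, or contract violations."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate universe.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs in canonical order.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise IntervalError("no chromosomes")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise IntervalError(f"duplicate chromosome name: {dup!r}")
        for name, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise IntervalError(
                    f"chromosome {name!r}: length must be a positive integer, got {length!r}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: int(length) for name, length in self.chromosomes}

    @property
    def total_size(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def rank(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise IntervalError(f"unknown chromosome: {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"negative start: {self}")
        if self.start >= self.end:
            raise IntervalError(f"start >= end: {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """A sorted collection of intervals for one condition.

    Intervals are ordered by (chromosome rank, start, end). The chromosome
    order is the one seen at construction (layout order when a layout is
    supplied). A PeakSet may contain overlapping intervals until normalized
    with :func:`merge_adjacent`.
    """

    intervals: list[Interval]
    label: str = ""
    sorted: bool = False
    chrom_order: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[Interval],
        label: str = "",
        layout: GenomeLayout | None = None,
    ) -> "PeakSet":
        """Build a sorted PeakSet, validating against *layout* when given."""
        ivs = list(intervals)
        if layout is not None:
            lengths = layout.lengths
            for iv in ivs:
                if iv.chrom not in lengths:
                    raise IntervalError(f"unknown chromosome: {iv.chrom!r}")
                if iv.end > lengths[iv.chrom]:
                    raise IntervalError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {lengths[iv.chrom]}"
                    )
            order = layout.names
        else:
            order = tuple(dict.fromkeys(iv.chrom for iv in ivs))
        rank = {name: i for i, name in enumerate(order)}
        ivs.sort(key=lambda iv: (rank.get(iv.chrom, len(rank)), iv.start, iv.end))
        return cls(intervals=ivs, label=label, sorted=True, chrom_order=order)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals and self.label == other.label

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Group into per-chromosome (starts, ends) int64 arrays."""
        out: dict[str, list[list[int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, [[], []])
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        return {
            chrom: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for chrom, (s, e) in out.items()
        }

    def _require_sorted(self, op: str) -> None:
        if not self.sorted:
            raise IntervalError(f"{op}: input PeakSet is not sorted")
        seen: dict[str, int] = {}
        prev_chrom = None
        prev_key = (-1, -1)
        for iv in self.intervals:
            if iv.chrom != prev_chrom:
                if iv.chrom in seen:
                    raise IntervalError(f"{op}: chromosomes not contiguous ({iv.chrom})")
                seen[iv.chrom] = 1
                prev_chrom = iv.chrom
                prev_key = (-1, -1)
            if (iv.start, iv.end) < prev_key:
                raise IntervalError(f"{op}: intervals out of order at {iv}")
            prev_key = (iv.start, iv.end)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a two-column tab-separated chrom.sizes file, preserving order."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise IntervalError(f"{path}:{lineno}: expected two tab-separated columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise IntervalError(
                    f"{path}:{lineno}: length is not an integer: {parts[1]!r}"
                ) from None
            if length <= 0:
                raise IntervalError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise IntervalError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise IntervalError(f"{path}: no chromosomes")
    return GenomeLayout(tuple(chroms))


_SKIP_PREFIXES = ("track", "browser")


def read_bed(path: str | Path, layout: GenomeLayout) -> PeakSet:
    """Read BED3+ into a validated, sorted PeakSet.

    Columns beyond the third are ignored. Comment (``#``), ``track`` and
    ``browser`` lines are skipped. A ``# label=<text>`` comment, if present,
    sets the PeakSet label.
    """
    lengths = layout.lengths
    intervals: list[Interval] = []
    label = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("label="):
                    label = stripped[len("label="):]
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntervalError(f"{path}:{lineno}: expected at least 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise IntervalError(f"{path}:{lineno}: non-integer coordinates") from None
            if chrom not in lengths:
                raise IntervalError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start >= end:
                raise IntervalError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0 or end > lengths[chrom]:
                raise IntervalError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"chromosome {chrom} of length {lengths[chrom]}"
                )
            intervals.append(Interval(chrom, start, end))
    return PeakSet.from_intervals(intervals, label=label, layout=layout)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a sorted PeakSet as BED3 with a ``# label=`` comment header."""
    peaks._require_sorted("write_bed")
    with open(path, "w") as fh:
        fh.write(f"# label={peaks.label}\n")
        for iv in peaks.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_adjacent(peaks: PeakSet, gap: int = DEFAULT_MERGE_GAP) -> PeakSet:
    """Merge intervals separated by at most *gap* uncovered bp.

    Two consecutive intervals on a chromosome merge iff
    ``next.start - prev.end <= gap``; overlapping intervals always merge.
    ``gap=0`` normalizes the set (overlaps and book-ended intervals fuse).
    """
    if gap < 0:
        raise IntervalError(f"merge_adjacent: negative gap {gap}")
    peaks._require_sorted("merge_adjacent")
    merged: list[Interval] = []
    cur: Interval | None = None
    for iv in peaks.intervals:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= gap:
            if iv.end > cur.end:
                cur = Interval(cur.chrom, cur.start, iv.end)
            continue
        if cur is not None:
            merged.append(cur)
        cur = iv
    if cur is not None:
        merged.append(cur)
    return PeakSet(
        intervals=merged,
        label=peaks.label,
        sorted=True,
        chrom_order=peaks.chrom_order,
    )


def complement(peaks: PeakSet, layout: GenomeLayout) -> PeakSet:
    """Maximal intervals of each chromosome not covered by any peak.

    Chromosomes with no peaks contribute one full-length interval. The input
    need not be pre-normalized; it is merged with gap 0 internally.
    """
    peaks._require_sorted("complement")
    norm = merge_adjacent(peaks, gap=0)
    per_chrom: dict[str, list[Interval]] = {}
    for iv in norm.intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for name, length in layout.chromosomes:
        pos = 0
        for iv in per_chrom.get(name, []):
            if iv.end > length:
                raise IntervalError(
                    f"complement: interval {iv} exceeds chromosome length {length}"
                )
            if iv.start > pos:
                out.append(Interval(name, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < length:
            out.append(Interval(name, pos, length))
    label = f"complement({peaks.label})" if peaks.label else "complement"
    return PeakSet(intervals=out, label=label, sorted=True, chrom_order=layout.names)


def _coverage_overlap(
    qs: np.ndarray, qe: np.ndarray, rs: np.ndarray, re_: np.ndarray
) -> np.ndarray:
    """Total bp each query interval shares with a merged reference set."""
    if len(rs) == 0:
        return np.zeros(len(qs), dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(re_ - rs)))
    i0 = np.searchsorted(re_, qs, side="right")
    i1 = np.searchsorted(rs, qe, side="left")
    full = cum[i1] - cum[i0]
    has = i1 > i0
    left = np.zeros(len(qs), dtype=np.int64)
    right = np.zeros(len(qs), dtype=np.int64)
    left[has] = np.maximum(0, qs[has] - rs[i0[has]])
    right[has] = np.maximum(0, re_[i1[has] - 1] - qe[has])
    return np.where(has, full - left - right, 0)


def intersect_fraction(
    query: PeakSet,
    reference: PeakSet,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    reciprocal: bool = False,
) -> tuple[PeakSet, PeakSet]:
    """Split *query* into (hits, misses) by fractional overlap with *reference*.

    A query interval is a hit iff the total bp it shares with the union of
    reference intervals is at least ``min_fraction`` of its own length. Each
    query interval is counted once however many reference intervals it
    touches. With ``reciprocal=True`` a hit additionally requires some single
    reference interval for which the shared bp is at least ``min_fraction``
    of both interval lengths.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise IntervalError(f"min_fraction must be in (0, 1], got {min_fraction}")
    query._require_sorted("intersect_fraction")
    reference._require_sorted("intersect_fraction")
    ref_norm = merge_adjacent(reference, gap=0)
    ref_by = ref_norm.by_chrom()
    raw_ref_by = reference.by_chrom()
    hits: list[Interval] = []
    misses: list[Interval] = []
    q_by = query.by_chrom()
    # vectorized per chromosome; original order restored by a second walk
    hit_flags: dict[str, np.ndarray] = {}
    for chrom, (qs, qe) in q_by.items():
        if chrom not in ref_by:
            hit_flags[chrom] = np.zeros(len(qs), dtype=bool)
            continue
        rs, re_ = ref_by[chrom]
        ov = _coverage_overlap(qs, qe, rs, re_)
        frac_ok = (ov / (qe - qs)) >= min_fraction
        if reciprocal:
            rrs, rre = raw_ref_by[chrom]
            rec_ok = np.zeros(len(qs), dtype=bool)
            i0 = np.searchsorted(rre, qs, side="right")
            i1 = np.searchsorted(rrs, qe, side="left")
            for k in range(len(qs)):
                for j in range(i0[k], i1[k]):
                    pair = min(qe[k], rre[j]) - max(qs[k], rrs[j])
                    if pair <= 0:
                        continue
                    if (pair / (qe[k] - qs[k])) >= min_fraction and (
                        pair / (rre[j] - rrs[j])
                    ) >= min_fraction:
                        rec_ok[k] = True
                        break
            frac_ok = frac_ok & rec_ok
        hit_flags[chrom] = frac_ok
    counters: dict[str, int] = {}
    for iv in query.intervals:
        k = counters.get(iv.chrom, 0)
        counters[iv.chrom] = k + 1
        (hits if hit_flags[iv.chrom][k] else misses).append(iv)
    mk = lambda ivs, tag: PeakSet(
        intervals=ivs,
        label=f"{query.label} {tag}".strip(),
        sorted=True,
        chrom_order=query.chrom_order,
    )
    return mk(hits, "hits"), mk(misses, "misses")
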