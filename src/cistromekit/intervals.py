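"""Genomic interval data model, BED I/O, and peak-set algebra.

Coordinates are 0-based half-open throughout (BED convention). Two intervals
overlap when they share at least one base on the same chromosome; strand is
ignored. A peak that overlaps several partners is counted once (peak-anchored
counting), which is the convention used when a transcription-factor peak set
is partitioned into factor-specific and shared sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "OverlapPartition",
    "DynamicsPartition",
    "BedParseError",
    "read_bed",
    "write_bed",
    "sort_and_validate",
    "intersect_partition",
    "classify_dynamics",
    "merge_intervals",
]

_VALID_STRANDS = frozenset({"+", "-", "."})


class BedParseError(ValueError):
    """Malformed BED record; message carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """One peak/region on a chromosome, 0-based half-open.

    score carries the peak intensity and must be nonnegative.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValueError(f"score must be nonnegative, got {self.score}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Interval midpoint, floor((start+end)/2)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class PeakSet:
    """An ordered (chrom, start, end)-sorted sequence of intervals with a label."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "peaks",
        _presorted: bool = False,
    ) -> None:
        ivs = list(intervals)
        if not _presorted:
            ivs.sort(key=GenomicInterval.key)
        self.intervals: list[GenomicInterval] = ivs
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def relabel(self, label: str) -> "PeakSet":
        ps = PeakSet(self.intervals, label=label, _presorted=True)
        return ps


@dataclass
class OverlapPartition:
    """Partition of two validated peak sets by >=1 bp overlap.

    pair_index maps the index of each common A interval (position within the
    sorted A set) to the indices of the B intervals it overlaps.
    """

    a_unique: PeakSet
    a_common: PeakSet
    b_unique: PeakSet
    b_common: PeakSet
    pair_index: dict[int, list[int]] = field(default_factory=dict)


@dataclass
class DynamicsPartition:
    """Vehicle-anchored lost/shared plus treated-anchored gained peaks."""

    lost: PeakSet
    shared: PeakSet
    gained: PeakSet
    shared_treated: PeakSet


def read_bed(path, label: str | None = None) -> PeakSet:
    """Read a 3-6 column BED file into a validated, sorted PeakSet.

    Missing name/score/strand columns are filled with "." / 0 / ".".
    Raises BedParseError (with the 1-based line number) on malformed
    coordinates or start >= end.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:  # tolerate space-separated input
                cols = line.split()
            if not 3 <= len(cols) <= 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected 3-6 columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate ({exc})"
                ) from None
            name = cols[3] if len(cols) > 3 else "."
            try:
                score = float(cols[4]) if len(cols) > 4 else 0.0
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from None
            strand = cols[5] if len(cols) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(cols[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(intervals, label=label or path.stem)


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED6 (score written as-is)."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def sort_and_validate(peaks: PeakSet) -> PeakSet:
    """Return a sorted PeakSet with duplicate (chrom, start, end) triples removed.

    Duplicates (first occurrence kept) are reported through a warning.
    """
    seen: set[tuple[str, int, int]] = set()
    kept: list[GenomicInterval] = []
    removed = 0
    for iv in sorted(peaks, key=GenomicInterval.key):
        k = iv.key()
        if k in seen:
            removed += 1
            continue
        seen.add(k)
        kept.append(iv)
    if removed:
        warnings.warn(
            f"sort_and_validate: removed {removed} duplicate interval(s) "
            f"from {peaks.label!r}",
            stacklevel=2,
        )
    return PeakSet(kept, label=peaks.label, _presorted=True)


class _ChromIndex:
    """Per-chromosome arrays for overlap queries against a sorted peak set."""

    def __init__(self, peaks: PeakSet) -> None:
        self.index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]] = {}
        for chrom, ivs in peaks.by_chrom().items():
            starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64)
            ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64)
            # positions of these intervals within the full sorted set
            cummax_end = np.maximum.accumulate(ends)
            self.index[chrom] = (starts, ends, cummax_end, ivs)
        # global positions
        pos = {id(iv): i for i, iv in enumerate(peaks)}
        self._pos = pos

    def overlapping(self, iv: GenomicInterval) -> list[int]:
        """Global indices (into the sorted set) of intervals overlapping iv."""
        entry = self.index.get(iv.chrom)
        if entry is None:
            return []
        starts, ends, cummax_end, ivs = entry
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        hits: list[int] = []
        j = hi - 1
        while j >= 0 and cummax_end[j] > iv.start:
            if ends[j] > iv.start:
                hits.append(self._pos[id(ivs[j])])
            j -= 1
        hits.reverse()
        return hits


def intersect_partition(a: PeakSet, b: PeakSet) -> OverlapPartition:
    """Partition peak sets A and B into unique and common (>=1 bp overlap) subsets.

    Counting is peak-anchored: an interval overlapping several partners is a
    single common peak. Output is independent of input ordering because both
    sets are kept in sorted order.
    """
    bidx = _ChromIndex(b)
    a_unique: list[GenomicInterval] = []
    a_common: list[GenomicInterval] = []
    pair_index: dict[int, list[int]] = {}
    b_hit = np.zeros(len(b), dtype=bool)
    for i, iv in enumerate(a):
        hits = bidx.overlapping(iv)
        if hits:
            pair_index[i] = hits
            a_common.append(iv)
            b_hit[hits] = True
        else:
            a_unique.append(iv)
    b_common = [iv for j, iv in enumerate(b) if b_hit[j]]
    b_unique = [iv for j, iv in enumerate(b) if not b_hit[j]]
    return OverlapPartition(
        a_unique=PeakSet(a_unique, f"{a.label}_unique", _presorted=True),
        a_common=PeakSet(a_common, f"{a.label}_common", _presorted=True),
        b_unique=PeakSet(b_unique, f"{b.label}_unique", _presorted=True),
        b_common=PeakSet(b_common, f"{b.label}_common", _presorted=True),
        pair_index=pair_index,
    )


def classify_dynamics(vehicle: PeakSet, treated: PeakSet) -> DynamicsPartition:
    """Split condition-paired peak sets into lost, shared, and gained peaks.

    lost/shared are vehicle-anchored; gained are treated peaks with no vehicle
    overlap. shared_treated are the treated peaks that do overlap vehicle.
    """
    tidx = _ChromIndex(treated)
    lost, shared = [], []
    for iv in vehicle:
        (shared if tidx.overlapping(iv) else lost).append(iv)
    vidx = _ChromIndex(vehicle)
    gained, shared_t = [], []
    for iv in treated:
        (shared_t if vidx.overlapping(iv) else gained).append(iv)
    return DynamicsPartition(
        lost=PeakSet(lost, f"{vehicle.label}_lost", _presorted=True),
        shared=PeakSet(shared, f"{vehicle.label}_shared", _presorted=True),
        gained=PeakSet(gained, f"{treated.label}_gained", _presorted=True),
        shared_treated=PeakSet(shared_t, f"{treated.label}_shared", _presorted=True),
    )


def merge_intervals(peaks: PeakSet, max_gap: int = 0) -> PeakSet:
    """Union intervals whose gap (next.start - prev.end) is <= max_gap.

    Scores are summed over merged constituents; merged interval names encode
    the constituent count as ``<label>_merged_<i>_n<count>``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    cur: list[GenomicInterval] = []

    def _flush() -> None:
        if not cur:
            return
        merged.append(
            GenomicInterval(
                cur[0].chrom,
                cur[0].start,
                max(iv.end for iv in cur),
                f"{peaks.label}_merged_{len(merged)}_n{len(cur)}",
                float(sum(iv.score for iv in cur)),
                ".",
            )
        )

    cur_end = -1
    for iv in peaks:
        if cur and iv.chrom == cur[0].chrom and iv.start - cur_end <= max_gap:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            _flush()
            cur = [iv]
            cur_end = iv.end
    _flush()
    return PeakSet(merged, label=f"{peaks.label}_merged", _presorted=True)
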