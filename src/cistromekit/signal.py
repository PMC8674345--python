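"""Piecewise-constant genome signal tracks (bedGraph), pileups, and region stats.

A SignalTrack stores per-chromosome runs ``(start, end, value)``; uncovered
bases read as 0. Pileup matrices follow the field convention of binning a
fixed flank around peak centers (e.g. +/-2 kb in 50 bp windows) and averaging
the track value per bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "SignalTrack",
    "ProfileMatrix",
    "BedGraphParseError",
    "read_bedgraph",
    "write_bedgraph",
    "profile_matrix",
    "mean_profile",
    "quantify_regions",
]


class BedGraphParseError(ValueError):
    """Malformed bedGraph record; message carries the 1-based line number."""


class SignalTrack:
    """Non-overlapping, sorted constant runs per chromosome.

    Parameters
    ----------
    runs
        Mapping chrom -> (starts, ends, values) arrays. Runs must be sorted by
        start and non-overlapping; values must be finite.
    resolution
        Optional note recording the sampling resolution the track was built at.
    """

    def __init__(self, runs: dict[str, tuple], resolution: int | None = None) -> None:
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.resolution = resolution
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: run arrays must have equal length")
            if len(starts) == 0:
                continue
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: runs must have start < end")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: runs overlap or are unsorted")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite value in track")
            self.runs[chrom] = (starts, ends, values)
            # cumulative integral up to the start of run i
            self._cum[chrom] = np.concatenate(
                ([0.0], np.cumsum((ends - starts) * values))
            )

    def chroms(self) -> list[str]:
        return list(self.runs)

    def coverage_end(self, chrom: str) -> int:
        """Last covered coordinate on chrom (0 when chrom absent)."""
        if chrom not in self.runs:
            return 0
        return int(self.runs[chrom][1][-1])

    def _antiderivative(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the track over (-inf, x) for an array of positions."""
        starts, ends, values = self.runs[chrom]
        cum = self._cum[chrom]
        j = np.searchsorted(starts, x, side="right") - 1
        jc = np.clip(j, 0, len(starts) - 1)
        inside = np.clip(x - starts[jc], 0, ends[jc] - starts[jc])
        return np.where(j >= 0, cum[jc] + values[jc] * inside, 0.0)

    def integral(self, chrom: str, start, end) -> np.ndarray | float:
        """Sum of per-base values over [start, end); vectorized over arrays."""
        scalar = np.isscalar(start) and np.isscalar(end)
        s = np.atleast_1d(np.asarray(start, dtype=np.float64))
        e = np.atleast_1d(np.asarray(end, dtype=np.float64))
        if chrom not in self.runs:
            out = np.zeros_like(s)
        else:
            out = self._antiderivative(chrom, e) - self._antiderivative(chrom, s)
        return float(out[0]) if scalar else out

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty region")
        return float(self.integral(chrom, start, end)) / (end - start)

    def value_at(self, chrom: str, pos: int) -> float:
        """Track value at a single base (0 outside any run)."""
        if chrom not in self.runs:
            return 0.0
        starts, ends, values = self.runs[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j < 0 or pos >= ends[j]:
            return 0.0
        return float(values[j])

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.runs.items()},
            resolution=self.resolution,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack) or set(self.runs) != set(other.runs):
            return False
        for c in self.runs:
            s1, e1, v1 = self.runs[c]
            s2, e2, v2 = other.runs[c]
            if not (
                np.array_equal(s1, s2)
                and np.array_equal(e1, e2)
                and np.array_equal(v1, v2)
            ):
                return False
        return True


def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack.

    Overlapping runs and non-numeric values are rejected with the offending
    1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            float_precision="round_trip",
        )
    except Exception as exc:
        raise BedGraphParseError(f"{path}: cannot parse ({exc})") from None
    for col in ("start", "end", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise BedGraphParseError(f"{path}:{lineno}: non-numeric {col}")
        df[col] = pd.to_numeric(df[col])
    if (df["end"] <= df["start"]).any():
        lineno = int((df["end"] <= df["start"]).idxmax()) + 1
        raise BedGraphParseError(f"{path}:{lineno}: start >= end")
    runs = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="mergesort")
        overlap = grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]
        if overlap.any():
            lineno = int(grp.index[1:][overlap][0]) + 1
            raise BedGraphParseError(f"{path}:{lineno}: overlapping runs on {chrom}")
        runs[chrom] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["value"].to_numpy(np.float64),
        )
    return SignalTrack(runs)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a SignalTrack as bedGraph.

    Values use shortest round-trip float formatting so read_bedgraph
    reproduces them bit-exactly.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, values = track.runs[chrom]
            fh.write(
                "".join(
                    f"{chrom}\t{s}\t{e}\t{v!r}\n"
                    for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist())
                )
            )


@dataclass
class ProfileMatrix:
    """Per-peak binned signal around peak centers.

    values has one row per peak and ``2*flank/bin_width`` columns; rows whose
    window is truncated by a chromosome end are flagged in ``truncated``.
    """

    values: np.ndarray
    truncated: np.ndarray
    bin_width: int
    flank: int
    peak_names: list[str]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def profile_matrix(
    peaks: PeakSet,
    track: SignalTrack,
    flank: int = 2000,
    bin_width: int = 50,
    chrom_sizes: dict[str, int] | None = None,
) -> ProfileMatrix:
    """Bin the track in ``bin_width`` windows tiling [center-flank, center+flank).

    Peak center is floor((start+end)/2). Bin value is the mean track value over
    the bin's bases; bins partially (or fully) outside the chromosome average
    over covered bases only and flag the row as truncated.
    """
    if flank <= 0 or bin_width <= 0:
        raise ValueError("flank and bin_width must be positive")
    if (2 * flank) % bin_width != 0:
        raise ValueError("bin_width must divide 2*flank")
    n_bins = 2 * flank // bin_width
    values = np.zeros((len(peaks), n_bins))
    truncated = np.zeros(len(peaks), dtype=bool)
    names = []
    for i, iv in enumerate(peaks):
        names.append(iv.name)
        c = iv.center
        edges = c - flank + bin_width * np.arange(n_bins + 1, dtype=np.int64)
        lo, hi = edges[:-1].astype(float), edges[1:].astype(float)
        size = None if chrom_sizes is None else chrom_sizes.get(iv.chrom)
        clo = np.clip(lo, 0, None)
        chi = np.clip(hi, 0, None)
        if size is not None:
            clo, chi = np.clip(clo, None, size), np.clip(chi, None, size)
        covered = chi - clo
        if covered.min() < bin_width:
            truncated[i] = True
        integ = track.integral(iv.chrom, clo, chi)
        with np.errstate(invalid="ignore"):
            row = np.where(covered > 0, integ / np.where(covered > 0, covered, 1), 0.0)
        values[i] = row
    return ProfileMatrix(values, truncated, bin_width, flank, names)


def mean_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column means over non-truncated rows (the average pileup curve)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty profile matrix")
    keep = ~matrix.truncated
    if not keep.any():
        raise ValueError("all profile rows are truncated; no usable windows")
    return matrix.values[keep].mean(axis=0)


def quantify_regions(
    regions: PeakSet, track: SignalTrack, statistic: str = "mean"
) -> pd.DataFrame:
    """Per-region mean or sum of the track over each region's bases."""
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    rows = []
    for iv in regions:
        total = float(track.integral(iv.chrom, iv.start, iv.end))
        val = total if statistic == "sum" else total / iv.length
        rows.append((iv.name, iv.chrom, iv.start, iv.end, val))
    return pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", statistic]
    )
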