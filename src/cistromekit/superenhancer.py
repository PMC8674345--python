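"""Super-enhancer calling: peak stitching, hockey-stick ranking, fold change.

Enhancer peaks within a stitching distance (default 12.5 kb) are merged into
stitched regions; regions are ranked by total signal and drawn as a
unit-scaled curve (x = rank/m, y = signal/max). The super-enhancer cutoff is
the point where the curve's tangent has slope 1 — for the convex ranked curve
that is the region maximizing (x - y), the deepest point below the diagonal.
Regions with signal strictly above the cutoff signal are flagged super.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, merge_intervals
from .signal import SignalTrack

__all__ = [
    "StitchedRegion",
    "SERanking",
    "stitch_peaks",
    "find_cutoff",
    "rank_enhancers",
    "se_fold_change",
]


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    constituent_count: int
    total_signal: float


@dataclass
class SERanking:
    """Regions ranked by increasing total signal with the tangent cutoff applied."""

    regions: list[StitchedRegion]
    scaled_x: np.ndarray
    scaled_y: np.ndarray
    cutoff_signal: float
    cutoff_index: int  # position in the ascending ranking (-1 when degenerate)
    is_super: np.ndarray

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.interval.name for r in self.regions],
                "chrom": [r.interval.chrom for r in self.regions],
                "start": [r.interval.start for r in self.regions],
                "end": [r.interval.end for r in self.regions],
                "constituent_count": [r.constituent_count for r in self.regions],
                "total_signal": [r.total_signal for r in self.regions],
                "scaled_x": self.scaled_x,
                "scaled_y": self.scaled_y,
                "is_super": self.is_super,
            }
        )


def stitch_peaks(
    peaks: PeakSet,
    stitch_distance: int = 12_500,
    tss_table: pd.DataFrame | None = None,
    tss_exclusion: int = 2_500,
) -> list[StitchedRegion]:
    """Merge peaks whose gap is <= stitch_distance into stitched regions.

    When a TSS table is given, peaks lying fully within +/- tss_exclusion of
    any TSS are removed before stitching (promoter-proximal exclusion).
    total_signal is initialized from the summed constituent peak scores;
    rank_enhancers re-quantifies it from a signal track.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    retained = peaks
    if tss_table is not None:
        tss_by_chrom: dict[str, np.ndarray] = {
            chrom: np.sort(grp["tss"].to_numpy(np.int64))
            for chrom, grp in tss_table.groupby("chrom")
        }

        def _promoter_proximal(iv: GenomicInterval) -> bool:
            tss = tss_by_chrom.get(iv.chrom)
            if tss is None:
                return False
            j = int(np.searchsorted(tss, iv.start))
            for t in tss[max(0, j - 1) : j + 2]:
                if iv.start >= t - tss_exclusion and iv.end <= t + tss_exclusion:
                    return True
            return False

        retained = PeakSet(
            [iv for iv in peaks if not _promoter_proximal(iv)],
            label=peaks.label,
            _presorted=True,
        )
    merged = merge_intervals(retained, max_gap=stitch_distance)
    regions: list[StitchedRegion] = []
    for iv in merged:
        count = int(iv.name.rsplit("_n", 1)[-1])
        regions.append(StitchedRegion(iv, count, float(iv.score)))
    return regions


def find_cutoff(signals: np.ndarray) -> tuple[int, float, np.ndarray, np.ndarray, np.ndarray]:
    """Slope-1 tangent cutoff on the ascending unit-scaled signal curve.

    Returns (cutoff_index, cutoff_signal, scaled_x, scaled_y, is_super) for
    signals already sorted ascending. With all signals equal the scaled curve
    degenerates and no region is flagged.
    """
    signals = np.asarray(signals, dtype=np.float64)
    m = len(signals)
    if m < 2:
        raise ValueError("need at least 2 regions to rank")
    if np.any(np.diff(signals) < 0):
        raise ValueError("signals must be sorted ascending")
    x = np.arange(1, m + 1) / m
    smax = signals[-1]
    if signals[0] == smax:
        warnings.warn(
            "all region signals equal; scaled curve is degenerate, "
            "zero super-enhancers called",
            stacklevel=2,
        )
        y = np.ones(m) if smax > 0 else np.zeros(m)
        return -1, float(smax), x, y, np.zeros(m, dtype=bool)
    y = signals / smax
    cutoff_index = int(np.argmax(x - y))
    cutoff_signal = float(signals[cutoff_index])
    return cutoff_index, cutoff_signal, x, y, signals > cutoff_signal


def rank_enhancers(
    stitched: list[StitchedRegion],
    track: SignalTrack,
    control_track: SignalTrack | None = None,
    control_scale: float = 1.0,
) -> SERanking:
    """Rank stitched regions by total track signal and call super-enhancers.

    total_signal is the sum of track values over each region (optionally
    subtracting a scaled control track, floored at 0). Regions are sorted by
    increasing signal (coordinate tie-break) before the tangent cutoff.
    """
    if len(stitched) < 2:
        raise ValueError("need at least 2 stitched regions")
    quantified: list[StitchedRegion] = []
    for r in stitched:
        iv = r.interval
        sig = float(track.integral(iv.chrom, iv.start, iv.end))
        if control_track is not None:
            sig = max(
                0.0,
                sig
                - control_scale
                * float(control_track.integral(iv.chrom, iv.start, iv.end)),
            )
        quantified.append(StitchedRegion(iv, r.constituent_count, sig))
    quantified.sort(key=lambda r: (r.total_signal, r.interval.key()))
    signals = np.array([r.total_signal for r in quantified])
    cutoff_index, cutoff_signal, x, y, is_super = find_cutoff(signals)
    return SERanking(
        regions=quantified,
        scaled_x=x,
        scaled_y=y,
        cutoff_signal=cutoff_signal,
        cutoff_index=cutoff_index,
        is_super=is_super,
    )


def se_fold_change(
    se,
    track_a: SignalTrack,
    track_b: SignalTrack,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-region log2((signal_b + pc) / (signal_a + pc)) between two tracks.

    ``se`` may be an SERanking or a list of StitchedRegion. Regions on
    chromosomes absent from a track are quantified as zero signal with a
    warning.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    regions = se.regions if isinstance(se, SERanking) else list(se)
    missing = set()
    rows = []
    for r in regions:
        iv = r.interval
        for t in (track_a, track_b):
            if iv.chrom not in t.runs:
                missing.add(iv.chrom)
        sa = float(track_a.integral(iv.chrom, iv.start, iv.end))
        sb = float(track_b.integral(iv.chrom, iv.start, iv.end))
        rows.append(
            (
                iv.name,
                iv.chrom,
                iv.start,
                iv.end,
                sa,
                sb,
                float(np.log2((sb + pseudocount) / (sa + pseudocount))),
            )
        )
    if missing:
        warnings.warn(
            f"regions on chromosomes outside track extent treated as zero signal: "
            f"{sorted(missing)}",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["name", "chrom", "start", "end", "signal_a", "signal_b", "log2fc"],
    )
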