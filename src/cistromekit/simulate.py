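"""Seeded synthetic dataset generator with planted ground truth.

The generator emulates the data regime of a two-factor cistrome study: factor
A (an androgen-receptor-like factor whose binding is condition-stable here)
and factor B (a MYC-like factor that loses sites and intensity on treatment),
plus an acetylation-like signal track concentrated at peaks and gene
expression fold changes statistically coupled to each gene's binding class.

Construction guarantees, not sampling accidents:

* exactly ``round(rho * n_peaks_b)`` B peaks each overlap a distinct A peak;
* peaks are either fully inside a gene's +/-10 kb TSS window or kept well
  clear of every window, so occupancy classes have an exact planted truth;
* shared treated B peaks carry exactly ``delta`` times their vehicle
  intensity;
* every stochastic step consumes a named substream of the single seed, so
  adding a stage never perturbs earlier draws, and identical (config, seed)
  reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import write_gene_table
from .intervals import GenomicInterval, PeakSet, write_bed
from .signal import SignalTrack, write_bedgraph

__all__ = [
    "SimConfig",
    "SimConfigError",
    "PlacementError",
    "SyntheticCistromes",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_cistromes",
    "simulate_tracks",
    "simulate_expression",
    "generate_dataset",
    "write_dataset",
    "load_manifest_config",
    "bump_track",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """Peak placement collision budget exhausted."""


# named substreams: adding a stage never perturbs earlier draws
_STREAMS = {
    "genome": 0,
    "cistromes": 1,
    "tracks": 2,
    "expression": 3,
    "samples": 4,
}


@dataclass
class SimConfig:
    """Planted parameters of the synthetic dataset.

    Defaults are the study regime the package is exercised in: a ~25% B-peak
    co-binding fraction, treatment that removes the weakest 59% of B sites and
    gains 14% new low-intensity sites, halved treated B intensity, and unit
    log2 expression effects for A-bound (up) and B-only-bound (down) genes.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 7_500_000
    n_genes: int = 500
    n_peaks_a: int = 800
    n_peaks_b: int = 600
    co_binding_fraction: float = 0.25  # rho
    peak_width_log_mean: float = math.log(500.0)
    peak_width_log_sd: float = 0.25
    loss_fraction: float = 0.59  # lambda_lost
    gain_fraction: float = 0.14  # lambda_gain
    treated_intensity_scale: float = 0.5  # delta
    signal_background: float = 0.05
    signal_amplitude_mean: float = 20.0
    signal_amplitude_sd: float = 5.0
    expr_effect_a: float = 1.0
    expr_effect_b: float = 1.0
    expr_noise_sd: float = 0.3
    n_samples: int = 6  # per condition
    signature_size: int = 40
    # geometry knobs
    annotation_window_kb: float = 10.0
    tss_peak_fraction: float = 0.5
    common_ac_boost: float = 3.0
    sample_noise_sd: float = 0.25
    min_peak_width: int = 100
    max_peak_width: int = 2_500
    track_resolution: int = 10
    end_flank: int = 5_000

    def validate(self) -> None:
        c = self
        positives = [
            ("n_chroms", c.n_chroms),
            ("chrom_length", c.chrom_length),
            ("n_peaks_a", c.n_peaks_a),
            ("n_peaks_b", c.n_peaks_b),
            ("n_samples", c.n_samples),
            ("signature_size", c.signature_size),
            ("annotation_window_kb", c.annotation_window_kb),
            ("track_resolution", c.track_resolution),
            ("min_peak_width", c.min_peak_width),
        ]
        for name, v in positives:
            if v <= 0:
                raise SimConfigError(f"{name} must be positive, got {v}")
        if c.n_genes < 0:
            raise SimConfigError("n_genes must be >= 0")
        for name, v in [
            ("co_binding_fraction", c.co_binding_fraction),
            ("loss_fraction", c.loss_fraction),
            ("gain_fraction", c.gain_fraction),
            ("tss_peak_fraction", c.tss_peak_fraction),
        ]:
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < c.treated_intensity_scale <= 1.0:
            raise SimConfigError("treated_intensity_scale must be in (0, 1]")
        if round(c.co_binding_fraction * c.n_peaks_b) > c.n_peaks_a:
            raise SimConfigError(
                "co_binding_fraction * n_peaks_b exceeds n_peaks_a: each "
                "co-bound B peak needs a distinct A partner"
            )
        if c.expr_noise_sd < 0 or c.signal_background < 0:
            raise SimConfigError("noise/background parameters must be >= 0")

    # -- geometry helpers ---------------------------------------------------
    @property
    def window(self) -> int:
        """Half-width of the TSS occupancy window in bases."""
        return int(round(self.annotation_window_kb * 1000))

    @property
    def tss_spacing(self) -> int:
        """Minimum TSS spacing: twice the full +/-window width."""
        return 4 * self.window

    @property
    def genome_margin(self) -> int:
        return self.window + self.end_flank

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_STREAMS[stream],))
        )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.validate()
        return cfg


@dataclass
class SyntheticCistromes:
    a_vehicle: PeakSet
    b_vehicle: PeakSet
    a_treated: PeakSet
    b_treated: PeakSet
    gene_truth: pd.DataFrame  # gene_id, a_bound, b_bound, true_class


@dataclass
class SyntheticDataset:
    config: SimConfig
    genes: pd.DataFrame
    cistromes: SyntheticCistromes
    tracks: dict[str, SignalTrack]
    fold_changes: pd.DataFrame  # gene_id, true_effect, log2fc
    expression: pd.DataFrame  # genes x samples
    signature: list[str]


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> pd.DataFrame:
    """Gene table with uniformly placed, well-separated TSSs.

    TSSs keep a minimum spacing of twice the full occupancy window so gene
    classes are unambiguous, and stay ``window + end_flank`` clear of
    chromosome ends.
    """
    config.validate()
    if config.n_genes == 0:
        return pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"])
    rng = config.rng("genome")
    counts = rng.multinomial(
        config.n_genes, np.full(config.n_chroms, 1.0 / config.n_chroms)
    )
    spacing, margin = config.tss_spacing, config.genome_margin
    rows = []
    for chrom, k in zip(config.chrom_names(), counts):
        if k == 0:
            continue
        usable = config.chrom_length - 2 * margin - (k - 1) * spacing
        if usable < 0:
            raise SimConfigError(
                f"cannot place {k} TSSs on {chrom} ({config.chrom_length} bp) "
                f"with minimum spacing {spacing} bp (twice the full "
                f"+/-{config.window} bp occupancy window); increase "
                "chrom_length or reduce n_genes"
            )
        u = np.sort(rng.uniform(0, usable, size=k))
        tss = (margin + u + spacing * np.arange(k)).astype(np.int64)
        strands = rng.choice(["+", "-"], size=k)
        for t, s in zip(tss, strands):
            rows.append((chrom, int(t), s))
    df = pd.DataFrame(rows, columns=["chrom", "tss", "strand"])
    df.insert(0, "gene_id", [f"gene{i:05d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# cistromes


class _Placer:
    """Tracks placed intervals per chromosome for overlap rejection."""

    def __init__(self) -> None:
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.by_chrom.get(chrom, ()):  # sets are small at desk scale
            if s < end and start < e:
                return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))


def _draw_width(rng: np.random.Generator, config: SimConfig) -> int:
    w = int(round(rng.lognormal(config.peak_width_log_mean, config.peak_width_log_sd)))
    return int(np.clip(w, config.min_peak_width, config.max_peak_width))


def simulate_cistromes(config: SimConfig, genes: pd.DataFrame) -> SyntheticCistromes:
    """Four peak sets with a constructed co-binding fraction and B dynamics.

    Exactly ``round(rho * n_peaks_b)`` B peaks overlap a distinct A peak.
    Peaks targeted at a gene are placed fully inside its TSS window;
    background peaks keep clear of every window, so the planted occupancy
    class of each gene is exact. The treated B set keeps the
    highest-intensity vehicle peaks (intensity scaled by delta) and adds
    low-intensity gained peaks.
    """
    config.validate()
    rng = config.rng("cistromes")
    w = config.window
    inner = w - 2200  # near-TSS centers stay this close so peaks fit the window
    clearance = w + config.max_peak_width  # background centers keep this far
    tss_by_chrom = {
        chrom: np.sort(grp["tss"].to_numpy(np.int64))
        for chrom, grp in genes.groupby("chrom")
    }
    chrom_names = config.chrom_names()
    placer = _Placer()
    budget = [200 * (config.n_peaks_a + config.n_peaks_b)]

    def _spend() -> None:
        budget[0] -= 1
        if budget[0] <= 0:
            raise PlacementError(
                "peak placement collision budget exhausted; "
                "consider longer chromosomes or fewer peaks"
            )

    def _clear_of_windows(chrom: str, center: int) -> bool:
        tss = tss_by_chrom.get(chrom)
        if tss is None or len(tss) == 0:
            return True
        j = int(np.searchsorted(tss, center))
        near = tss[max(0, j - 1) : j + 1]
        return bool(np.all(np.abs(near - center) >= clearance))

    def _place_background(width: int) -> tuple[str, int]:
        while True:
            _spend()
            chrom = chrom_names[int(rng.integers(config.n_chroms))]
            lo = config.end_flank + width
            hi = config.chrom_length - config.end_flank - width
            center = int(rng.integers(lo, hi))
            s, e = center - width // 2, center - width // 2 + width
            if _clear_of_windows(chrom, center) and not placer.collides(chrom, s, e):
                return chrom, center

    def _place_at_gene(gi: int, width: int) -> tuple[str, int]:
        chrom = genes["chrom"].iat[gi]
        tss = int(genes["tss"].iat[gi])
        while True:
            _spend()
            center = int(rng.integers(tss - inner, tss + inner + 1))
            s, e = center - width // 2, center - width // 2 + width
            if not placer.collides(chrom, s, e):
                return chrom, center

    n_genes = len(genes)
    # --- A peaks -----------------------------------------------------------
    n_a_tss = int(round(config.tss_peak_fraction * config.n_peaks_a)) if n_genes else 0
    a_records: list[tuple[str, int, int, float, int]] = []  # chrom, center, width, score, gene
    a_gene_targets = (
        rng.integers(0, n_genes, size=n_a_tss) if n_a_tss else np.empty(0, dtype=int)
    )
    for i in range(config.n_peaks_a):
        width = _draw_width(rng, config)
        if i < n_a_tss:
            chrom, center = _place_at_gene(int(a_gene_targets[i]), width)
            gene = int(a_gene_targets[i])
        else:
            chrom, center = _place_background(width)
            gene = -1
        score = float(rng.lognormal(1.0, 0.5))
        placer.add(chrom, center - width // 2, center - width // 2 + width)
        a_records.append((chrom, center, width, score, gene))

    # --- common B peaks: one per distinct A partner -------------------------
    n_common = int(round(config.co_binding_fraction * config.n_peaks_b))
    partners = (
        rng.choice(config.n_peaks_a, size=n_common, replace=False)
        if n_common
        else np.empty(0, dtype=int)
    )
    b_records: list[tuple[str, int, int, float, int, str]] = []
    for j, ai in enumerate(partners):
        chrom, ac, aw, _, gene = a_records[int(ai)]
        width = _draw_width(rng, config)
        offset = int(round(rng.uniform(-0.3, 0.3) * aw))
        center = ac + offset
        score = float(rng.lognormal(1.0, 0.5))
        b_records.append((chrom, center, width, score, gene, "bc"))

    # --- unique B peaks: never overlapping any A peak ------------------------
    n_unique = config.n_peaks_b - n_common
    n_b_tss = int(round(config.tss_peak_fraction * n_unique)) if n_genes else 0
    b_gene_targets = (
        rng.integers(0, n_genes, size=n_b_tss) if n_b_tss else np.empty(0, dtype=int)
    )
    for i in range(n_unique):
        width = _draw_width(rng, config)
        if i < n_b_tss:
            chrom, center = _place_at_gene(int(b_gene_targets[i]), width)
            gene = int(b_gene_targets[i])
        else:
            chrom, center = _place_background(width)
            gene = -1
        score = float(rng.lognormal(1.0, 0.5))
        b_records.append((chrom, center, width, score, gene, "bu"))

    # --- treated B: keep strongest (1 - loss) vehicle peaks at delta scale ---
    n_lost = int(round(config.loss_fraction * config.n_peaks_b))
    n_gain = int(round(config.gain_fraction * config.n_peaks_b))
    order = sorted(range(len(b_records)), key=lambda i: -b_records[i][3])
    shared_idx = set(order[: config.n_peaks_b - n_lost])
    gained: list[tuple[str, int, int, float, int, str]] = []
    for i in range(n_gain):
        width = _draw_width(rng, config)
        chrom, center = _place_background(width)
        score = 0.25 * float(rng.lognormal(1.0, 0.5))
        gained.append((chrom, center, width, score, -1, "bg"))

    def _iv(rec, name: str, scale: float = 1.0) -> GenomicInterval:
        chrom, center, width, score, _gene, _kind = rec
        start = center - width // 2
        return GenomicInterval(chrom, start, start + width, name, score * scale, ".")

    a_ivs = [
        _iv((c, ctr, wd, sc, g, "a"), f"a_{i:05d}")
        for i, (c, ctr, wd, sc, g) in enumerate(a_records)
    ]
    b_ivs = [_iv(rec, f"{rec[5]}_{i:05d}") for i, rec in enumerate(b_records)]
    bt_ivs = [
        _iv(b_records[i], f"{b_records[i][5]}_{i:05d}", config.treated_intensity_scale)
        for i in sorted(shared_idx)
    ] + [_iv(rec, f"bg_{i:05d}") for i, rec in enumerate(gained)]

    # --- planted gene truth --------------------------------------------------
    a_genes = {g for (_, _, _, _, g) in a_records if g >= 0}
    b_genes = {rec[4] for rec in b_records if rec[4] >= 0}
    cls = []
    for gi in range(n_genes):
        a, b = gi in a_genes, gi in b_genes
        cls.append("common" if a and b else "A_only" if a else "B_only" if b else "none")
    gene_truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "a_bound": [gi in a_genes for gi in range(n_genes)],
            "b_bound": [gi in b_genes for gi in range(n_genes)],
            "true_class": cls,
        }
    )
    return SyntheticCistromes(
        a_vehicle=PeakSet(a_ivs, "a_vehicle"),
        b_vehicle=PeakSet(b_ivs, "b_vehicle"),
        a_treated=PeakSet(a_ivs, "a_treated"),
        b_treated=PeakSet(bt_ivs, "b_treated"),
        gene_truth=gene_truth,
    )


# ---------------------------------------------------------------------------
# tracks


def bump_track(
    bumps: list[tuple[str, int, int, float]],
    chrom_lengths: dict[str, int],
    background: float = 0.0,
    resolution: int = 10,
) -> SignalTrack:
    """Gaussian-bump track sampled on a regular grid and run-length compressed.

    Each bump is (chrom, center, width, amplitude); its SD is width/4 so ~95%
    of the signal mass falls inside the peak interval, and it is evaluated
    within +/- width (4 SD) of the center. Grid values apply to
    [i*resolution, (i+1)*resolution).
    """
    grids = {
        chrom: np.full(int(np.ceil(L / resolution)), float(background))
        for chrom, L in chrom_lengths.items()
    }
    for chrom, center, width, amp in bumps:
        grid = grids[chrom]
        sd = width / 4.0
        radius = width
        i0 = max(0, (center - radius) // resolution)
        i1 = min(len(grid), (center + radius) // resolution + 1)
        x = np.arange(i0, i1) * resolution
        grid[i0:i1] += amp * np.exp(-((x - center) ** 2) / (2.0 * sd * sd))
    runs = {}
    for chrom, grid in grids.items():
        change = np.flatnonzero(np.diff(grid)) + 1
        starts = np.concatenate(([0], change)) * resolution
        ends = np.concatenate((change, [len(grid)])) * resolution
        ends = np.minimum(ends, chrom_lengths[chrom])
        runs[chrom] = (starts, ends, grid[np.concatenate(([0], change))])
    return SignalTrack(runs, resolution=resolution)


def simulate_tracks(
    cistromes: SyntheticCistromes, config: SimConfig
) -> dict[str, SignalTrack]:
    """One track per mark x condition: a_*, b_*, ac_* for vehicle/treated.

    Per-peak bump amplitudes are drawn once; the acetylation-like track sums
    bumps over all vehicle peaks with a boost at co-bound (common) sites. In
    the treated acetylation track, B-only bumps are attenuated by delta while
    A and common-site bumps persist; the treated B binding track follows the
    treated B peak set (shared peaks at delta intensity plus weak gains).
    """
    config.validate()
    rng = config.rng("tracks")
    chrom_lengths = {c: config.chrom_length for c in config.chrom_names()}

    def _amp() -> float:
        return float(max(0.5, rng.normal(config.signal_amplitude_mean, config.signal_amplitude_sd)))

    amp_a = {iv.name: _amp() for iv in cistromes.a_vehicle}
    amp_b = {iv.name: _amp() for iv in cistromes.b_vehicle}
    amp_gain = {
        iv.name: 0.25 * _amp()
        for iv in cistromes.b_treated
        if iv.name.startswith("bg_")
    }

    def _bumps(peaks, amps, scale=lambda iv: 1.0):
        return [
            (iv.chrom, iv.center, iv.length, amps[iv.name] * scale(iv))
            for iv in peaks
        ]

    delta = config.treated_intensity_scale
    boost = config.common_ac_boost
    common_a = {
        iv.name
        for iv in cistromes.a_vehicle
        # A peaks that host a common B partner get the acetylation boost
    }
    # identify A partners of common B peaks by overlap with bc_* peaks
    bc_peaks = [iv for iv in cistromes.b_vehicle if iv.name.startswith("bc_")]
    common_a = set()
    by_chrom_a = cistromes.a_vehicle.by_chrom()
    for bc in bc_peaks:
        for a in by_chrom_a.get(bc.chrom, ()):  # desk-scale linear scan
            if a.start < bc.end and bc.start < a.end:
                common_a.add(a.name)

    def _ac_scale_vehicle(iv: GenomicInterval) -> float:
        if iv.name in common_a or iv.name.startswith("bc_"):
            return boost
        return 1.0

    def _ac_scale_treated(iv: GenomicInterval) -> float:
        if iv.name in common_a or iv.name.startswith("bc_"):
            return boost
        if iv.name.startswith("bu_"):
            return delta
        return 1.0

    tracks = {
        "a_vehicle": bump_track(
            _bumps(cistromes.a_vehicle, amp_a),
            chrom_lengths,
            config.signal_background,
            config.track_resolution,
        ),
        "b_vehicle": bump_track(
            _bumps(cistromes.b_vehicle, amp_b),
            chrom_lengths,
            config.signal_background,
            config.track_resolution,
        ),
    }
    tracks["a_treated"] = tracks["a_vehicle"]
    bt_bumps = []
    for iv in cistromes.b_treated:
        if iv.name.startswith("bg_"):
            bt_bumps.append((iv.chrom, iv.center, iv.length, amp_gain[iv.name]))
        else:
            bt_bumps.append((iv.chrom, iv.center, iv.length, amp_b[iv.name] * delta))
    tracks["b_treated"] = bump_track(
        bt_bumps, chrom_lengths, config.signal_background, config.track_resolution
    )
    ac_vehicle_bumps = _bumps(cistromes.a_vehicle, amp_a, _ac_scale_vehicle) + _bumps(
        cistromes.b_vehicle, amp_b, _ac_scale_vehicle
    )
    ac_treated_bumps = _bumps(cistromes.a_vehicle, amp_a, _ac_scale_treated) + _bumps(
        cistromes.b_vehicle, amp_b, _ac_scale_treated
    )
    tracks["ac_vehicle"] = bump_track(
        ac_vehicle_bumps, chrom_lengths, config.signal_background, config.track_resolution
    )
    tracks["ac_treated"] = bump_track(
        ac_treated_bumps, chrom_lengths, config.signal_background, config.track_resolution
    )
    return tracks


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genes: pd.DataFrame, gene_truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Fold-change table, per-sample matrix, and the signature gene list.

    The planted treatment effect per gene is ``+effect_a`` when A-bound
    (treatment activates A targets) and ``-effect_b`` when bound by B only
    (treatment removes the B activator); Gaussian noise is added on top. The
    signature lists the ``signature_size`` B-only genes (the B-upregulated
    set), ordered by gene_id.
    """
    config.validate()
    rng = config.rng("expression")
    truth = gene_truth.set_index("gene_id").loc[genes["gene_id"]]
    a_bound = truth["a_bound"].to_numpy(bool)
    b_only = truth["b_bound"].to_numpy(bool) & ~a_bound
    effect = config.expr_effect_a * a_bound - config.expr_effect_b * b_only
    log2fc = effect + rng.normal(0.0, config.expr_noise_sd, size=len(genes))
    fc = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "true_effect": effect,
            "log2fc": log2fc,
        }
    )
    b_only_genes = sorted(genes["gene_id"][b_only])
    if config.signature_size > len(b_only_genes):
        raise SimConfigError(
            f"signature_size={config.signature_size} exceeds the "
            f"{len(b_only_genes)} B-only-bound genes available"
        )
    signature = b_only_genes[: config.signature_size]

    srng = config.rng("samples")
    base = srng.normal(8.0, 2.0, size=len(genes))
    cols = {}
    for j in range(config.n_samples):
        cols[f"vehicle_{j + 1:02d}"] = base + srng.normal(
            0.0, config.sample_noise_sd, size=len(genes)
        )
    for j in range(config.n_samples):
        cols[f"treated_{j + 1:02d}"] = (
            base + log2fc + srng.normal(0.0, config.sample_noise_sd, size=len(genes))
        )
    expr = pd.DataFrame(cols, index=pd.Index(genes["gene_id"], name="gene_id"))
    return fc, expr, signature


# ---------------------------------------------------------------------------
# orchestration and I/O


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run every simulation stage under the named substreams of one seed."""
    config.validate()
    genes = simulate_genome(config)
    cistromes = simulate_cistromes(config, genes)
    tracks = simulate_tracks(cistromes, config)
    fc, expr, signature = simulate_expression(genes, cistromes.gene_truth, config)
    return SyntheticDataset(config, genes, cistromes, tracks, fc, expr, signature)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _bed6_rounded(peaks: PeakSet) -> PeakSet:
    """BED6 convention of the dataset: score = intensity * 1000, rounded."""
    return PeakSet(
        [
            GenomicInterval(
                iv.chrom, iv.start, iv.end, iv.name, float(round(iv.score * 1000)), iv.strand
            )
            for iv in peaks
        ],
        label=peaks.label,
        _presorted=True,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write every component to ``outdir`` and return the manifest dict.

    Layout: peaks/*.bed (BED6, score = intensity x 1000 rounded),
    tracks/*.bedgraph, genes.tsv, gene_truth.tsv, expression/fold_changes.tsv,
    expression/matrix.tsv, signature.txt, config.yaml, manifest.json.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "expression").mkdir(exist_ok=True)
    cz = dataset.cistromes
    peak_sets = {
        "a_vehicle": cz.a_vehicle,
        "b_vehicle": cz.b_vehicle,
        "a_treated": cz.a_treated,
        "b_treated": cz.b_treated,
        "ac_vehicle": PeakSet(
            list(cz.a_vehicle) + list(cz.b_vehicle), label="ac_vehicle"
        ),
    }
    for name, ps in peak_sets.items():
        write_bed(_bed6_rounded(ps), outdir / "peaks" / f"{name}.bed")
    for name, track in dataset.tracks.items():
        write_bedgraph(track, outdir / "tracks" / f"{name}.bedgraph")
    write_gene_table(dataset.genes, outdir / "genes.tsv")
    dataset.cistromes.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    dataset.fold_changes.to_csv(
        outdir / "expression" / "fold_changes.tsv", sep="\t", index=False
    )
    dataset.expression.to_csv(outdir / "expression" / "matrix.tsv", sep="\t")
    (outdir / "signature.txt").write_text("\n".join(dataset.signature) + "\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    files = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": dataset.config.to_dict(),
        "seed": dataset.config.seed,
        "track_resolution": dataset.config.track_resolution,
        "files": {f: _sha256(outdir / f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_manifest_config(path) -> SimConfig:
    """Rebuild the SimConfig recorded in a dataset manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    return SimConfig.from_dict(manifest["config"])
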