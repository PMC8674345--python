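"""TSS-window annotation, gene occupancy classes, and enrichment tests.

Genes are annotated by the peaks overlapping a fixed half-open window
[tss - w, tss + w) around their transcription start site, strand-blind.
Occupancy classes (A_only / B_only / common / none) follow from which of two
factors has at least one peak in the window. Enrichment of a query gene set
for proximal binding is measured against equal-size random gene sets drawn
from the universe, summarized as an odds ratio (observed percentage over mean
null percentage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "GENE_TABLE_COLUMNS",
    "EnrichmentResult",
    "read_gene_table",
    "write_gene_table",
    "assign_peaks_to_genes",
    "genes_with_peak",
    "occupancy_classes",
    "resample_enrichment",
    "hypergeom_overlap",
]

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
OCCUPANCY_LABELS = ("A_only", "B_only", "common", "none")


def read_gene_table(path) -> pd.DataFrame:
    """Read a TSV gene table (gene_id, chrom, tss, strand) with header line."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated gene_id")
    if (df["tss"] < 0).any():
        raise ValueError(f"{path}: negative TSS coordinate")
    return df.reset_index(drop=True)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def _window_hits(
    peaks: PeakSet, genes: pd.DataFrame, window: int
) -> list[list[GenomicInterval]]:
    """Per-gene list of peaks overlapping [tss-window, tss+window)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list]] = {}
    for chrom, ivs in peaks.by_chrom().items():
        starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64)
        ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64)
        by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends), ivs)
    out: list[list[GenomicInterval]] = []
    for chrom, tss in zip(genes["chrom"], genes["tss"]):
        entry = by_chrom.get(chrom)
        hits: list[GenomicInterval] = []
        if entry is not None:
            starts, ends, cummax_end, ivs = entry
            lo, hi = int(tss) - window, int(tss) + window
            j = int(np.searchsorted(starts, hi, side="left")) - 1
            while j >= 0 and cummax_end[j] > lo:
                if ends[j] > lo:
                    hits.append(ivs[j])
                j -= 1
            hits.reverse()
        out.append(hits)
    return out


def assign_peaks_to_genes(
    peaks: PeakSet, genes: pd.DataFrame, window_kb: float = 20.0
) -> dict[str, list[GenomicInterval]]:
    """Map gene_id -> peaks overlapping [tss - w, tss + w), w = window_kb * 1000."""
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    window = int(round(window_kb * 1000))
    hits = _window_hits(peaks, genes, window)
    return dict(zip(genes["gene_id"], hits))


def genes_with_peak(
    peaks: PeakSet, genes: pd.DataFrame, window_kb: float
) -> np.ndarray:
    """Boolean array: gene has >=1 peak in its TSS window."""
    window = int(round(window_kb * 1000))
    return np.array([bool(h) for h in _window_hits(peaks, genes, window)])


def occupancy_classes(
    genes: pd.DataFrame,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    window_kb: float = 10.0,
) -> pd.DataFrame:
    """Classify each gene as A_only / B_only / common / none by TSS-window occupancy."""
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    a = genes_with_peak(peaks_a, genes, window_kb)
    b = genes_with_peak(peaks_b, genes, window_kb)
    cls = np.where(a & b, "common", np.where(a, "A_only", np.where(b, "B_only", "none")))
    return pd.DataFrame({"gene_id": genes["gene_id"], "occupancy": cls})


@dataclass
class EnrichmentResult:
    """Resampling enrichment of a query gene set for proximal peaks.

    observed_pct is the percentage of query genes with at least one peak in the
    TSS window; null_pcts holds the same percentage for n_iter equal-size
    random gene sets drawn from the universe without replacement. The odds
    ratio is observed_pct / mean(null_pcts); p_empirical is the +1-corrected
    upper-tail resampling p; p_t is the one-sided one-sample t-test of the null
    percentages against the observed value.
    """

    observed_pct: float
    null_pcts: np.ndarray
    odds_ratio: float
    p_empirical: float
    p_t: float
    seed: int
    n_query: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_pcts))


def resample_enrichment(
    query_genes: Iterable[str],
    peaks: PeakSet,
    universe: pd.DataFrame,
    window_kb: float = 20.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of query genes for peaks within +/- window_kb of the TSS.

    Each null draw samples |query| genes from the universe without
    replacement. Reproducible under ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    query = list(dict.fromkeys(query_genes))
    # canonical gene order: the result is invariant to any permutation of the
    # universe table (and to chromosome relabeling, which window hits ignore)
    universe = universe.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    ids = universe["gene_id"]
    id_pos = pd.Series(np.arange(len(ids)), index=ids)
    missing = [g for g in query if g not in id_pos.index]
    if missing:
        raise ValueError(
            f"query genes not in universe (first few): {missing[:5]}"
        )
    if len(query) > len(universe):
        raise ValueError("query larger than universe")
    bound = genes_with_peak(peaks, universe, window_kb).astype(np.float64)
    qpos = id_pos.loc[query].to_numpy()
    observed_pct = 100.0 * float(bound[qpos].mean())

    rng = np.random.default_rng(seed)
    n, q = len(universe), len(query)
    # sample-without-replacement null draws, vectorized
    null_pcts = np.empty(n_iter)
    chunk = max(1, min(n_iter, int(4e6 / max(n, 1)) or 1))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        mat = np.tile(np.arange(n), (m, 1))
        rng.permuted(mat, axis=1, out=mat)
        null_pcts[done : done + m] = 100.0 * bound[mat[:, :q]].mean(axis=1)
        done += m

    null_mean = float(null_pcts.mean())
    if null_mean == 0.0:
        if observed_pct == 0.0:
            warnings.warn(
                "no gene in universe has a proximal peak; odds ratio reported as 0",
                stacklevel=2,
            )
            odds_ratio = 0.0
        else:
            warnings.warn(
                "all null percentages are zero; odds ratio reported as +inf",
                stacklevel=2,
            )
            odds_ratio = float("inf")
    else:
        odds_ratio = observed_pct / null_mean
    p_empirical = (1.0 + float(np.sum(null_pcts >= observed_pct))) / (n_iter + 1.0)
    if np.all(null_pcts == null_pcts[0]):
        p_t = 1.0 if null_pcts[0] >= observed_pct else 0.0
        p_t = min(max(p_t, np.nextafter(0, 1)), 1.0)
    else:
        p_t = float(
            stats.ttest_1samp(null_pcts, observed_pct, alternative="less").pvalue
        )
        p_t = min(max(p_t, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(
        observed_pct=observed_pct,
        null_pcts=null_pcts,
        odds_ratio=odds_ratio,
        p_empirical=p_empirical,
        p_t=p_t,
        seed=seed,
        n_query=q,
    )


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when drawing n genes from a universe of N containing
    K marked genes. Computed by summing log-pmf terms for stability.
    """
    for label, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise ValueError(f"{label} must be nonnegative")
    if K > N or n > N:
        raise ValueError("require K <= N and n <= N")
    if k > min(K, n):
        raise ValueError("require k <= min(K, n)")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))
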