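"""Signature z-scores and the small statistical comparisons used downstream.

The per-sample signature score is the sum over a fixed gene list of
standardized expression values z = (x - mu) / sigma, with mu and sigma the
per-gene study mean and sample (n-1) standard deviation across all samples.
Because each gene's z-scores sum to zero across samples, so do the signature
scores — a useful identity check.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "signature_zscore",
    "compare_groups",
    "ratio_chisq",
]


def signature_zscore(
    expr: pd.DataFrame, signature: Iterable[str]
) -> pd.DataFrame:
    """Per-sample sum of per-gene z-scores over a signature gene list.

    ``expr`` is a genes x samples table indexed by gene_id. Signature genes
    absent from the matrix are skipped; genes with zero variance are dropped
    with a warning. Returns a table (sample_id, score, n_genes_used).
    """
    signature = list(dict.fromkeys(signature))
    if not signature:
        raise ValueError("empty signature")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score")
    present = [g for g in signature if g in expr.index]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    absent = len(signature) - len(present)
    if absent:
        warnings.warn(
            f"{absent} signature gene(s) absent from the matrix; skipped",
            stacklevel=2,
        )
    sub = expr.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sigma = sub.std(axis=1, ddof=1)
    zero_var = sigma == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} signature gene(s) with zero variance dropped",
            stacklevel=2,
        )
        sub = sub.loc[~zero_var]
        mu, sigma = mu[~zero_var], sigma[~zero_var]
    if sub.empty:
        raise ValueError("all usable signature genes have zero variance")
    z = sub.sub(mu, axis=0).div(sigma, axis=0)
    scores = z.sum(axis=0)
    return pd.DataFrame(
        {
            "sample_id": scores.index,
            "score": scores.to_numpy(),
            "n_genes_used": len(sub),
        }
    )


def compare_groups(
    values_by_class: Mapping[str, Sequence[float]], min_size: int = 3
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with BH adjustment.

    Classes with fewer than ``min_size`` values are skipped with a warning.
    Returns columns class_a, class_b, n_a, n_b, statistic, p_value, p_adjusted.
    """
    labels = list(values_by_class)
    usable = []
    for lab in labels:
        if len(values_by_class[lab]) < min_size:
            warnings.warn(
                f"class {lab!r} has < {min_size} values; its pairs are skipped",
                stacklevel=2,
            )
        else:
            usable.append(lab)
    rows = []
    for a, b in itertools.combinations(usable, 2):
        x = np.asarray(values_by_class[a], dtype=float)
        y = np.asarray(values_by_class[b], dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append((a, b, len(x), len(y), float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(
        rows, columns=["class_a", "class_b", "n_a", "n_b", "statistic", "p_value"]
    )
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


def ratio_chisq(up1: int, down1: int, up2: int, down2: int) -> tuple[float, float]:
    """2x2 chi-squared test (no continuity correction) on regulated-gene counts.

    Rows are the two conditions, columns the up/down counts. Returns
    (statistic, p_value). Zero margins are rejected.
    """
    table = np.array([[up1, down1], [up2, down2]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test undefined with a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
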