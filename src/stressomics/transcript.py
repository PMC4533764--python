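"""Count normalisation, fold changes, percentile abundance ranks, mRNA DE.

Size factors follow the median-of-ratios rule: for sample *j*,
``s_j = median_g (k_gj / (prod_j k_gj)^(1/m))`` over genes with non-zero
counts in every sample.  Percentile abundance ranks (the "blue plot"
metric) place the least abundant feature at 0 and the most abundant at 100,
with ties sharing the averaged rank; ranks are computed per time point and
then averaged across a condition's time points.  The mRNA DE caller is a
label-permutation test on the mean log2 difference with Benjamini-Hochberg
adjustment — a deliberately simple stand-in, since the pipeline also accepts
externally computed transcript DE tables.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample."""
    x = counts.to_numpy(float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene with non-zero counts in every sample; add a pseudocount first"
        )
    ref = x[all_nonzero]
    log_gm = np.mean(np.log(ref), axis=1)
    sf = np.median(ref / np.exp(log_gm)[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    sf = size_factors(counts)
    return counts / sf, sf


def log2fc(
    normalized: pd.DataFrame,
    stress_cols: list[str],
    control_cols: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((mean_stress + c) / (mean_control + c)) per gene."""
    ms = normalized[stress_cols].mean(axis=1)
    mc = normalized[control_cols].mean(axis=1)
    return np.log2((ms + pseudocount) / (mc + pseudocount)).rename("log2fc")


def percentile_rank(abundances: pd.DataFrame | pd.Series) -> pd.Series:
    """0-100 percentile abundance rank, averaged over columns if several.

    Each column (time point/replicate) is ranked separately with averaged
    ties, scaled as ``100 * (rank - 1) / (n - 1)``, then the per-column
    ranks are averaged.
    """
    if isinstance(abundances, pd.Series):
        abundances = abundances.to_frame()
    n = len(abundances)
    if n < 2:
        raise ValueError("percentile ranking needs at least 2 features")
    out = np.zeros(n)
    for col in abundances.columns:
        ranks = stats.rankdata(abundances[col].to_numpy(), method="average")
        out += 100.0 * (ranks - 1.0) / (n - 1.0)
    return pd.Series(out / abundances.shape[1], index=abundances.index, name="rank")


def de_call_mrna(
    normalized: pd.DataFrame,
    stress_cols: list[str],
    control_cols: list[str],
    fold: float = 2.0,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation DE call per gene: ``up`` / ``down`` / ``nonsig``.

    The statistic is the mean log2 difference between groups; its two-sided
    p-value comes from label permutations (exhaustive when feasible), BH
    adjustment across genes, and a category requires both q <= ``fdr`` and
    |log2fc| >= log2(``fold``).  With fewer than 2 replicates per group the
    caller degrades to a fold-only rule.
    """
    lfc = log2fc(normalized, stress_cols, control_cols, pseudocount)
    n1, n2 = len(stress_cols), len(control_cols)
    up_thresh = np.log2(fold)

    if n1 < 2 or n2 < 2:  # fold-only mode
        cat = np.where(lfc >= up_thresh, "up", np.where(lfc <= -up_thresh, "down", "nonsig"))
        return pd.DataFrame({"log2fc": lfc, "p": np.nan, "q": np.nan, "category": cat})

    x = np.log2(normalized[list(stress_cols) + list(control_cols)].to_numpy(float) + pseudocount)
    n = n1 + n2
    stat = x[:, :n1].mean(axis=1) - x[:, n1:].mean(axis=1)

    total = comb(n, n1)
    if total <= n_perm:
        assignments = np.array(list(itertools.combinations(range(n), n1)))
    else:
        rng = np.random.default_rng(seed)
        assignments = np.array([rng.choice(n, size=n1, replace=False) for _ in range(n_perm)])
    masks = np.zeros((len(assignments), n), dtype=bool)
    rows = np.repeat(np.arange(len(assignments)), n1)
    masks[rows, assignments.ravel()] = True
    w = masks.astype(float) / n1 - (~masks).astype(float) / n2
    perm_stats = x @ w.T  # (genes, perms)

    p = (1.0 + np.sum(np.abs(perm_stats) >= np.abs(stat)[:, None], axis=1)) / (
        1.0 + perm_stats.shape[1]
    )
    q = multipletests(p, method="fdr_bh")[1]
    sig = q <= fdr
    cat = np.where(
        sig & (lfc >= up_thresh), "up", np.where(sig & (lfc <= -up_thresh), "down", "nonsig")
    )
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "q": q, "category": cat}, index=normalized.index
    )
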