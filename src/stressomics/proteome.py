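"""iTRAQ ratio processing, SAM permutation testing and protein classification.

The SAM (significance analysis of microarrays) statistic for protein *i* is

    d_i = (xbar_stress - xbar_control) / (s_i + s0)

where ``s_i`` is the pooled standard error of the two group means and ``s0``
a small exchangeability constant that damps proteins with tiny variance.
Significance is assessed against the expected order statistics of ``d``
under label permutations: a protein is called when its ordered ``d`` departs
from the permutation expectation by more than a threshold delta, and delta is
chosen as the smallest value whose estimated false discovery rate (average
number of permutation calls divided by the number of real calls) is at or
below the target.

Classification is five-way: ``up`` / ``down`` (FDR pass and linear fold
change beyond 2), ``nonsig``, and the exclusive-detection categories
``stress_only`` / ``control_only`` which cannot carry a fold change and are
exported with the sentinel display values +6.0 and -5.0 — the largest
up/down fold observed among the differentially expressed proteins of the
study design this pipeline mirrors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRESS_ONLY_DISPLAY = 6.0
CONTROL_ONLY_DISPLAY = -5.0

CATEGORIES = ("up", "down", "nonsig", "stress_only", "control_only")


class SamError(ValueError):
    pass


def normalize_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and median-centre each sample (bias correction).

    Absent cells (NaN = not detected) stay absent.  A sample with no
    detected protein cannot be centred and is rejected.
    """
    if (ratios <= 0).to_numpy().any():
        raise ValueError("ratios must be positive where present")
    log2 = np.log2(ratios.astype(float))
    empty = log2.isna().all(axis=0)
    if empty.any():
        raise ValueError(f"sample(s) with no detected protein: {list(log2.columns[empty])}")
    return log2 - log2.median(axis=0, skipna=True)


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamOutcome:
    """Per-protein SAM results plus the delta actually used for calling."""

    table: pd.DataFrame  # xbar_stress, xbar_control, s, d, q, called
    s0: float
    delta: float
    fdr: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["called"]]


def _group_stats(x: np.ndarray, mask1: np.ndarray, mask2: np.ndarray):
    """NaN-aware group means and pooled standard error per row.

    A row whose (possibly permuted) group has no observed value gets a mean
    of 0 for that group — the permutation carries no evidence for it.
    """
    present = ~np.isnan(x)
    x0 = np.where(present, x, 0.0)
    n1 = present[:, mask1].sum(axis=1)
    n2 = present[:, mask2].sum(axis=1)
    m1 = x0[:, mask1].sum(axis=1) / np.maximum(n1, 1)
    m2 = x0[:, mask2].sum(axis=1) / np.maximum(n2, 1)
    ss1 = np.where(present[:, mask1], (x0[:, mask1] - m1[:, None]) ** 2, 0.0).sum(axis=1)
    ss2 = np.where(present[:, mask2], (x0[:, mask2] - m2[:, None]) ** 2, 0.0).sum(axis=1)
    dof = n1 + n2 - 2
    pooled = np.where(dof > 0, (ss1 + ss2) / np.maximum(dof, 1), 0.0)
    s = np.sqrt((1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)) * pooled)
    return m1, m2, s


def _tusher_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Exchangeability constant minimising the coefficient of variation of
    the d-statistic spread across windows of the s distribution."""
    alphas = np.linspace(0.0, 1.0, 21)
    quantiles = np.quantile(s, np.linspace(0.0, 1.0, 101))
    windows = np.clip(np.searchsorted(quantiles[1:-1], s, side="right"), 0, 99)
    best, best_cv = float(np.median(s)), np.inf
    for alpha in alphas:
        s0 = float(np.quantile(s, alpha))
        if s0 + s.min() <= 0:
            continue
        d = diff / (s + s0)
        mads = []
        for w in range(100):
            sel = windows == w
            if sel.sum() >= 2:
                dw = d[sel]
                mads.append(np.median(np.abs(dw - np.median(dw))) * 1.4826)
        mads = np.array(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv:
            best_cv, best = cv, s0
    return best


def _permutation_masks(n1: int, n2: int, n_perm: int, seed: int) -> np.ndarray:
    """Boolean masks (P, n1+n2) assigning columns to the pseudo-stress group.

    Exhaustive when the number of distinct assignments is within ``n_perm``,
    otherwise ``n_perm`` assignments sampled with the given seed.
    """
    n = n1 + n2
    from math import comb

    total = comb(n, n1)
    if total <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n1, replace=False)] = True
    return masks


def sam_test(
    log2: pd.DataFrame,
    stress_cols: list[str],
    control_cols: list[str],
    s0_mode: str = "tusher",
    n_perm: int = 1000,
    fdr_target: float = 0.05,
    seed: int = 0,
    max_delta_grid: int = 200,
) -> SamOutcome:
    """Two-class unpaired SAM with permutation FDR.

    Only proteins quantified in at least two samples of each group enter the
    test.  ``s0_mode`` is ``"tusher"`` (CV-minimising window search) or
    ``"median"`` (median of the per-protein standard errors).
    """
    cols = list(stress_cols) + list(control_cols)
    x_all = log2[cols].to_numpy(float)
    n1, n2 = len(stress_cols), len(control_cols)
    if n1 < 2 or n2 < 2:
        raise SamError("need >= 2 replicates per group")
    usable = (
        (np.sum(~np.isnan(x_all[:, :n1]), axis=1) >= 2)
        & (np.sum(~np.isnan(x_all[:, n1:]), axis=1) >= 2)
    )
    x = x_all[usable]
    index = log2.index[usable]
    mask1 = np.zeros(n1 + n2, dtype=bool)
    mask1[:n1] = True
    m1, m2, s = _group_stats(x, mask1, ~mask1)
    diff = m1 - m2

    if s0_mode == "tusher":
        s0 = _tusher_s0(diff, s)
    elif s0_mode == "median":
        s0 = float(np.median(s))
    else:
        raise ValueError(f"unknown s0_mode {s0_mode!r}")
    if np.any(s + s0 <= 0):
        raise SamError(
            "zero variance in both groups with s0=0; use s0_mode='median' or 'tusher'"
        )
    d = diff / (s + s0)

    masks = _permutation_masks(n1, n2, n_perm, seed)
    perm_d = np.empty((len(masks), len(d)))
    for i, pm in enumerate(masks):
        pm1, pm2, ps = _group_stats(x, pm, ~pm)
        perm_d[i] = (pm1 - pm2) / (ps + s0)
    perm_sorted = np.sort(perm_d, axis=1)
    dbar = perm_sorted.mean(axis=0)

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    diffs = d_sorted - dbar

    candidates = np.unique(np.abs(diffs))
    candidates = candidates[candidates > 0]
    if len(candidates) > max_delta_grid:
        candidates = np.quantile(candidates, np.linspace(0, 1, max_delta_grid))
    candidates = np.concatenate([candidates, [np.inf]])

    q = np.full(len(d), 1.0)
    chosen = None
    for delta in candidates:
        cut_up, cut_low = _cutpoints(d_sorted, dbar, delta)
        called = (d >= cut_up) | (d <= cut_low)
        n_called = int(called.sum())
        if n_called == 0:
            fdr = 0.0
        else:
            # average (not median) false calls across permutations: with few
            # exact permutations the median collapses to 0 and under-estimates
            false = np.sum(perm_d >= cut_up, axis=1) + np.sum(perm_d <= cut_low, axis=1)
            fdr = float(np.mean(false)) / n_called
        fdr = min(fdr, 1.0)
        q[called] = np.minimum(q[called], fdr)
        if chosen is None and fdr <= fdr_target:
            chosen = (float(delta), fdr, called)
    if chosen is None:  # pragma: no cover - grid always ends at +inf (0 calls)
        chosen = (float("inf"), 0.0, np.zeros(len(d), dtype=bool))
    delta, fdr, called = chosen

    table = pd.DataFrame(
        {
            "xbar_stress": m1,
            "xbar_control": m2,
            "s": s,
            "d": d,
            "q": q,
            "called": called,
        },
        index=index,
    )
    n_dropped = int(len(log2) - usable.sum())
    if n_dropped:
        log.info("sam_test: %d protein(s) lacked >=2 quantifications per group", n_dropped)
    return SamOutcome(table=table, s0=s0, delta=delta, fdr=fdr)


def _cutpoints(d_sorted: np.ndarray, dbar: np.ndarray, delta: float):
    diffs = d_sorted - dbar
    up = (diffs >= delta) & (d_sorted > 0)
    low = (diffs <= -delta) & (d_sorted < 0)
    cut_up = d_sorted[up].min() if up.any() else np.inf
    cut_low = d_sorted[low].max() if low.any() else -np.inf
    return cut_up, cut_low


# ---------------------------------------------------------------------------
# classification


def classify_proteins(
    ratios: pd.DataFrame,
    stress_cols: list[str],
    control_cols: list[str],
    sam: SamOutcome | None = None,
    fold_up: float = 2.0,
    min_detect: int = 1,
) -> pd.DataFrame:
    """Five-way classification with sentinel display values.

    ``detected`` in a condition means quantified in at least ``min_detect``
    of its samples.  Proteins detected in both conditions are ``up`` /
    ``down`` when the SAM FDR call passes and the linear fold change (ratio
    of replicate-mean ratios) is >= ``fold_up`` / <= 1/``fold_up``; otherwise
    ``nonsig``.  Exclusive detections become ``stress_only`` (+6.0 on the
    heat-map scale) or ``control_only`` (-5.0).  Proteins detected in
    neither condition are excluded (count logged).
    """
    det_stress = ratios[stress_cols].notna().sum(axis=1) >= min_detect
    det_control = ratios[control_cols].notna().sum(axis=1) >= min_detect
    mean_stress = ratios[stress_cols].mean(axis=1, skipna=True)
    mean_control = ratios[control_cols].mean(axis=1, skipna=True)
    fold = mean_stress / mean_control

    fdr_pass = pd.Series(False, index=ratios.index)
    if sam is not None:
        fdr_pass.loc[fdr_pass.index.intersection(sam.significant)] = True

    records = []
    n_excluded = 0
    for pid in ratios.index:
        ds, dc = bool(det_stress[pid]), bool(det_control[pid])
        if not ds and not dc:
            n_excluded += 1
            continue
        if ds and not dc:
            cat, fc, disp = "stress_only", np.nan, STRESS_ONLY_DISPLAY
        elif dc and not ds:
            cat, fc, disp = "control_only", np.nan, CONTROL_ONLY_DISPLAY
        else:
            fc = float(fold[pid])
            passed = bool(fdr_pass[pid])
            if passed and fc >= fold_up:
                cat = "up"
            elif passed and fc <= 1.0 / fold_up:
                cat = "down"
            else:
                cat = "nonsig"
            disp = fc if fc >= 1.0 else -1.0 / fc
        records.append(
            {
                "protein_id": pid,
                "category": cat,
                "fold_change": fc,
                "display_value": disp,
                "fdr_pass": bool(fdr_pass[pid]) and not np.isnan(fc) if ds and dc else False,
            }
        )
    if n_excluded:
        log.info("classify_proteins: %d protein(s) undetected in both conditions", n_excluded)
    return pd.DataFrame.from_records(records).set_index("protein_id") if records else pd.DataFrame(
        columns=["category", "fold_change", "display_value", "fdr_pass"]
    )


def summarize_de(records_by_level: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-level bookkeeping of the differential-expression calls.

    One row per stress level: proteins used for DE (detected under both
    conditions), FDR-passing up/down counts, fold-filtered up/down counts
    with their total, and the exclusive-detection counts.
    """
    rows = []
    for level, rec in records_by_level.items():
        both = rec["category"].isin(["up", "down", "nonsig"])
        up = rec["category"] == "up"
        down = rec["category"] == "down"
        fdr_up = rec["fdr_pass"] & (rec["fold_change"] > 1.0)
        fdr_down = rec["fdr_pass"] & (rec["fold_change"] < 1.0)
        rows.append(
            {
                "level": level,
                "used_for_de": int(both.sum()),
                "de_fdr_up": int(fdr_up.sum()),
                "de_fdr_down": int(fdr_down.sum()),
                "de_fold_up": int(up.sum()),
                "de_fold_down": int(down.sum()),
                "de_fold_total": int(up.sum() + down.sum()),
                "stress_only": int((rec["category"] == "stress_only").sum()),
                "control_only": int((rec["category"] == "control_only").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("level")
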