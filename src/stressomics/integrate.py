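"""Join protein and mRNA layers; discordance, hypothesis and percentile
screens; per-category correlations; COG enrichment.

Discordance is the signature of post-transcriptional regulation: a protein
moving opposite to its transcript (up while the mRNA is down, or down /
undetected under stress while the mRNA is up), or a protein appearing or
disappearing entirely despite good mRNA levels.  Three mechanistic screens
follow:

* **H1** — chronically inefficient translation: mRNA abundance rank high
  (>= 80) and protein rank low (<= 20) under stress *and* control alike.
* **H2** — stress-specific translational silencing: at medium and high
  stress, mRNA differentially up (fold > 2) while the protein is down or
  undetected.
* **H3** — high translation efficiency from flat mRNA: protein
  differentially up (fold >= 2, FDR pass) while both transcript datasets are
  non-significant; flagged records are annotated with whether the 5'UTR is
  longer than the genome median and the RBS score above the genome mean.

The revised percentile screens compare abundance rather than differential
calls: ``rev_lowM_highP`` (mRNA rank < 60, protein rank > 80, protein up or
stress-only) and its mirror ``rev_highM_lowP``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MRNA_DATASETS = ("microarray", "rnaseq")


def join_omics(
    protein_records: pd.DataFrame,
    mrna_de: dict[str, pd.DataFrame],
    protein_rank_stress: pd.Series | None = None,
    protein_rank_control: pd.Series | None = None,
    mrna_rank_stress: pd.Series | None = None,
    mrna_rank_control: pd.Series | None = None,
    utr_len: pd.Series | None = None,
    rbs_score: pd.Series | None = None,
) -> pd.DataFrame:
    """One record per protein-detected gene; missing layers stay absent.

    ``mrna_de`` maps dataset name (``microarray``/``rnaseq``) to a frame with
    ``log2fc`` and ``category`` columns.  Unmatched ids are logged, never
    imputed.
    """
    if protein_records.index.has_duplicates:
        dup = protein_records.index[protein_records.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in protein records")
    out = protein_records.rename(
        columns={"category": "protein_category", "display_value": "protein_display_value"}
    ).copy()
    for name, table in mrna_de.items():
        missing = out.index.difference(table.index)
        if len(missing):
            log.info("join_omics: %d gene(s) missing from %s DE table", len(missing), name)
        out[f"mrna_category_{name}"] = table["category"].reindex(out.index)
        out[f"mrna_log2fc_{name}"] = table["log2fc"].reindex(out.index)
    for col, series in [
        ("protein_rank_stress", protein_rank_stress),
        ("protein_rank_control", protein_rank_control),
        ("mrna_rank_stress", mrna_rank_stress),
        ("mrna_rank_control", mrna_rank_control),
        ("utr_len", utr_len),
        ("rbs_score", rbs_score),
    ]:
        out[col] = series.reindex(out.index) if series is not None else np.nan
    return out


def call_discordance(
    records: pd.DataFrame,
    fold_thresh: float = 2.0,
    good_mrna_rank: float = 50.0,
    reference: str = "microarray",
) -> pd.DataFrame:
    """Flag proteome-transcriptome discordance and record which clause fired.

    Clauses: (1) protein up or stress-only with the reference mRNA down;
    (2) protein down or control-only with the reference mRNA up; (3) an
    exclusive-detection protein whose mRNA is non-significant but well
    expressed (rank >= ``good_mrna_rank``) — the "despite good mRNA levels"
    case.
    """
    out = records.copy()
    pcat = out["protein_category"]
    mcat = out[f"mrna_category_{reference}"]
    rank = out["mrna_rank_stress"]
    c1 = pcat.isin(["up", "stress_only"]) & (mcat == "down")
    c2 = pcat.isin(["down", "control_only"]) & (mcat == "up")
    c3 = (
        pcat.isin(["stress_only", "control_only"])
        & (mcat == "nonsig")
        & (rank >= good_mrna_rank)
    )
    out["discordant"] = c1 | c2 | c3
    subtype = np.select(
        [c1, c2, c3],
        ["protein_up_mrna_down", "protein_down_mrna_up", "exclusive_good_mrna"],
        default="",
    )
    out["discordance_subtype"] = subtype
    return out


def screen_hypotheses(
    records: pd.DataFrame,
    rank_hi: float = 80.0,
    rank_lo: float = 20.0,
    fold_thresh: float = 2.0,
    median_utr_len: float | None = None,
    mean_rbs_score: float | None = None,
    is_med_or_high: bool = True,
) -> pd.DataFrame:
    """Per-record H1/H2/H3 flags (see module docstring).

    H2 only applies at medium/high stress; pass ``is_med_or_high=False`` for
    the low level and the flag stays False.  H3 records also get ``long_utr``
    (5'UTR above the genome median) and ``strong_rbs`` (score above the
    genome mean) annotations when the reference values are supplied.
    """
    out = records.copy()
    pcat = out["protein_category"]
    mrna_nonsig_both = (out["mrna_category_microarray"] == "nonsig") & (
        out["mrna_category_rnaseq"] == "nonsig"
    )

    out["H1"] = (
        (out["mrna_rank_stress"] >= rank_hi)
        & (out["mrna_rank_control"] >= rank_hi)
        & (out["protein_rank_stress"] <= rank_lo)
        & (out["protein_rank_control"] <= rank_lo)
    ).fillna(False)

    mrna_up_any = (out["mrna_category_microarray"] == "up") | (
        out["mrna_category_rnaseq"] == "up"
    )
    protein_low = pcat.isin(["down", "control_only"])
    out["H2"] = (mrna_up_any & protein_low & is_med_or_high).fillna(False)

    out["H3"] = ((pcat == "up") & mrna_nonsig_both).fillna(False)
    if median_utr_len is not None:
        out["long_utr"] = out["H3"] & (out["utr_len"] > median_utr_len)
    if mean_rbs_score is not None:
        out["strong_rbs"] = out["H3"] & (out["rbs_score"] > mean_rbs_score)
    return out


def screen_revised(
    records: pd.DataFrame,
    mrna_rank_lt: float = 60.0,
    protein_rank_gt: float = 80.0,
) -> pd.DataFrame:
    """Abundance-percentile screens (strict inequalities).

    ``rev_lowM_highP``: mRNA rank < ``mrna_rank_lt`` and protein rank >
    ``protein_rank_gt`` with the protein up or stress-only.  The mirrored
    ``rev_highM_lowP`` uses mRNA rank > ``protein_rank_gt`` and protein rank
    < ``mrna_rank_lt`` (or the protein undetected under stress) with the
    protein down or control-only.
    """
    out = records.copy()
    pcat = out["protein_category"]
    m, p = out["mrna_rank_stress"], out["protein_rank_stress"]
    out["rev_lowM_highP"] = (
        (m < mrna_rank_lt) & (p > protein_rank_gt) & pcat.isin(["up", "stress_only"])
    ).fillna(False)
    low_protein = (p < mrna_rank_lt) | p.isna()
    out["rev_highM_lowP"] = (
        (m > protein_rank_gt) & low_protein & pcat.isin(["down", "control_only"])
    ).fillna(False)
    return out


def pearson_by_category(
    records: pd.DataFrame,
    x_col: str,
    y_col: str,
    categories: tuple = ("up", "down", "nonsig"),
) -> pd.Series:
    """Sample Pearson r of two fold-change columns within each category.

    Exclusive-detection categories have no fold change (no standard
    deviation) and are excluded by construction; a category with fewer than
    3 complete pairs reports NaN.
    """
    out = {}
    for cat in categories:
        sub = records.loc[records["protein_category"] == cat, [x_col, y_col]].dropna()
        if len(sub) < 3 or sub[x_col].std() == 0 or sub[y_col].std() == 0:
            out[cat] = np.nan
        else:
            out[cat] = float(stats.pearsonr(sub[x_col], sub[y_col])[0])
    return pd.Series(out, name=f"r({x_col},{y_col})")


def cog_enrichment(
    records: pd.DataFrame,
    cog: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher tests for up/down over-representation per COG letter.

    For each letter and direction, tests whether proteins of that category
    are over-represented inside the letter versus the rest of the
    categorised proteome; Benjamini-Hochberg across letters x directions.
    Labels: ``up-enriched``, ``down-enriched``, ``both`` or ``none``.
    """
    df = records.join(cog.rename("cog"), how="inner")
    df = df[df["cog"].astype(str) != ""]
    if df.empty:
        raise ValueError("no categorised protein carries a COG letter")
    letters = sorted(df["cog"].unique())
    rows = []
    for letter in letters:
        inside = df["cog"] == letter
        row = {"cog_letter": letter, "n_total": int(inside.sum())}
        for direction in ("up", "down"):
            is_dir = df["protein_category"] == direction
            a = int((inside & is_dir).sum())
            b = int((inside & ~is_dir).sum())
            c = int((~inside & is_dir).sum())
            d = int((~inside & ~is_dir).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            row[f"n_{direction}"] = a
            row[f"odds_{direction}"] = odds
            row[f"p_{direction}"] = p
        rows.append(row)
    out = pd.DataFrame(rows).set_index("cog_letter")
    pvals = np.concatenate([out["p_up"].to_numpy(), out["p_down"].to_numpy()])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out["q_up"] = qvals[: len(out)]
    out["q_down"] = qvals[len(out) :]
    sig_up = out["q_up"] <= fdr
    sig_down = out["q_down"] <= fdr
    out["label"] = np.select(
        [sig_up & sig_down, sig_up, sig_down],
        ["both", "up-enriched", "down-enriched"],
        default="none",
    )
    return out
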