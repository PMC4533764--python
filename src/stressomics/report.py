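"""Bookkeeping identities and publication-style summary tables.

Every number in a pipeline summary is recomputable from the stage outputs;
the helpers here hold the arithmetic conventions (inclusion-exclusion for
detected-set unions, exclusive-detection subtraction, row totals) so the
summaries and their tests share a single definition.
"""

from __future__ import annotations

import pandas as pd


def venn_union(n_a: int, n_b: int, n_both: int) -> int:
    """Size of the union of two detected sets by inclusion-exclusion."""
    if n_both > min(n_a, n_b):
        raise ValueError("intersection cannot exceed either set")
    return n_a + n_b - n_both


def detected_in_both_conditions(n_total: int, n_stress_only: int, n_control_only: int) -> int:
    """Proteins usable for differential expression: detected under both the
    stress and the control condition of one experiment."""
    n = n_total - n_stress_only - n_control_only
    if n < 0:
        raise ValueError("exclusive counts exceed the total")
    return n


def de_total(n_up: int, n_down: int) -> int:
    """Total differentially expressed proteins in one table row."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    return n_up + n_down


def summary_counts(de_summary: pd.DataFrame) -> dict:
    """Flatten a per-level DE summary into a plain dict for the run summary."""
    out = {}
    for level, row in de_summary.iterrows():
        out[str(level)] = {k: int(v) for k, v in row.items()}
        out[str(level)]["de_fold_total_check"] = de_total(
            int(row["de_fold_up"]), int(row["de_fold_down"])
        )
    return out
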