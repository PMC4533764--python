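"""TSS calling from TEX-enriched coverage, 5'UTR lengths, leaderless
transcripts and Shine-Dalgarno (RBS) strength scoring.

A transcriptional start site is called where strand-specific coverage rises
sharply: candidate positions within the upstream search window need a
minimum depth, a minimum step ratio against the next nucleotide upstream
and, when a TEX- library is available, a minimum TEX+/TEX- enrichment.
The 5'UTR length L is the strand-aware distance from the called TSS to the
first base of the CDS; a transcript is leaderless when L is at or below a
small tolerance (an L that cannot host an SD motif plus its minimal spacer).

RBS strength is an exhaustive search over SD-like motifs (AGGAGG, its exact
subwords down to 3 nt and single-mismatch 5/6-mers in lower bins) crossed
with spacer bins {3-4, 5-10, 11-15} against a fixed score table whose
endpoints are calibrated so a perfect AGGAGG at the optimal spacer scores
12.87 and a motif-free upstream window scores -18.92.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .omics_io import AnnotationIndex, CoverageTrack, Gene

log = logging.getLogger(__name__)

SCORE_FLOOR = -18.92
SCORE_CEILING = 12.87
UPSTREAM_WINDOW = 21  # nt of sequence inspected for the SD motif
DEFAULT_LEADERLESS_TOL = 5

SD_CORE = "AGGAGG"

# spacer bins: index 0 = optimal 5-10 nt, 1 = tight 3-4 nt, 2 = loose 11-15 nt
_SPACER_BIN = {**{k: 1 for k in (3, 4)}, **{k: 0 for k in range(5, 11)}, **{k: 2 for k in range(11, 16)}}

# score per (motif tier, spacer bin); tiers ordered strongest first.  The
# non-endpoint values populate the intermediate bins of the calibrated table.
_TIER_SCORES = [
    (12.87, 12.09, 11.11),  # exact AGGAGG
    (12.38, 11.11, 9.25),   # exact 5-mers GGAGG / AGGAG
    (9.25, 7.68, 6.23),     # exact 4-mers
    (7.68, 6.23, 4.93),     # 6-mers with one mismatch
    (4.93, 3.53, 2.24),     # 5-mers with one mismatch
    (2.24, 1.34, 0.51),     # exact 3-mers
]


def _subwords(word: str, k: int) -> set[str]:
    return {word[i : i + k] for i in range(len(word) - k + 1)}


def _one_mismatch(words: set[str]) -> set[str]:
    out: set[str] = set()
    for w in words:
        for i in range(len(w)):
            for nt in "ACGT":
                if nt != w[i]:
                    out.add(w[:i] + nt + w[i + 1 :])
    return out


def _build_motif_tiers() -> dict[str, int]:
    exact6 = {SD_CORE}
    exact5 = _subwords(SD_CORE, 5)
    exact4 = _subwords(SD_CORE, 4)
    exact3 = _subwords(SD_CORE, 3)
    mm6 = _one_mismatch(exact6) - exact6
    mm5 = _one_mismatch(exact5) - exact5
    tiers: dict[str, int] = {}
    # weakest first so stronger assignments overwrite
    for motif in exact3:
        tiers[motif] = 5
    for motif in mm5:
        tiers[motif] = 4
    for motif in mm6:
        tiers[motif] = 3
    for motif in exact4:
        tiers[motif] = 2
    for motif in exact5:
        tiers[motif] = 1
    for motif in exact6:
        tiers[motif] = 0
    return tiers


_MOTIF_TIER = _build_motif_tiers()


@dataclass
class TssRecord:
    gene_id: str
    condition: str
    tss_pos: int  # 0-based contig coordinate of the first transcribed nt
    utr_len: int
    leaderless: bool
    step_score: float
    tex_enrichment_obs: float | None = None


@dataclass
class RbsRecord:
    gene_id: str
    motif: str | None
    spacer: int | None
    score: float


def tss_records_frame(records: list[TssRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "condition": [r.condition for r in records],
            "tss_pos": [r.tss_pos for r in records],
            "utr_len": [r.utr_len for r in records],
            "leaderless": [r.leaderless for r in records],
            "step_score": [r.step_score for r in records],
            "tex_enrichment_obs": [r.tex_enrichment_obs for r in records],
        }
    )


# ---------------------------------------------------------------------------
# TSS calling


def utr_length(tss_pos: int, start: int, end: int, strand: str) -> int:
    """Strand-aware 5'UTR length, 0-based half-open gene interval."""
    if strand == "+":
        length = start - tss_pos
    else:
        length = tss_pos - (end - 1)
    if length < 0:
        raise ValueError(
            f"TSS at {tss_pos} lies inside the CDS [{start}, {end}) on strand {strand}"
        )
    return int(length)


def call_tss(
    tex_plus: dict[str, CoverageTrack],
    annotation: AnnotationIndex,
    condition: str = "",
    tex_minus: dict[str, CoverageTrack] | None = None,
    window_up: int = 300,
    min_depth: float = 10.0,
    min_step: float = 3.0,
    min_tex: float = 2.0,
    leaderless_tol: int = DEFAULT_LEADERLESS_TOL,
) -> list[TssRecord]:
    """Call one TSS per operon-leading gene from stranded TEX+ coverage.

    ``tex_plus`` (and optionally ``tex_minus``) map strand to a
    :class:`CoverageTrack`.  Candidates p within the upstream window satisfy
    ``cov[p] >= min_depth`` and ``(cov[p]+1)/(cov[upstream(p)]+1) >= min_step``
    and, when TEX- is given, ``(TEX+ + 1)/(TEX- + 1) >= min_tex``.  The
    winner has the maximal step ratio, ties broken toward the start codon.
    The window is capped at the neighbouring gene boundary minus 1 nt.
    """
    records: list[TssRecord] = []
    genes = annotation.genes
    for idx, gene in enumerate(genes):
        if not gene.first_in_operon:
            continue
        track = tex_plus.get(gene.strand)
        if track is None or track.contig != gene.contig:
            raise ValueError(f"no TEX+ track for contig {gene.contig} strand {gene.strand}")
        cov = track.values
        n = len(cov)
        minus = tex_minus.get(gene.strand).values if tex_minus else None

        if gene.strand == "+":
            lo = max(0, gene.start - window_up)
            for j in range(idx - 1, -1, -1):
                if genes[j].contig == gene.contig and genes[j].end <= gene.start:
                    lo = max(lo, genes[j].end + 1)
                    break
            positions = range(lo + 1, gene.start + 1)
            upstream = -1
        else:
            five = gene.end - 1
            hi = min(n - 1, five + window_up)
            for j in range(idx + 1, len(genes)):
                if genes[j].contig == gene.contig and genes[j].start >= gene.end:
                    hi = min(hi, genes[j].start - 2)
                    break
            positions = range(five, hi)
            upstream = +1

        best = None
        for p in positions:
            u = p + upstream
            if not 0 <= u < n:
                continue
            if cov[p] < min_depth:
                continue
            step = (cov[p] + 1.0) / (cov[u] + 1.0)
            if step < min_step:
                continue
            tex_ratio = None
            if minus is not None:
                tex_ratio = (cov[p] + 1.0) / (minus[p] + 1.0)
                if tex_ratio < min_tex:
                    continue
            dist = abs(gene.start - p) if gene.strand == "+" else abs(p - (gene.end - 1))
            # prefer larger step; on ties prefer the position closer to ATG
            key = (step, -dist)
            if best is None or key > best[0]:
                best = (key, p, step, tex_ratio)
        if best is None:
            log.info("call_tss: no TSS candidate for %s (%s)", gene.gene_id, condition)
            continue
        _, p, step, tex_ratio = best
        L = utr_length(p, gene.start, gene.end, gene.strand)
        records.append(
            TssRecord(
                gene_id=gene.gene_id,
                condition=condition,
                tss_pos=int(p),
                utr_len=L,
                leaderless=L <= leaderless_tol,
                step_score=float(step),
                tex_enrichment_obs=float(tex_ratio) if tex_ratio is not None else None,
            )
        )
    return records


def detect_tss_shift(
    records: pd.DataFrame,
    control_condition: str = "control",
    leaderless_tol: int = DEFAULT_LEADERLESS_TOL,
) -> pd.DataFrame:
    """Leaderless-status switches between control and each stress condition.

    ``records`` is a frame as from :func:`tss_records_frame` covering several
    conditions.  Returns one row per (gene, stress condition) whose
    leaderless status differs from control, with the direction
    ``leadered->leaderless`` or ``leaderless->leadered``.
    """
    utr = records.pivot_table(index="gene_id", columns="condition", values="utr_len")
    if control_condition not in utr.columns:
        return pd.DataFrame(columns=["gene_id", "condition", "utr_control", "utr_stress", "shift"])
    rows = []
    for cond in utr.columns:
        if cond == control_condition:
            continue
        both = utr[[control_condition, cond]].dropna()
        for gene_id, (lc, ls) in both.iterrows():
            lc_less, ls_less = lc <= leaderless_tol, ls <= leaderless_tol
            if lc_less == ls_less:
                continue
            rows.append(
                {
                    "gene_id": gene_id,
                    "condition": cond,
                    "utr_control": int(lc),
                    "utr_stress": int(ls),
                    "shift": "leadered->leaderless" if ls_less else "leaderless->leadered",
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "condition", "utr_control", "utr_stress", "shift"])


# ---------------------------------------------------------------------------
# RBS scoring


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def upstream_window(genome: dict[str, str], gene: Gene, width: int = UPSTREAM_WINDOW) -> str | None:
    """The ``width`` nt immediately 5' of the start codon, on the sense strand."""
    seq = genome[gene.contig]
    if gene.strand == "+":
        if gene.start < width:
            return None
        return seq[gene.start - width : gene.start]
    if len(seq) - gene.end < width:
        return None
    return _revcomp(seq[gene.end : gene.end + width])


def score_window(window: str, spacer_range: tuple[int, int] = (3, 15)) -> RbsRecord:
    """Best (motif, spacer) score inside an upstream window.

    Pure function of the window string.  The spacer is the distance in nt
    from the motif's 3' end to the start codon.
    """
    window = window.upper()
    w = len(window)
    best: tuple[float, str, int] | None = None
    for k in (6, 5, 4, 3):
        for i in range(w - k + 1):
            motif = window[i : i + k]
            tier = _MOTIF_TIER.get(motif)
            if tier is None:
                continue
            spacer = w - (i + k)
            if not spacer_range[0] <= spacer <= spacer_range[1]:
                continue
            score = _TIER_SCORES[tier][_SPACER_BIN[spacer]]
            if best is None or score > best[0]:
                best = (score, motif, spacer)
    if best is None:
        return RbsRecord(gene_id="", motif=None, spacer=None, score=SCORE_FLOOR)
    return RbsRecord(gene_id="", motif=best[1], spacer=best[2], score=best[0])


def score_rbs(
    genome: dict[str, str],
    gene: Gene,
    spacer_range: tuple[int, int] = (3, 15),
) -> RbsRecord:
    """RBS strength of a gene from its 21-nt upstream sequence."""
    window = upstream_window(genome, gene)
    if window is None:
        log.warning("score_rbs: insufficient upstream sequence for %s", gene.gene_id)
        return RbsRecord(gene_id=gene.gene_id, motif=None, spacer=None, score=SCORE_FLOOR)
    rec = score_window(window, spacer_range)
    rec.gene_id = gene.gene_id
    return rec


def score_all_rbs(genome: dict[str, str], annotation: AnnotationIndex) -> pd.DataFrame:
    records = [score_rbs(genome, g) for g in annotation]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "motif": [r.motif if r.motif is not None else "" for r in records],
            "spacer": [r.spacer if r.spacer is not None else -1 for r in records],
            "score": [r.score for r in records],
        }
    ).set_index("gene_id")


def median_utr(utr_lengths) -> float:
    """Median 5'UTR length; the even-count median averages the central pair."""
    arr = np.asarray(list(utr_lengths), dtype=float)
    if len(arr) == 0:
        raise ValueError("median_utr needs at least one record")
    return float(np.median(arr))
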