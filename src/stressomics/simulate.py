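"""Synthetic multi-omic data with planted ground truth.

Emulates the study design of a metabolite-stress experiment in a
solventogenic clostridium: a miniature genome organised into operons, a
transcriptional start site (TSS) planted upstream of every operon-leading
gene, Shine-Dalgarno motifs at a fixed spacer, strand-specific coverage
tracks with and without TEX (5'-phosphate-dependent exonuclease) enrichment,
negative-binomial RNAseq counts, microarray log-ratios, and iTRAQ-style
protein ratios against a pooled reference with detection-limit censoring.

Every gene carries a planted expression class that determines how its mRNA
and protein respond to stress:

========================  =======================  ==========================
class                     mRNA under stress        protein under stress
========================  =======================  ==========================
``conc_up``               up (8-fold)              up (concordant)
``conc_down``             down (8-fold)            down (concordant)
``disc_protein_up``       flat                     up (translation boost)
``disc_protein_down``     up (4-fold)              down (translation loss)
``stress_only``           flat, well expressed     below detection in control,
                                                   detected under stress
``control_only``          flat, well expressed     detected in control, below
                                                   detection under stress
``nonsig``                flat                     flat
========================  =======================  ==========================

The class is assigned once per gene and applied to both stressors and all
three stress levels; baseline abundance and translation efficiency are
physical properties of the gene shared across the two stress experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omics_io import AnnotationIndex, CoverageTrack, Gene

CLASSES = (
    "conc_up",
    "conc_down",
    "disc_protein_up",
    "disc_protein_down",
    "stress_only",
    "control_only",
    "nonsig",
)

#: planted discordant fraction = disc_protein_down + stress_only + control_only
DEFAULT_CLASS_FRACTIONS = {
    "conc_up": 0.10,
    "conc_down": 0.10,
    "disc_protein_up": 0.06,
    "disc_protein_down": 0.08,
    "stress_only": 0.10,
    "control_only": 0.08,
    "nonsig": 0.48,
}

# log2 effect sizes per class (identical at low/med/high stress)
_MRNA_LFC = {"conc_up": 3.0, "conc_down": -3.0, "disc_protein_down": 2.0}
_BOOST_LOG2 = {
    "disc_protein_up": 3.0,
    "disc_protein_down": -4.0,
    "stress_only": 8.0,
    "control_only": -7.0,
}
# stress_only proteins are translated at a constitutively low efficiency so
# that they sit far below the detection limit without stress
_EFF_LOG2 = {"stress_only": -8.0}

SD_MOTIF = "AGGAGG"
COG_LETTERS = "CDEFGHIJKLMNOPQRSTUV"

_NT = np.array(list("ACGT"))
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_CODONS = [c for c in _CODONS if c not in ("TAA", "TAG", "TGA")]


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic experiment."""

    n_genes: int = 300
    leaderless_fraction: float = 0.2
    utr_median: float = 42.0  # nt, lognormal median of leadered 5'UTRs
    utr_sigma: float = 0.6
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    detection_limit: float = 0.15  # abundance quantile censored per sample
    noise_sd_protein: float = 0.25  # log2 units
    noise_sd_mrna: float = 0.25
    replicates: int = 3
    protein_timepoints: tuple = (15, 45, 75)
    rna_timepoints: tuple = (15, 30, 60, 75)
    stressors: tuple = ("BuOH", "BA")
    levels: tuple = ("low", "med", "high")
    dispersion: float = 0.05  # NB dispersion shared across genes
    operon_mean_size: float = 2.5
    tss_shift_fraction: float = 0.05
    sd_spacer: int = 7  # nt between SD 3' end and start codon
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 20:
            raise GeneratorError("n_genes too small to place operons (need >= 20)")
        for name in ("leaderless_fraction", "detection_limit", "tss_shift_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorError(f"{name} must be in [0, 1], got {v}")
        fr = self.class_fractions
        if set(fr) != set(CLASSES):
            raise GeneratorError(f"class_fractions must cover exactly {CLASSES}")
        if any(p < 0 for p in fr.values()) or not math.isclose(sum(fr.values()), 1.0, abs_tol=1e-9):
            raise GeneratorError("class fractions must be non-negative and sum to 1")
        if self.replicates < 1:
            raise GeneratorError("replicates must be >= 1")

    @property
    def conditions(self) -> tuple:
        """Coverage conditions: control plus the high level of each stressor."""
        return ("control",) + tuple(f"{s}_high" for s in self.stressors)


def _draw_utr(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    utr = int(round(rng.lognormal(math.log(cfg.utr_median), cfg.utr_sigma)))
    # a leadered UTR must host the SD motif (6 nt) plus the minimal spacer
    return int(np.clip(utr, 13, 250))


def generate_genome(config: GeneratorConfig):
    """Build genome sequence, annotation and planted truth.

    Returns ``(genome, annotation, truth)`` where ``genome`` maps contig name
    to sequence, ``annotation`` is an :class:`AnnotationIndex` and ``truth`` a
    per-gene DataFrame holding every planted quantity.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng((cfg.seed, 11))

    # operon sizes: geometric with mean operon_mean_size
    p = 1.0 / cfg.operon_mean_size
    sizes: list[int] = []
    total = 0
    while total < cfg.n_genes:
        k = int(rng.geometric(p))
        k = min(k, cfg.n_genes - total)
        sizes.append(k)
        total += k

    conditions = cfg.conditions
    genes: list[Gene] = []
    rows: list[dict] = []
    chunks: list[str] = []
    offset = 0
    gene_no = 0
    for op_no, size in enumerate(sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        operon_id = f"op{op_no:04d}"
        lengths = [3 * int(rng.integers(100, 301)) for _ in range(size)]

        # 5'UTR of the leading gene, per condition
        leaderless_base = rng.random() < cfg.leaderless_fraction
        if leaderless_base:
            utr_base = 0
        else:
            utr_base = _draw_utr(rng, cfg)
        utrs = {c: utr_base for c in conditions}
        shifted = rng.random() < cfg.tss_shift_fraction
        if shifted:
            if leaderless_base and cfg.leaderless_fraction < 1.0:
                alt = _draw_utr(rng, cfg)  # leaderless -> leadered under stress
            elif not leaderless_base and cfg.leaderless_fraction > 0.0:
                alt = 0  # leadered -> leaderless under stress
            else:
                alt = utr_base
            for c in conditions:
                if c != "control":
                    utrs[c] = alt

        utr_max = max(utrs.values())
        margin_up = 60
        seg: list[str] = ["".join(rng.choice(_NT, size=margin_up + utr_max))]
        pos = margin_up + utr_max  # local start codon of the leading gene
        local_genes: list[tuple[int, int]] = []
        local_sd: list[bool] = []
        for i, glen in enumerate(lengths):
            if i > 0:
                gap = "".join(rng.choice(_NT, size=25))
                seg.append(gap)
                pos += 25
            has_sd = i > 0 or utr_max > 0  # all-leaderless leading genes lack an SD
            if has_sd:
                # overwrite the SD motif at the configured spacer upstream of ATG
                head = seg.pop()
                cut = len(head) - cfg.sd_spacer - len(SD_MOTIF)
                head = head[:cut] + SD_MOTIF + head[cut + len(SD_MOTIF):]
                seg.append(head)
            body = "ATG" + "".join(rng.choice(_CODONS, size=glen // 3 - 2)) + "TAA"
            seg.append(body)
            local_genes.append((pos, pos + glen))
            local_sd.append(has_sd)
            pos += glen
        seg.append("".join(rng.choice(_NT, size=40)))
        segment = "".join(seg)
        seg_len = len(segment)

        if strand == "-":
            segment = _revcomp(segment)

        tss_local = {c: (margin_up + utr_max) - utrs[c] for c in conditions}
        for i, (a, b) in enumerate(local_genes):
            gene_no += 1
            gene_id = f"CAS{gene_no:04d}"
            if strand == "+":
                g_start, g_end = offset + a, offset + b
            else:
                g_start, g_end = offset + seg_len - b, offset + seg_len - a
            first = i == 0
            row = {
                "gene_id": gene_id,
                "strand": strand,
                "operon_id": operon_id,
                "first_in_operon": first,
                "start": g_start,
                "end": g_end,
                "cog": rng.choice(list(COG_LETTERS)),
                "sd_motif_planted": SD_MOTIF if local_sd[i] else "",
            }
            for c in conditions:
                if first:
                    row[f"utr_{c}"] = utrs[c]
                    t = tss_local[c]
                    row[f"tss_{c}"] = offset + t if strand == "+" else offset + seg_len - 1 - t
                else:
                    row[f"utr_{c}"] = pd.NA
                    row[f"tss_{c}"] = pd.NA
            rows.append(row)
            genes.append(
                Gene(gene_id, "chr", strand, g_start, g_end, operon_id, first, row["cog"])
            )
        chunks.append(segment)
        offset += seg_len

    genome = {"chr": "".join(chunks)}
    truth = pd.DataFrame(rows).set_index("gene_id")
    for c in conditions:
        truth[f"utr_{c}"] = truth[f"utr_{c}"].astype("Int64")
        truth[f"tss_{c}"] = truth[f"tss_{c}"].astype("Int64")

    _assign_classes(truth, cfg)
    return genome, AnnotationIndex(genes), truth


def _assign_classes(truth: pd.DataFrame, cfg: GeneratorConfig) -> None:
    rng = np.random.default_rng((cfg.seed, 12))
    n = len(truth)
    probs = np.array([cfg.class_fractions[c] for c in CLASSES])
    cls = rng.choice(CLASSES, size=n, p=probs)
    truth["true_class"] = cls
    for level in cfg.levels:
        truth[f"class_{level}"] = cls  # effect identical at every stress level

    # effect-class genes live in the detectable abundance stratum so the
    # planted label is identifiable despite detection-limit censoring
    base_nonsig = rng.normal(8.0, 2.5, size=n)
    base_effect = rng.normal(10.0, 1.5, size=n)
    # exclusive-detection genes are planted with clearly good mRNA levels
    # (above the genome median) so the "despite good mRNA" pattern holds
    base_exclusive = rng.normal(11.0, 0.8, size=n)
    is_nonsig = cls == "nonsig"
    is_exclusive = np.isin(cls, ["stress_only", "control_only"])
    truth["baseline_log2"] = np.where(
        is_nonsig, base_nonsig, np.where(is_exclusive, base_exclusive, base_effect)
    )
    truth["eff_log2"] = np.array([_EFF_LOG2.get(c, 0.0) for c in cls])
    truth["boost_log2"] = np.array([_BOOST_LOG2.get(c, 0.0) for c in cls])
    truth["translation_boost"] = 2.0 ** truth["boost_log2"]
    truth["mrna_lfc"] = np.array([_MRNA_LFC.get(c, 0.0) for c in cls])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# coverage


def generate_coverage(
    annotation: AnnotationIndex,
    truth: pd.DataFrame,
    genome_length: int,
    depth: float = 50.0,
    tex_enrichment: float = 5.0,
    background: float = 0.5,
    conditions: tuple | None = None,
    seed: int = 0,
) -> dict:
    """Strand-specific TEX+/TEX- coverage per condition.

    Coverage rises sharply at the planted TSS of each operon and runs through
    the operon; the TEX+ library multiplies the mean depth of the first 5 nt
    downstream of the TSS by ``tex_enrichment``.  Poisson noise throughout.
    Returns ``{(condition, strand, library): CoverageTrack}``.
    """
    if depth <= 0:
        raise GeneratorError(f"depth must be > 0, got {depth}")
    if conditions is None:
        conditions = tuple(
            c.removeprefix("tss_") for c in truth.columns if c.startswith("tss_")
        )
    rng = np.random.default_rng((seed, 13))
    operon_end = {}
    operon_start = {}
    for g in annotation:
        operon_end[g.operon_id] = max(operon_end.get(g.operon_id, 0), g.end)
        operon_start[g.operon_id] = min(operon_start.get(g.operon_id, genome_length), g.start)

    tracks = {}
    firsts = truth[truth["first_in_operon"]]
    for cond in conditions:
        mean = {s: np.full(genome_length, background) for s in "+-"}
        for _gene_id, row in firsts.iterrows():
            tss = int(row[f"tss_{cond}"])
            strand = row["strand"]
            if strand == "+":
                span = slice(tss, operon_end[row["operon_id"]])
            else:
                span = slice(operon_start[row["operon_id"]], tss + 1)
            mean[strand][span] += depth
        for s in "+-":
            tminus = rng.poisson(mean[s]).astype(float)
            tplus_mean = mean[s].copy()
            for gene_id, row in firsts[firsts["strand"] == s].iterrows():
                tss = int(row[f"tss_{cond}"])
                if s == "+":
                    head = slice(tss, min(tss + 5, genome_length))
                else:
                    head = slice(max(tss - 4, 0), tss + 1)
                tplus_mean[head] = (tplus_mean[head] - background) * tex_enrichment + background
            tplus = rng.poisson(tplus_mean).astype(float)
            tracks[(cond, s, "TEX-")] = CoverageTrack("chr", s, tminus, "TEX-", cond)
            tracks[(cond, s, "TEX+")] = CoverageTrack("chr", s, tplus, "TEX+", cond)
    return tracks


# ---------------------------------------------------------------------------
# expression


def _protein_columns(cfg: GeneratorConfig) -> list[str]:
    return [
        f"{s}_{lv}_{t}_{r}"
        for s in cfg.stressors
        for lv in ("control",) + tuple(cfg.levels)
        for t in cfg.protein_timepoints
        for r in range(1, cfg.replicates + 1)
    ]


def _rna_columns(cfg: GeneratorConfig) -> list[str]:
    return [
        f"{s}_{lv}_{t}_{r}"
        for s in cfg.stressors
        for lv in ("control",) + tuple(cfg.levels)
        for t in cfg.rna_timepoints
        for r in range(1, cfg.replicates + 1)
    ]


def _array_columns(cfg: GeneratorConfig) -> list[str]:
    return [
        f"{s}_{lv}_{t}_{r}"
        for s in cfg.stressors
        for lv in cfg.levels
        for t in cfg.rna_timepoints
        for r in range(1, cfg.replicates + 1)
    ]


def generate_expression(truth: pd.DataFrame, config: GeneratorConfig):
    """RNAseq counts, microarray log-ratios and the censored protein table.

    Counts are negative-binomially distributed around the planted mRNA mean;
    microarray values are the true mRNA log2 fold change plus Gaussian noise;
    protein abundance is mRNA abundance scaled by the gene's translation
    efficiency and stress boost with lognormal noise, censored below the
    per-sample ``detection_limit`` abundance quantile, and reported as a
    ratio to the per-stressor pooled reference (the mean of all samples of
    that stress experiment, control included).

    Returns ``(counts, microarray, ratios, intensities)``; ``intensities``
    is the reporter-intensity abundance table censored identically to the
    ratio table — the quantity the percentile abundance ranking of the
    protein layer is computed from.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng((cfg.seed, 14))
    n = len(truth)
    base = truth["baseline_log2"].to_numpy(float)
    mrna_lfc = truth["mrna_lfc"].to_numpy(float)
    eff = truth["eff_log2"].to_numpy(float)
    boost = truth["boost_log2"].to_numpy(float)

    # --- RNAseq counts --------------------------------------------------
    rna_cols = _rna_columns(cfg)
    counts = np.empty((n, len(rna_cols)), dtype=np.int64)
    for j, col in enumerate(rna_cols):
        _stressor, level, _t, _r = col.split("_")
        lfc = mrna_lfc if level != "control" else np.zeros(n)
        sf = 2.0 ** rng.normal(0.0, 0.15)
        mu = (2.0 ** (base + lfc)) * sf
        if cfg.dispersion > 0:
            lam = rng.gamma(1.0 / cfg.dispersion, mu * cfg.dispersion)
            counts[:, j] = rng.poisson(lam)
        else:
            counts[:, j] = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=truth.index, columns=rna_cols)

    # --- microarray log-ratios ------------------------------------------
    arr_cols = _array_columns(cfg)
    arr = np.empty((n, len(arr_cols)))
    for j, col in enumerate(arr_cols):
        _stressor, level, _t, _r = col.split("_")
        arr[:, j] = mrna_lfc + rng.normal(0.0, cfg.noise_sd_mrna, size=n)
    array_df = pd.DataFrame(arr, index=truth.index, columns=arr_cols)

    # --- iTRAQ protein ratios -------------------------------------------
    prot_cols = _protein_columns(cfg)
    abund = np.empty((n, len(prot_cols)))
    for j, col in enumerate(prot_cols):
        _stressor, level, _t, _r = col.split("_")
        if level == "control":
            lfc_p = np.zeros(n)
        else:
            lfc_p = mrna_lfc + boost
        abund[:, j] = 2.0 ** (
            base + eff + lfc_p + rng.normal(0.0, cfg.noise_sd_protein, size=n)
        )
    abund_df = pd.DataFrame(abund, index=truth.index, columns=prot_cols)

    ratios = pd.DataFrame(index=truth.index, columns=prot_cols, dtype=float)
    for stressor in cfg.stressors:
        cols = [c for c in prot_cols if c.startswith(stressor + "_")]
        pool = abund_df[cols].mean(axis=1)  # pooled reference of this 4-plex set
        ratios[cols] = abund_df[cols].div(pool, axis=0)

    intensities = abund_df.copy()
    if cfg.detection_limit > 0:
        for col in prot_cols:
            thr = np.quantile(abund_df[col].to_numpy(), cfg.detection_limit)
            censored = abund_df[col] < thr
            ratios.loc[censored, col] = np.nan
            intensities.loc[censored, col] = np.nan
    return counts_df, array_df, ratios, intensities


# ---------------------------------------------------------------------------
# truth round-trip


_INT_COLS = ("start", "end")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", lineterminator="\n", na_rep="")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[""])
    for col in df.columns:
        if col.startswith(("utr_", "tss_")):
            df[col] = df[col].astype("Int64")
    if "sd_motif_planted" in df.columns:
        df["sd_motif_planted"] = df["sd_motif_planted"].fillna("").astype(str)
    if "first_in_operon" in df.columns:
        df["first_in_operon"] = df["first_in_operon"].astype(bool)
    return df


def planted_category(truth: pd.DataFrame) -> pd.Series:
    """Expected five-way protein category for each planted class."""
    mapping = {
        "conc_up": "up",
        "conc_down": "down",
        "disc_protein_up": "up",
        "disc_protein_down": "down",
        "stress_only": "stress_only",
        "control_only": "control_only",
        "nonsig": "nonsig",
    }
    return truth["true_class"].map(mapping)
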