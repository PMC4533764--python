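"""Configuration-driven end-to-end runs and the planted-truth validation.

``run_pipeline`` executes every stage on files (simulated or real) and
writes one TSV per stage plus a JSON summary whose every number is
recomputable from those TSVs.  ``simulate_and_validate`` generates a
synthetic dataset with planted ground truth, runs the full pipeline on the
written files (exercising all readers), and scores recovery: a confusion
matrix of planted versus called protein categories, H3 sensitivity and
precision, TSS recovery within a small tolerance, and the discordant
fraction against the planted one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import integrate as integ
from . import omics_io as oio
from . import proteome, report, simulate, transcript, tss_rbs

log = logging.getLogger(__name__)

LEVELS = ("low", "med", "high")
_STRAND_TOKEN = {"+": "fwd", "-": "rev"}
_LIB_TOKEN = {"TEX+": "texplus", "TEX-": "texminus"}


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run; round-trips through YAML."""

    genome_fasta: str = ""
    annotation_gff3: str = ""
    protein_ratios_tsv: str = ""
    protein_intensity_tsv: str = ""
    rnaseq_counts_tsv: str = ""
    microarray_tsv: str = ""
    coverage_dir: str = ""  # empty -> TSS stage skipped with a warning
    coverage_conditions: tuple = ()
    stressors: tuple = ("BuOH", "BA")
    levels: tuple = LEVELS
    fdr: float = 0.05
    fold: float = 2.0
    rank_hi: float = 80.0
    rank_lo: float = 20.0
    rev_mrna_rank_lt: float = 60.0
    rev_protein_rank_gt: float = 80.0
    good_mrna_rank: float = 50.0
    leaderless_tol: int = 5
    stress_only_display: float = proteome.STRESS_ONLY_DISPLAY
    control_only_display: float = proteome.CONTROL_ONLY_DISPLAY
    reference_mrna: str = "microarray"
    min_detect: int = 1
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.fold < 1:
            raise ValueError("fold threshold must be >= 1")
        for name in ("rank_hi", "rank_lo", "rev_mrna_rank_lt", "rev_protein_rank_gt",
                     "good_mrna_rank"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentile in [0, 100]")
        if self.leaderless_tol < 0:
            raise ValueError("leaderless_tol must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        tuple_fields = {f.name for f in fields(cls) if isinstance(getattr(cls, f.name, None), tuple)
                        or f.name in ("stressors", "levels", "coverage_conditions")}
        for k in list(d):
            if k in tuple_fields and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _cols(df: pd.DataFrame, stressor: str, level: str) -> list[str]:
    prefix = f"{stressor}_{level}_"
    return [c for c in df.columns if c.startswith(prefix)]


def _array_de_call(array_df: pd.DataFrame, cols: list[str], fold: float, fdr: float) -> pd.DataFrame:
    """DE categories for microarray log-ratios (already stress-vs-control).

    One-sample t-test of the per-gene log-ratios against zero, BH-adjusted,
    with the usual fold filter on the mean log-ratio.
    """
    x = array_df[cols].to_numpy(float)
    lfc = x.mean(axis=1)
    t, p = stats.ttest_1samp(x, 0.0, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    thr = np.log2(fold)
    sig = q <= fdr
    cat = np.where(sig & (lfc >= thr), "up", np.where(sig & (lfc <= -thr), "down", "nonsig"))
    return pd.DataFrame({"log2fc": lfc, "p": p, "q": q, "category": cat}, index=array_df.index)


# ---------------------------------------------------------------------------
# stages


@_stage("load_inputs")
def _load_inputs(cfg: PipelineConfig) -> dict:
    data = {
        "genome": oio.read_fasta(cfg.genome_fasta),
        "annotation": oio.read_gff3(cfg.annotation_gff3),
        "ratios": oio.read_matrix(cfg.protein_ratios_tsv, "protein_ratio"),
        "counts": oio.read_matrix(cfg.rnaseq_counts_tsv, "counts"),
        "array": oio.read_matrix(cfg.microarray_tsv, "log_ratio"),
    }
    if cfg.protein_intensity_tsv:
        data["intensity"] = oio.read_matrix(cfg.protein_intensity_tsv, "protein_ratio")
    else:
        data["intensity"] = None
    if cfg.coverage_dir:
        covdir = Path(cfg.coverage_dir)
        lengths = {c: len(s) for c, s in data["genome"].items()}
        tracks = {}
        for cond in cfg.coverage_conditions:
            for strand, stok in _STRAND_TOKEN.items():
                for lib, ltok in _LIB_TOKEN.items():
                    p = covdir / f"coverage_{cond}_{stok}_{ltok}.bedgraph"
                    per_contig = oio.read_bedgraph(p, lengths, strand, lib, cond)
                    for contig, track in per_contig.items():
                        tracks[(cond, contig, strand, lib)] = track
        data["coverage"] = tracks
    else:
        data["coverage"] = None
    return data


@_stage("proteome_de")
def _proteome_stage(cfg: PipelineConfig, ratios: pd.DataFrame) -> dict:
    """SAM + classification per stressor and level; Table-1-style summary."""
    log2 = proteome.normalize_ratios(ratios)
    out: dict[str, dict] = {}
    for stressor in cfg.stressors:
        control_cols = _cols(ratios, stressor, "control")
        records_by_level = {}
        for level in cfg.levels:
            stress_cols = _cols(ratios, stressor, level)
            sam = proteome.sam_test(
                log2, stress_cols, control_cols,
                n_perm=cfg.n_perm, fdr_target=cfg.fdr, seed=cfg.seed,
            )
            rec = proteome.classify_proteins(
                ratios, stress_cols, control_cols, sam,
                fold_up=cfg.fold, min_detect=cfg.min_detect,
            )
            records_by_level[level] = rec
        out[stressor] = {
            "records": records_by_level,
            "summary": proteome.summarize_de(records_by_level),
        }
    return out


@_stage("transcript_quant")
def _transcript_stage(cfg: PipelineConfig, counts: pd.DataFrame, array: pd.DataFrame) -> dict:
    norm, sf = transcript.normalize_counts(counts)
    out: dict[str, dict] = {"size_factors": sf}
    for stressor in cfg.stressors:
        control_cols = _cols(counts, stressor, "control")
        per_level = {}
        for level in cfg.levels:
            stress_cols = _cols(counts, stressor, level)
            rnaseq_de = transcript.de_call_mrna(
                norm, stress_cols, control_cols,
                fold=cfg.fold, fdr=cfg.fdr, n_perm=cfg.n_perm, seed=cfg.seed,
            )
            array_cols = _cols(array, stressor, level)
            array_de = _array_de_call(array, array_cols, cfg.fold, cfg.fdr)
            per_level[level] = {
                "rnaseq": rnaseq_de,
                "microarray": array_de,
                "mrna_rank_stress": transcript.percentile_rank(norm[stress_cols]),
                "mrna_rank_control": transcript.percentile_rank(norm[control_cols]),
            }
        out[stressor] = per_level
    return out


@_stage("tss_rbs")
def _tss_stage(cfg: PipelineConfig, genome: dict, annotation, coverage) -> dict:
    rbs = tss_rbs.score_all_rbs(genome, annotation)
    out = {"rbs": rbs, "mean_rbs": float(rbs["score"].mean())}
    if coverage is None:
        log.warning("tss stage: no coverage tracks supplied; TSS/UTR calling skipped")
        out["tss"] = None
        out["shifts"] = None
        out["median_utr"] = None
        return out
    contigs = {g.contig for g in annotation}
    all_records = []
    for cond in cfg.coverage_conditions:
        for contig in contigs:
            tex_plus = {s: coverage[(cond, contig, s, "TEX+")] for s in "+-"}
            tex_minus = {s: coverage[(cond, contig, s, "TEX-")] for s in "+-"}
            all_records.extend(
                tss_rbs.call_tss(
                    tex_plus, annotation, condition=cond, tex_minus=tex_minus,
                    leaderless_tol=cfg.leaderless_tol,
                )
            )
    tss = tss_rbs.tss_records_frame(all_records)
    out["tss"] = tss
    out["shifts"] = tss_rbs.detect_tss_shift(tss, leaderless_tol=cfg.leaderless_tol)
    control = tss[tss["condition"] == "control"]
    out["median_utr"] = (
        tss_rbs.median_utr(control["utr_len"]) if len(control) else None
    )
    return out


@_stage("integrate")
def _integrate_stage(cfg, prot, trans, tssr, ratios, intensity, annotation) -> dict:
    cog = annotation.to_frame()["cog"]
    out: dict[str, dict] = {}
    for stressor in cfg.stressors:
        control_cols = _cols(ratios, stressor, "control")
        per_level = {}
        for level in cfg.levels:
            stress_cols = _cols(ratios, stressor, level)
            rec = prot[stressor]["records"][level]
            tl = trans[stressor][level]
            if intensity is not None:
                prank_s = transcript.percentile_rank(intensity[stress_cols])
                prank_c = transcript.percentile_rank(intensity[control_cols])
            else:
                prank_s = prank_c = None
            utr = _utr_series(tssr, stressor)
            joined = integ.join_omics(
                rec,
                {"microarray": tl["microarray"], "rnaseq": tl["rnaseq"]},
                protein_rank_stress=prank_s,
                protein_rank_control=prank_c,
                mrna_rank_stress=tl["mrna_rank_stress"],
                mrna_rank_control=tl["mrna_rank_control"],
                utr_len=utr,
                rbs_score=tssr["rbs"]["score"],
            )
            joined = integ.call_discordance(
                joined, fold_thresh=cfg.fold, good_mrna_rank=cfg.good_mrna_rank,
                reference=cfg.reference_mrna,
            )
            joined = integ.screen_hypotheses(
                joined, rank_hi=cfg.rank_hi, rank_lo=cfg.rank_lo, fold_thresh=cfg.fold,
                median_utr_len=tssr["median_utr"], mean_rbs_score=tssr["mean_rbs"],
                is_med_or_high=level in ("med", "high"),
            )
            joined = integ.screen_revised(
                joined, mrna_rank_lt=cfg.rev_mrna_rank_lt,
                protein_rank_gt=cfg.rev_protein_rank_gt,
            )
            joined["protein_log2fc"] = np.log2(joined["fold_change"])
            correlations = pd.DataFrame(
                {
                    "protein_vs_microarray": integ.pearson_by_category(
                        joined, "protein_log2fc", "mrna_log2fc_microarray"
                    ),
                    "protein_vs_rnaseq": integ.pearson_by_category(
                        joined, "protein_log2fc", "mrna_log2fc_rnaseq"
                    ),
                    "microarray_vs_rnaseq": integ.pearson_by_category(
                        joined, "mrna_log2fc_microarray", "mrna_log2fc_rnaseq"
                    ),
                }
            )
            cogtab = integ.cog_enrichment(joined, cog, fdr=cfg.fdr)
            per_level[level] = {"records": joined, "correlations": correlations, "cog": cogtab}
        out[stressor] = per_level
    return out


def _utr_series(tssr: dict, stressor: str) -> pd.Series | None:
    """Per-gene 5'UTR length: the stressor's high-stress call, else control."""
    tss = tssr.get("tss")
    if tss is None or tss.empty:
        return None
    pivot = tss.pivot_table(index="gene_id", columns="condition", values="utr_len")
    stress_cond = f"{stressor}_high"
    if stress_cond in pivot.columns:
        base = pivot[stress_cond]
        if "control" in pivot.columns:
            base = base.fillna(pivot["control"])
    elif "control" in pivot.columns:
        base = pivot["control"]
    else:
        return None
    return base


# ---------------------------------------------------------------------------
# run


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage, write stage TSVs, a JSON summary and a log file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("stressomics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cfg.to_yaml(outdir / "config_used.yaml")
        log.info("thresholds: fdr=%s fold=%s rank_hi=%s rank_lo=%s rev=<%s/>%s good_mrna=%s "
                 "leaderless_tol=%s sentinels=%s/%s",
                 cfg.fdr, cfg.fold, cfg.rank_hi, cfg.rank_lo, cfg.rev_mrna_rank_lt,
                 cfg.rev_protein_rank_gt, cfg.good_mrna_rank, cfg.leaderless_tol,
                 cfg.stress_only_display, cfg.control_only_display)
        data = _load_inputs(cfg)
        prot = _proteome_stage(cfg, data["ratios"])
        trans = _transcript_stage(cfg, data["counts"], data["array"])
        tssr = _tss_stage(cfg, data["genome"], data["annotation"], data["coverage"])
        res = _integrate_stage(cfg, prot, trans, tssr, data["ratios"],
                               data["intensity"], data["annotation"])
        summary = _write_outputs(cfg, outdir, data, prot, trans, tssr, res)
        return {"proteome": prot, "transcript": trans, "tss_rbs": tssr,
                "integration": res, "summary": summary}
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_outputs(cfg, outdir: Path, data, prot, trans, tssr, res) -> dict:
    summary: dict = {"thresholds": {
        "fdr": cfg.fdr, "fold": cfg.fold, "rank_hi": cfg.rank_hi, "rank_lo": cfg.rank_lo,
        "rev_mrna_rank_lt": cfg.rev_mrna_rank_lt, "rev_protein_rank_gt": cfg.rev_protein_rank_gt,
        "good_mrna_rank": cfg.good_mrna_rank, "leaderless_tol": cfg.leaderless_tol,
        "stress_only_display": cfg.stress_only_display,
        "control_only_display": cfg.control_only_display,
    }}

    # detected-proteome Venn by inclusion-exclusion, cross-checked directly
    ratios = data["ratios"]
    detected = {
        s: set(ratios.index[ratios[[c for c in ratios.columns if c.startswith(s + "_")]]
                            .notna().any(axis=1)])
        for s in cfg.stressors
    }
    if len(cfg.stressors) == 2:
        a, b = (detected[s] for s in cfg.stressors)
        union = report.venn_union(len(a), len(b), len(a & b))
        assert union == len(a | b)
        summary["venn"] = {
            "detected": {s: len(detected[s]) for s in cfg.stressors},
            "both": len(a & b),
            "union": union,
        }

    summary["proteome"] = {}
    for stressor in cfg.stressors:
        de_sum = prot[stressor]["summary"]
        oio.write_tsv(de_sum, outdir / f"de_summary_{stressor}.tsv")
        for level, rec in prot[stressor]["records"].items():
            oio.write_tsv(rec, outdir / f"de_proteins_{stressor}_{level}.tsv")
        n_total = len(detected[stressor])
        any_stress_only = set()
        any_control_only = set()
        for rec in prot[stressor]["records"].values():
            any_stress_only |= set(rec.index[rec["category"] == "stress_only"])
            any_control_only |= set(rec.index[rec["category"] == "control_only"])
        summary["proteome"][stressor] = {
            "detected": n_total,
            "stress_only_any_level": len(any_stress_only),
            "control_only_any_level": len(any_control_only),
            "used_for_de_union": report.detected_in_both_conditions(
                n_total, len(any_stress_only - any_control_only),
                len(any_control_only - any_stress_only)),
            "levels": report.summary_counts(de_sum),
        }

    oio.write_tsv(trans["size_factors"].to_frame(), outdir / "size_factors.tsv")

    if tssr["tss"] is not None:
        oio.write_tsv(tssr["tss"], outdir / "tss_records.tsv", index=False)
        oio.write_tsv(tssr["shifts"], outdir / "tss_shifts.tsv", index=False)
    oio.write_tsv(tssr["rbs"], outdir / "rbs_scores.tsv")
    summary["tss_rbs"] = {
        "median_utr": tssr["median_utr"],
        "mean_rbs_score": tssr["mean_rbs"],
        "n_tss": 0 if tssr["tss"] is None else int(len(tssr["tss"])),
        "n_leaderless": 0 if tssr["tss"] is None else int(tssr["tss"]["leaderless"].sum()),
        "n_shifts": 0 if tssr["shifts"] is None else int(len(tssr["shifts"])),
    }

    summary["integration"] = {}
    for stressor in cfg.stressors:
        per = {}
        for level in cfg.levels:
            rec = res[stressor][level]["records"]
            oio.write_tsv(rec, outdir / f"integration_{stressor}_{level}.tsv")
            oio.write_tsv(res[stressor][level]["correlations"],
                          outdir / f"correlations_{stressor}_{level}.tsv")
            oio.write_tsv(res[stressor][level]["cog"],
                          outdir / f"cog_enrichment_{stressor}_{level}.tsv")
            per[level] = {
                "n_records": int(len(rec)),
                "n_discordant": int(rec["discordant"].sum()),
                "discordant_fraction": float(rec["discordant"].mean()) if len(rec) else 0.0,
                "H1": int(rec["H1"].sum()),
                "H2": int(rec["H2"].sum()),
                "H3": int(rec["H3"].sum()),
                "H3_genes": sorted(rec.index[rec["H3"]]),
                "rev_lowM_highP": int(rec["rev_lowM_highP"].sum()),
                "rev_highM_lowP": int(rec["rev_highM_lowP"].sum()),
            }
        summary["integration"][stressor] = per

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# simulate + validate


def write_simulated_inputs(gen_cfg: simulate.GeneratorConfig, indir,
                           depth: float = 50.0, tex_enrichment: float = 5.0) -> PipelineConfig:
    """Generate a full synthetic dataset, write it to ``indir`` and return a
    :class:`PipelineConfig` pointing at the files."""
    indir = Path(indir)
    indir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = simulate.generate_genome(gen_cfg)
    counts, array, ratios, intensity = simulate.generate_expression(truth, gen_cfg)
    tracks = simulate.generate_coverage(
        annotation, truth, len(genome["chr"]), depth=depth,
        tex_enrichment=tex_enrichment, seed=gen_cfg.seed,
    )
    oio.write_fasta(genome, indir / "genome.fasta")
    oio.write_gff3(annotation, indir / "annotation.gff3")
    oio.write_matrix(counts, indir / "rnaseq_counts.tsv")
    oio.write_matrix(array, indir / "microarray.tsv")
    oio.write_matrix(ratios, indir / "protein_ratios.tsv")
    oio.write_matrix(intensity, indir / "protein_intensity.tsv")
    simulate.write_truth(truth, indir / "truth.tsv")
    for (cond, strand, lib), track in tracks.items():
        name = f"coverage_{cond}_{_STRAND_TOKEN[strand]}_{_LIB_TOKEN[lib]}.bedgraph"
        oio.write_bedgraph(track, indir / name)
    return PipelineConfig(
        genome_fasta=str(indir / "genome.fasta"),
        annotation_gff3=str(indir / "annotation.gff3"),
        protein_ratios_tsv=str(indir / "protein_ratios.tsv"),
        protein_intensity_tsv=str(indir / "protein_intensity.tsv"),
        rnaseq_counts_tsv=str(indir / "rnaseq_counts.tsv"),
        microarray_tsv=str(indir / "microarray.tsv"),
        coverage_dir=str(indir),
        coverage_conditions=gen_cfg.conditions,
        stressors=gen_cfg.stressors,
        levels=gen_cfg.levels,
        seed=gen_cfg.seed,
    )


def simulate_and_validate(gen_cfg: simulate.GeneratorConfig, outdir,
                          pipe_overrides: dict | None = None,
                          tss_tolerance_nt: int = 2) -> dict:
    """Planted-truth recovery report for the full pipeline.

    Returns a dict with the per-category confusion matrix, overall category
    accuracy, H3 sensitivity/precision, TSS recovery fraction and the
    called-vs-planted discordant fraction; all tables are also written as
    TSV under ``outdir``.
    """
    outdir = Path(outdir)
    cfg = write_simulated_inputs(gen_cfg, outdir / "inputs")
    if pipe_overrides:
        for k, v in pipe_overrides.items():
            setattr(cfg, k, v)
    result = run_pipeline(cfg, outdir / "run")
    truth = simulate.read_truth(outdir / "inputs" / "truth.tsv")
    expected = simulate.planted_category(truth)

    # confusion matrix over all (stressor, level, gene) classifications
    pairs = []
    for stressor in cfg.stressors:
        for level in cfg.levels:
            rec = result["proteome"][stressor]["records"][level]
            pairs.append(pd.DataFrame({
                "planted": expected.reindex(rec.index),
                "called": rec["category"],
            }))
    allpairs = pd.concat(pairs)
    confusion = pd.crosstab(allpairs["planted"], allpairs["called"])
    accuracy = float((allpairs["planted"] == allpairs["called"]).mean())

    # H3 recovery: planted disc_protein_up vs flagged H3 at med+high stress
    planted_h3 = set(truth.index[truth["true_class"] == "disc_protein_up"])
    called_h3 = set()
    for stressor in cfg.stressors:
        for level in ("med", "high"):
            rec = result["integration"][stressor][level]["records"]
            called_h3 |= set(rec.index[rec["H3"]])
    tp = len(planted_h3 & called_h3)
    h3_sensitivity = tp / len(planted_h3) if planted_h3 else float("nan")
    h3_precision = tp / len(called_h3) if called_h3 else float("nan")

    # TSS recovery per condition
    tss = result["tss_rbs"]["tss"]
    tss_recovery = {}
    if tss is not None:
        firsts = truth[truth["first_in_operon"]]
        for cond in cfg.coverage_conditions:
            sub = tss[tss["condition"] == cond].set_index("gene_id")
            true_pos = firsts[f"tss_{cond}"].astype(float)
            called_pos = sub["tss_pos"].reindex(firsts.index).astype(float)
            hit = (called_pos - true_pos).abs() <= tss_tolerance_nt
            tss_recovery[cond] = float(hit.fillna(False).mean())

    # discordant fraction: called vs planted (classes meeting the rule)
    planted_disc = truth["true_class"].isin(
        ["disc_protein_down", "stress_only", "control_only"]
    )
    disc = {}
    for stressor in cfg.stressors:
        rec = result["integration"][stressor]["high"]["records"]
        disc[stressor] = {
            "called_fraction": float(rec["discordant"].mean()) if len(rec) else 0.0,
            "planted_fraction": float(planted_disc.reindex(rec.index).mean()),
        }

    report_dict = {
        "category_accuracy": accuracy,
        "h3_sensitivity": h3_sensitivity,
        "h3_precision": h3_precision,
        "tss_recovery": tss_recovery,
        "discordance": disc,
    }
    valdir = outdir / "validation"
    valdir.mkdir(parents=True, exist_ok=True)
    oio.write_tsv(confusion, valdir / "confusion_matrix.tsv")
    with open(valdir / "recovery.json", "w", encoding="utf-8") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
    report_dict["confusion"] = confusion
    return report_dict
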