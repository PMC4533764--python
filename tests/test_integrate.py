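"""Joining, discordance calling, hypothesis and percentile screens,
correlations and COG enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from stressomics.integrate import (
    call_discordance,
    cog_enrichment,
    join_omics,
    pearson_by_category,
    screen_hypotheses,
    screen_revised,
)


def _protein_records(rows):
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["category", "fold_change", "display_value", "fdr_pass"],
    )
    df.index.name = "protein_id"
    return df


def _mrna(rows):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["log2fc", "category"])
    return df


def _record(**kw):
    """One integration record with sensible defaults, overridable."""
    base = dict(
        protein_category="nonsig", fold_change=1.0, protein_display_value=1.0,
        fdr_pass=False, mrna_category_microarray="nonsig", mrna_log2fc_microarray=0.0,
        mrna_category_rnaseq="nonsig", mrna_log2fc_rnaseq=0.0,
        protein_rank_stress=50.0, protein_rank_control=50.0,
        mrna_rank_stress=50.0, mrna_rank_control=50.0,
        utr_len=30.0, rbs_score=5.0,
    )
    base.update(kw)
    return pd.DataFrame([base], index=["g1"])


class TestJoin:
    mrna = {
        "microarray": _mrna({"g1": [2.0, "up"], "g2": [0.0, "nonsig"]}),
        "rnaseq": _mrna({"g1": [1.8, "up"], "g2": [0.1, "nonsig"]}),
    }

    def test_protein_only_gene_has_absent_mrna_fields(self):
        rec = _protein_records({"g9": ["up", 3.0, 3.0, True]})
        out = join_omics(rec, self.mrna)
        assert pd.isna(out.loc["g9", "mrna_category_microarray"])
        assert pd.isna(out.loc["g9", "mrna_log2fc_rnaseq"])

    def test_full_toy_join(self):
        rec = _protein_records({
            "g1": ["up", 3.0, 3.0, True],
            "g2": ["nonsig", 1.1, 1.1, False],
        })
        out = join_omics(rec, self.mrna,
                         mrna_rank_stress=pd.Series({"g1": 90.0, "g2": 10.0}))
        assert len(out) == 2
        assert out.loc["g1", "protein_category"] == "up"
        assert out.loc["g1", "mrna_category_microarray"] == "up"
        assert out.loc["g1", "mrna_rank_stress"] == 90.0
        assert out.loc["g2", "mrna_log2fc_rnaseq"] == 0.1

    def test_empty_protein_set_gives_empty_output(self):
        rec = _protein_records({})
        assert join_omics(rec, self.mrna).empty

    def test_duplicate_gene_ids_rejected(self):
        rec = pd.concat([_protein_records({"g1": ["up", 3.0, 3.0, True]})] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            join_omics(rec, self.mrna)


class TestDiscordance:
    def test_protein_up_mrna_down_is_discordant(self):
        rec = _record(protein_category="up", fold_change=3.0,
                      mrna_category_microarray="down", mrna_log2fc_microarray=-1.3)
        out = call_discordance(rec)
        assert bool(out["discordant"].iloc[0])
        assert out["discordance_subtype"].iloc[0] == "protein_up_mrna_down"

    def test_stress_only_with_good_mrna_is_discordant(self):
        rec = _record(protein_category="stress_only", fold_change=np.nan,
                      mrna_category_microarray="nonsig", mrna_rank_stress=80.0)
        out = call_discordance(rec)
        assert bool(out["discordant"].iloc[0])
        assert out["discordance_subtype"].iloc[0] == "exclusive_good_mrna"

    def test_stress_only_with_poor_mrna_is_not(self):
        rec = _record(protein_category="stress_only", mrna_rank_stress=20.0)
        assert not call_discordance(rec)["discordant"].iloc[0]

    def test_concordant_up_up(self):
        rec = _record(protein_category="up", mrna_category_microarray="up")
        assert not call_discordance(rec)["discordant"].iloc[0]


class TestHypotheses:
    def test_rubrerythrin_like_record_is_h3_long_utr_strong_rbs(self):
        rec = _record(protein_category="up", fold_change=16.0, fdr_pass=True,
                      utr_len=96.0, rbs_score=12.87)
        out = screen_hypotheses(rec, median_utr_len=42.0, mean_rbs_score=7.09)
        row = out.iloc[0]
        assert row["H3"] and row["long_utr"] and row["strong_rbs"]
        assert not row["H1"] and not row["H2"]

    def test_h1_requires_the_pattern_in_control_too(self):
        stress_only_pattern = _record(mrna_rank_stress=90.0, mrna_rank_control=40.0,
                                      protein_rank_stress=10.0, protein_rank_control=10.0)
        assert not screen_hypotheses(stress_only_pattern)["H1"].iloc[0]
        both = _record(mrna_rank_stress=90.0, mrna_rank_control=90.0,
                       protein_rank_stress=10.0, protein_rank_control=10.0)
        assert screen_hypotheses(both)["H1"].iloc[0]

    def test_h2_only_at_medium_or_high_stress(self):
        rec = _record(protein_category="down", mrna_category_microarray="up")
        assert screen_hypotheses(rec, is_med_or_high=True)["H2"].iloc[0]
        assert not screen_hypotheses(rec, is_med_or_high=False)["H2"].iloc[0]

    def test_record_failing_every_clause_gets_no_flags(self):
        out = screen_hypotheses(_record(), median_utr_len=42.0, mean_rbs_score=7.09)
        assert not out[["H1", "H2", "H3"]].any().any()


class TestRevised:
    def test_low_mrna_high_protein_flagged(self):
        rec = _record(protein_category="up", mrna_rank_stress=55.0,
                      protein_rank_stress=85.0)
        assert screen_revised(rec)["rev_lowM_highP"].iloc[0]

    def test_boundary_rank_60_not_flagged(self):
        rec = _record(protein_category="up", mrna_rank_stress=60.0,
                      protein_rank_stress=85.0)
        assert not screen_revised(rec)["rev_lowM_highP"].iloc[0]

    def test_high_mrna_undetected_protein_mirror_flag(self):
        rec = _record(protein_category="control_only", mrna_rank_stress=90.0,
                      protein_rank_stress=np.nan)
        assert screen_revised(rec)["rev_highM_lowP"].iloc[0]


class TestPearson:
    def _recs(self, x, y, category="up"):
        return pd.DataFrame({
            "protein_category": [category] * len(x), "x": x, "y": y,
        })

    def test_identical_vectors_give_one(self):
        r = pearson_by_category(self._recs([1, 2, 3], [1, 2, 3]), "x", "y")
        assert r["up"] == pytest.approx(1.0)

    def test_exact_negatives_give_minus_one(self):
        r = pearson_by_category(self._recs([1, 2, 3], [-1, -2, -3]), "x", "y")
        assert r["up"] == pytest.approx(-1.0)

    def test_five_point_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r = pearson_by_category(self._recs(x, y), "x", "y")
        assert r["up"] == pytest.approx(expected)

    def test_invariant_to_order_and_affine_rescale(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = pearson_by_category(self._recs(x, y), "x", "y")["up"]
        shuffled = self._recs(x, y).sample(frac=1.0, random_state=1)
        assert pearson_by_category(shuffled, "x", "y")["up"] == pytest.approx(base)
        scaled = pearson_by_category(self._recs(3 * x + 7, y), "x", "y")["up"]
        assert scaled == pytest.approx(base)

    def test_fewer_than_three_pairs_reports_absent(self):
        r = pearson_by_category(self._recs([1, 2], [3, 4]), "x", "y")
        assert np.isnan(r["up"])

    def test_exclusive_categories_are_not_reported(self):
        r = pearson_by_category(self._recs([1, 2, 3], [1, 2, 3], "stress_only"), "x", "y")
        assert set(r.index) == {"up", "down", "nonsig"}


class TestCogEnrichment:
    def _records(self, cats, letters):
        rec = pd.DataFrame({"protein_category": cats},
                           index=[f"g{i}" for i in range(len(cats))])
        cog = pd.Series(letters, index=rec.index)
        return rec, cog

    def test_all_up_category_is_up_enriched(self):
        cats = ["up"] * 8 + ["up"] * 10 + ["nonsig"] * 90
        letters = ["J"] * 8 + ["C"] * 100
        rec, cog = self._records(cats, letters)
        out = cog_enrichment(rec, cog)
        assert out.loc["J", "label"] == "up-enriched"
        # hypergeometric tail by direct enumeration: all 8 up inside J
        n_up = 18
        p_expected = sum(
            comb(n_up, k) * comb(108 - n_up, 8 - k) for k in (8,)
        ) / comb(108, 8)
        assert out.loc["J", "p_up"] == pytest.approx(p_expected)

    def test_uniform_proportions_show_no_enrichment(self):
        cats = (["up"] * 2 + ["down"] * 2 + ["nonsig"] * 16) * 2
        letters = ["J"] * 20 + ["C"] * 20
        rec, cog = self._records(cats, letters)
        assert (cog_enrichment(rec, cog)["label"] == "none").all()

    def test_both_directions_label(self):
        cats = ["up"] * 10 + ["down"] * 10 + ["nonsig"] * 2 + ["nonsig"] * 150
        letters = ["J"] * 22 + ["C"] * 150
        rec, cog = self._records(cats, letters)
        assert cog_enrichment(rec, cog).loc["J", "label"] == "both"


class TestSyntheticInvariants:
    def _high_records(self, sim_run, stressor="BuOH"):
        return sim_run["result"]["integration"][stressor]["high"]["records"]

    def test_no_record_is_both_h3_and_rev_high_m_low_p(self, sim_run):
        rec = self._high_records(sim_run)
        assert not (rec["H3"] & rec["rev_highM_lowP"]).any()

    def test_h1_subset_of_relaxed_mirror_eligibility(self, sim_run):
        rec = self._high_records(sim_run)
        eligible = (rec["mrna_rank_stress"] >= 80.0) & (
            (rec["protein_rank_stress"] < 60.0) | rec["protein_rank_stress"].isna()
        )
        assert (~rec["H1"] | eligible).all()

    def test_h2_near_null_on_concordant_data(self):
        from stressomics import pipeline, simulate

        fr = {c: 0.0 for c in simulate.CLASSES}
        fr.update(conc_up=0.15, conc_down=0.15, nonsig=0.70)
        cfg = simulate.GeneratorConfig(n_genes=120, seed=31, stressors=("BuOH",),
                                       class_fractions=fr)
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            pc = pipeline.write_simulated_inputs(cfg, d + "/in")
            res = pipeline.run_pipeline(pc, d + "/run")
        rec = res["integration"]["BuOH"]["high"]["records"]
        assert rec["H2"].mean() <= 0.02


def test_discordant_fraction_recovers_planted_fraction():
    """Mean called discordant fraction across seeds stays within 0.05 of the
    planted one (disc_protein_down + exclusive-detection classes)."""
    from stressomics import pipeline, simulate
    import tempfile

    called, planted = [], []
    for seed in range(10):
        cfg = simulate.GeneratorConfig(n_genes=150, seed=seed, stressors=("BuOH",))
        with tempfile.TemporaryDirectory() as d:
            pc = pipeline.write_simulated_inputs(cfg, d + "/in")
            res = pipeline.run_pipeline(pc, d + "/run")
            truth = simulate.read_truth(d + "/in/truth.tsv")
        rec = res["integration"]["BuOH"]["high"]["records"]
        called.append(rec["discordant"].mean())
        planted.append(
            truth["true_class"].reindex(rec.index)
            .isin(["disc_protein_down", "stress_only", "control_only"]).mean()
        )
    assert abs(np.mean(called) - np.mean(planted)) <= 0.05
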