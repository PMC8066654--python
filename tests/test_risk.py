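"""Risk codings, GRS construction and the dose-response trend test."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from cravingqtl import (GeneticRiskScore, RiskCoding, RiskModel, SNPInfo,
                        assign_risk_coding, combined_report, compute_grs,
                        grs_trend_test, reference_panel, reference_risk_model)
from cravingqtl.risk import make_coding
from cravingqtl.scoring import ITEM_COLUMNS, score_table
from .conftest import toy_matrix


def _phen(values):
    n = len(values)
    df = pd.DataFrame(index=[f"s{i}" for i in range(n)])
    df["age"], df["sex"], df["bmi"] = 40.0, "male", 22.0
    base, rem = np.divmod(np.asarray(values, dtype=int), 14)
    for j, col in enumerate(ITEM_COLUMNS):
        df[col] = base + (j < rem)
    return score_table(df)


class TestReferenceModel:
    def test_max_score_is_six(self, ref_model):
        assert ref_model.max_score == 6

    def test_exhaustive_genotype_combinations_span_0_to_6(self, ref_model):
        """All 3^5 genotype combinations scored; range must be [0, 6]."""
        genos = [list(c.codes) for c in ref_model.codings]
        combos = list(itertools.product(*genos))
        calls = {c.snp_id: [combo[i] for combo in combos]
                 for i, c in enumerate(ref_model.codings)}
        m = toy_matrix(calls, [f"s{i}" for i in range(len(combos))])
        scores = compute_grs(m, ref_model).scores
        assert scores.min() == 0 and scores.max() == 6
        assert set(scores.astype(int)) == set(range(7))

    def test_published_zero_and_max_subjects(self, ref_model):
        m = toy_matrix({"rs2240158": ["T/T", "C/C", "C/T"],
                        "rs3983721": ["C/C", "T/T", "C/T"],
                        "rs6583954": ["C/C", "T/T", "C/T"],
                        "rs2129575": ["G/G", "T/T", "G/T"],
                        "rs174699": ["T/T", "C/C", "C/T"]},
                       ["zero", "max", "mid"])
        scores = compute_grs(m, ref_model).scores
        assert scores["zero"] == 0
        assert scores["max"] == 6
        assert scores["mid"] == 2   # 1 + 0 + 1 + 0 + 0


class TestComputeGrs:
    def snp_model(self):
        snp = SNPInfo("rs1", "G1", "A", "G")
        return RiskModel((make_coding(snp, "additive", "G"),))

    def test_missing_policy_exclude(self):
        m = toy_matrix({"rs1": ["A/G", "./."]}, ["s1", "s2"])
        grs = compute_grs(m, self.snp_model(), missing_policy="exclude")
        assert grs.scores["s1"] == 1 and np.isnan(grs.scores["s2"])
        assert grs.n_missing["s2"] == 1

    def test_missing_policy_partial(self):
        m = toy_matrix({"rs1": ["A/G", "./."]}, ["s1", "s2"])
        grs = compute_grs(m, self.snp_model(), missing_policy="partial")
        assert grs.scores["s2"] == 0 and grs.n_missing["s2"] == 1

    def test_unmapped_genotype_is_error(self):
        m = toy_matrix({"rs1": ["C/C"]}, ["s1"])
        with pytest.raises(ValueError, match="coding map"):
            compute_grs(m, self.snp_model())

    def test_monotone_in_single_genotype_upgrade(self, ref_model):
        rng = np.random.default_rng(0)
        genos = {c.snp_id: list(c.codes) for c in ref_model.codings}
        calls = {sid: [rng.choice(g) for _ in range(30)]
                 for sid, g in genos.items()}
        m = toy_matrix(calls, [f"s{i}" for i in range(30)])
        base = compute_grs(m, ref_model).scores
        coding = ref_model.codings[0]
        best = max(coding.codes, key=coding.codes.get)
        upgraded = m.calls.copy()
        upgraded[coding.snp_id] = best
        up = compute_grs(
            type(m)(upgraded, validate=False), ref_model).scores
        assert (up >= base).all()

    def test_snp_order_invariance(self, ref_model):
        rng = np.random.default_rng(1)
        calls = {c.snp_id: [rng.choice(list(c.codes)) for _ in range(20)]
                 for c in ref_model.codings}
        m = toy_matrix(calls, [f"s{i}" for i in range(20)])
        reordered = RiskModel(tuple(reversed(ref_model.codings)))
        a = compute_grs(m, ref_model).scores
        b = compute_grs(m, reordered).scores
        assert (a == b).all()


class TestAssignRiskCoding:
    def build(self, calls, totals):
        m = toy_matrix({"rs0001": calls}, [f"s{i}" for i in range(len(calls))])
        return m, _phen(totals)

    def test_recessive_high_minor_homozygote(self, toy_snp):
        # G/G clearly above the rest -> recessive coding on G
        calls = ["A/A"] * 6 + ["A/G"] * 6 + ["G/G"] * 6
        totals = [26] * 6 + [25] * 6 + [31] * 6
        m, phen = self.build(calls, totals)
        coding = assign_risk_coding(m, phen, toy_snp, mode_policy="recessive")
        assert coding.mode == "recessive" and coding.risk_allele == "G"
        assert coding.codes == {"A/A": 0, "A/G": 0, "G/G": 1}

    def test_binary_policy_picks_carrier_grouping_when_hom_is_protective(
            self, toy_snp):
        # G/G clearly below the rest -> carriers of A are the risk group
        calls = ["A/A"] * 6 + ["A/G"] * 6 + ["G/G"] * 6
        totals = [27] * 6 + [28] * 6 + [17] * 6
        m, phen = self.build(calls, totals)
        coding = assign_risk_coding(m, phen, toy_snp, mode_policy="recessive")
        assert coding.mode == "dominant" and coding.risk_allele == "A"
        assert coding.codes == {"A/A": 1, "A/G": 1, "G/G": 0}

    def test_additive_monotone_means(self, toy_snp):
        calls = ["A/A"] * 5 + ["A/G"] * 5 + ["G/G"] * 5
        totals = [25] * 5 + [28] * 5 + [30] * 5
        m, phen = self.build(calls, totals)
        coding = assign_risk_coding(m, phen, toy_snp, mode_policy="additive")
        assert coding.mode == "additive" and coding.risk_allele == "G"
        assert coding.codes == {"A/A": 0, "A/G": 1, "G/G": 2}

    def test_exact_tie_raises(self, toy_snp):
        calls = ["A/A"] * 4 + ["G/G"] * 4
        totals = [20] * 4 + [20] * 4
        m, phen = self.build(calls, totals)
        with pytest.raises(ValueError, match="tie"):
            assign_risk_coding(m, phen, toy_snp, mode_policy="additive")

    def test_best_fit_prefers_stronger_coding(self, toy_snp):
        # a clean recessive signal should beat the additive fit
        rng = np.random.default_rng(4)
        codes = rng.choice([0, 1, 2], p=[0.36, 0.48, 0.16], size=300)
        y = np.clip(np.rint(24 + 7 * (codes == 2)
                            + rng.normal(0, 3, 300)), 0, 56)
        geno = {0: "A/A", 1: "A/G", 2: "G/G"}
        m = toy_matrix({"rs0001": [geno[c] for c in codes]},
                       [f"s{i}" for i in range(300)])
        coding = assign_risk_coding(m, _phen(y), toy_snp,
                                    mode_policy="best_fit")
        assert coding.mode == "recessive" and coding.risk_allele == "G"


class TestTrendTest:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(9)
        grs_scores = rng.integers(0, 7, size=500)
        y = np.clip(np.rint(20 + 2 * grs_scores + rng.normal(0, 5, 500)),
                    0, 56)
        phen = _phen(y)
        from cravingqtl.risk import GRSVector
        vec = GRSVector(pd.Series(grs_scores.astype(float), index=phen.index),
                        pd.Series(0, index=phen.index), 6)
        res = grs_trend_test(vec, phen)
        assert res.beta == pytest.approx(2.0, abs=0.3)
        assert res.p_trend < 1e-10
        assert len(res.level_means) == 7

    def test_constant_grs_is_error(self):
        phen = _phen([20, 25, 30])
        from cravingqtl.risk import GRSVector
        vec = GRSVector(pd.Series(1.0, index=phen.index),
                        pd.Series(0, index=phen.index), 6)
        with pytest.raises(ValueError, match="constant"):
            grs_trend_test(vec, phen)

    def test_level_means_monotone_under_strong_positive_effect(self):
        rng = np.random.default_rng(12)
        scores = rng.integers(0, 7, size=5000)
        y = np.clip(np.rint(18 + 3 * scores + rng.normal(0, 4, 5000)), 0, 56)
        phen = _phen(y)
        from cravingqtl.risk import GRSVector
        vec = GRSVector(pd.Series(scores.astype(float), index=phen.index),
                        pd.Series(0, index=phen.index), 6)
        means = grs_trend_test(vec, phen).level_means["mean"]
        assert means.is_monotonic_increasing


class TestCombinedReport:
    def test_shape_and_determinism(self, cohort, panel, ref_model):
        rep1 = combined_report(cohort.genotypes, cohort.phenotypes, panel,
                               ref_model)
        rep2 = combined_report(cohort.genotypes, cohort.phenotypes, panel,
                               ref_model)
        assert len(rep1) == len(ref_model.codings) + 1
        assert rep1.iloc[-1]["gene"] == "Combined"
        assert {"r2_total", "p_total", "r2_urge", "r2_ability"} <= set(rep1)
        pd.testing.assert_frame_equal(rep1, rep2)

    def test_single_snp_model_combined_matches_own_row(self, cohort, panel):
        model = RiskModel((reference_risk_model().codings[2],))  # additive SNP
        rep = combined_report(cohort.genotypes, cohort.phenotypes, panel,
                              model)
        snp_row, combined = rep.iloc[0], rep.iloc[1]
        assert combined["r2_total"] == pytest.approx(snp_row["r2_total"])
        assert combined["p_total"] == pytest.approx(snp_row["p_total"])


class TestGeneticRiskScoreEstimator:
    def test_learns_model_and_scores(self, cohort, panel):
        est = GeneticRiskScore(alpha=0.05,
                               force_include=tuple(s.snp_id for s in panel))
        with pytest.warns(UserWarning, match="learned from the cohort"):
            est.fit(cohort.genotypes, cohort.phenotypes, snps=panel)
        assert est.model_.learned_in_sample
        assert set(est.included_snps_) == {s.snp_id for s in panel}
        grs = est.transform(cohort.genotypes)
        assert grs.scores.max() <= est.model_.max_score

    def test_frozen_model_skips_learning(self, cohort, ref_model):
        est = GeneticRiskScore(model=ref_model)
        with warnings.catch_warnings():
            warnings.simplefilter("error")   # no circularity warning
            est.fit(cohort.genotypes)
        trend = est.trend_test(cohort.genotypes, cohort.phenotypes)
        assert trend.p_trend < 0.05  # simulated effects are real
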