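"""Inheritance-mode codings, linear fits, descriptive tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cravingqtl import (SNPInfo, associate_snp, code_genotypes,
                        contingency_chi_square, fit_linear_model,
                        stratified_means, two_sample_t)
from cravingqtl.association import SNPAssociation
from cravingqtl.scoring import ITEM_COLUMNS, score_table
from .conftest import toy_matrix


class TestCodeGenotypes:
    def test_additive_counts_risk_alleles(self):
        codes = code_genotypes(["C/C", "C/T", "T/T"], "T", "additive",
                               alleles=("C", "T"))
        assert codes.tolist() == [0, 1, 2]

    def test_carrier_grouping(self):
        # C-carrier scored 1, TT 0 (the GRIN3B-style binary grouping)
        codes = code_genotypes(["T/T", "C/T", "C/C"], "C", "dominant",
                               alleles=("C", "T"))
        assert codes.tolist() == [0, 1, 1]

    def test_recessive_requires_two_copies(self):
        codes = code_genotypes(["C/C", "C/T", "T/T"], "T", "recessive")
        assert codes.tolist() == [0, 0, 1]

    def test_missing_stays_missing(self):
        codes = code_genotypes(["C/C", None, np.nan], "C", "additive")
        assert codes[0] == 2 and np.isnan(codes[1]) and np.isnan(codes[2])

    def test_risk_allele_must_be_declared(self):
        with pytest.raises(ValueError, match="risk allele"):
            code_genotypes(["C/C"], "G", "additive", alleles=("C", "T"))

    @given(st.lists(st.sampled_from(["A/A", "A/G", "G/G"]), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_additive_equals_dominant_plus_recessive(self, calls):
        add = code_genotypes(calls, "G", "additive")
        dom = code_genotypes(calls, "G", "dominant")
        rec = code_genotypes(calls, "G", "recessive")
        np.testing.assert_allclose(add, dom + rec)


def normal_equations(y, X):
    """Independent brute-force OLS oracle."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    rss = resid @ resid
    tss = ((y - y.mean()) ** 2).sum()
    df = len(y) - X.shape[1]
    sigma2 = rss / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    return beta, se, 1 - rss / tss


class TestLinearModel:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        fit = fit_linear_model(2 * x + 1, x[:, None], names=["x"])
        assert fit.coef("intercept")["beta"] == pytest.approx(1.0)
        assert fit.coef("x")["beta"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_two_group_closed_form(self):
        fit = fit_linear_model([1, 2, 3, 4], np.array([[0, 0, 1, 1]]).T,
                               names=["x"])
        assert fit.coef("x")["beta"] == pytest.approx(2.0)
        assert fit.coef("intercept")["beta"] == pytest.approx(1.5)
        assert fit.r2 == pytest.approx(0.8)

    def test_intercept_only(self):
        fit = fit_linear_model([1.0, 2, 3, 6], np.empty((4, 0)), names=[])
        assert fit.coef("intercept")["beta"] == pytest.approx(3.0)
        assert fit.r2 == pytest.approx(0.0)

    def test_rank_deficiency_names_column(self):
        x = np.arange(8.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="'b'"):
            fit_linear_model(np.random.default_rng(0).normal(size=8), X)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_linear_model([1.0, 1, 1, 1], np.arange(4.0)[:, None])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(10, 51)
            k = rng.integers(1, 6)
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n) + X @ rng.normal(size=k)
            fit = fit_linear_model(y, X)
            beta, se, r2 = normal_equations(y, X)
            np.testing.assert_allclose(fit.params, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.bse, se, rtol=1e-8)
            assert fit.r2 == pytest.approx(r2, rel=1e-8)

    def test_r2_never_decreases_with_extra_predictor(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        r2 = [fit_linear_model(y, X[:, :k]).r2 for k in range(1, 4)]
        assert r2[0] <= r2[1] <= r2[2]


def _phen(values, sexes=None, ages=None, bmis=None):
    n = len(values)
    df = pd.DataFrame(index=[f"s{i}" for i in range(n)])
    df["age"] = ages if ages is not None else 40.0
    df["sex"] = sexes if sexes is not None else "male"
    df["bmi"] = bmis if bmis is not None else 22.0
    base, rem = np.divmod(np.asarray(values, dtype=int), 14)
    for j, col in enumerate(ITEM_COLUMNS):
        df[col] = base + (j < rem)
    return score_table(df)


class TestAssociateSnp:
    def test_recovers_simulated_slope(self, toy_snp):
        rng = np.random.default_rng(11)
        codes = rng.choice([0, 1, 2], size=300, p=[0.36, 0.48, 0.16])
        y = np.clip(20 + 4 * codes + rng.normal(0, 4, 300), 0, 56)
        geno = {0: "A/A", 1: "A/G", 2: "G/G"}
        m = toy_matrix({"rs0001": [geno[c] for c in codes]},
                       [f"s{i}" for i in range(300)])
        phen = _phen(np.rint(y))
        res = associate_snp(m, phen, toy_snp, mode="additive",
                            risk_allele="G", adjust=False)
        assert res.beta == pytest.approx(4.0, abs=0.8)
        assert res.p_unadjusted < 1e-10
        assert res.n == 300

    def test_missing_calls_reduce_n(self, toy_snp):
        calls = ["A/A"] * 10 + ["A/G"] * 10 + ["./."] * 5
        m = toy_matrix({"rs0001": calls}, [f"s{i}" for i in range(25)])
        phen = _phen(np.arange(25) + 10)
        res = associate_snp(m, phen, toy_snp, mode="additive",
                            risk_allele="G", adjust=False)
        assert res.n == 20

    def test_constant_coding_is_error(self, toy_snp):
        m = toy_matrix({"rs0001": ["A/A"] * 8}, [f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="no genotype variation"):
            associate_snp(m, _phen(np.arange(8) + 10), toy_snp,
                          mode="additive", risk_allele="G", adjust=False)

    def test_adjusted_beta_close_when_covariates_independent(self, toy_snp):
        rng = np.random.default_rng(3)
        n = 2000
        codes = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
        y = 25 + 2.0 * codes + rng.normal(0, 5, n)
        geno = {0: "A/A", 1: "A/G", 2: "G/G"}
        m = toy_matrix({"rs0001": [geno[c] for c in codes]},
                       [f"s{i}" for i in range(n)])
        phen = _phen(np.clip(np.rint(y), 0, 56),
                     sexes=rng.choice(["male", "female"], n),
                     ages=rng.normal(40, 7, n), bmis=rng.normal(22, 3, n))
        res = associate_snp(m, phen, toy_snp, mode="additive",
                            risk_allele="G", adjust=True)
        assert res.p_adjusted == pytest.approx(res.p_unadjusted, abs=0.02)


class TestStratifiedMeans:
    def test_hand_computed_cell(self, toy_snp):
        m = toy_matrix({"rs0001": ["A/A", "A/A", "A/G"]}, ["s0", "s1", "s2"])
        phen = _phen([28, 32, 40])
        out = stratified_means(m, phen, toy_snp)
        row = out[out["genotype"] == "A/A"].iloc[0]
        assert row["mean"] == pytest.approx(30.0)
        assert row["sd"] == pytest.approx(2.8284, abs=1e-4)

    def test_empty_class_has_zero_n(self, toy_snp):
        m = toy_matrix({"rs0001": ["A/A", "A/A"]}, ["s0", "s1"])
        out = stratified_means(m, _phen([20, 30]), toy_snp)
        assert out["n"].tolist() == [2, 0, 0]

    def test_sample_order_invariance(self, toy_snp):
        m1 = toy_matrix({"rs0001": ["A/A", "A/G", "G/G"]}, ["a", "b", "c"])
        m2 = toy_matrix({"rs0001": ["G/G", "A/A", "A/G"]}, ["c", "a", "b"])
        p1 = _phen([10, 20, 30])
        p2 = p1.rename(index={"s0": "a", "s1": "b", "s2": "c"})
        out1 = stratified_means(m1, p2, toy_snp)
        out2 = stratified_means(m2, p2.iloc[[2, 0, 1]], toy_snp)
        pd.testing.assert_frame_equal(out1, out2)


class TestContingency:
    def test_marital_status_counts_match_reported_p(self):
        chi2, df, p = contingency_chi_square(
            [[151, 39], [54, 15], [54, 13]])
        assert df == 2
        assert p == pytest.approx(0.9447, abs=0.002)

    def test_identical_row_proportions_give_zero(self):
        chi2, _, p = contingency_chi_square([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, df, p = contingency_chi_square([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(6.667, abs=1e-3)
        assert df == 1

    def test_transpose_invariance(self):
        tab = np.array([[5, 9, 2], [11, 3, 7]])
        assert contingency_chi_square(tab) == pytest.approx(
            contingency_chi_square(tab.T))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            contingency_chi_square([[0, 0], [5, 5]])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_pooled_t(self):
        t, df, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_summary_entry_point_matches_raw(self):
        a, b = [12.0, 15, 11, 19], [22.0, 25, 21]
        raw = two_sample_t(a, b)
        summ = two_sample_t(
            summary_a=(4, np.mean(a), np.std(a, ddof=1)),
            summary_b=(3, np.mean(b), np.std(b, ddof=1)))
        assert raw == pytest.approx(summ)

    def test_cohort_age_difference_is_significant(self):
        # male 43.2 (7.2) n=259 vs female 37.8 (6.3) n=67
        _, _, p = two_sample_t(summary_a=(259, 43.2, 7.2),
                               summary_b=(67, 37.8, 6.3))
        assert p < 0.001

    def test_degenerate_zero_variance(self):
        t, _, p = two_sample_t([2.0, 2, 2], [2.0, 2, 2])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2], [3.0, 3])


def test_snp_association_estimator_tidy_results(cohort, panel):
    est = SNPAssociation(adjust=False, modes=("additive",))
    est.fit(cohort.genotypes, cohort.phenotypes, snps=panel)
    res = est.results_
    assert set(res["phenotype"]) == {"total", "urge", "ability"}
    assert len(res) == len(panel) * 3
    assert ((res["r2"] >= 0) & (res["r2"] <= 1)).all()
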