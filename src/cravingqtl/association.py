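"""Single-SNP quantitative-trait association under inheritance-mode codings.

A SNP genotype is turned into a numeric predictor under one of three
inheritance modes, always expressed relative to a designated risk allele:

- additive:  number of risk-allele copies (0/1/2)
- dominant:  1 if the subject carries at least one risk allele
- recessive: 1 if the subject is homozygous for the risk allele

The phenotype (a craving score) is regressed on the coded genotype with
ordinary least squares, with and without adjustment for age, sex and BMI.
Complete-case analysis throughout: a subject missing the genotype, the
phenotype or any covariate is dropped from both fits so the adjusted and
unadjusted p-values are computed on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, SNPInfo
from .scoring import PHENOTYPES

MODES = ("additive", "dominant", "recessive")
DEFAULT_COVARIATES = ("age", "sex", "bmi")
SEX_CODES = {"female": 0.0, "male": 1.0}


def code_genotypes(calls: Sequence, risk_allele: str, mode: str,
                   alleles: tuple[str, str] | None = None) -> np.ndarray:
    """Numerically code diploid calls under an inheritance mode.

    Parameters
    ----------
    calls : sequence of normalized call strings ("C/T") or NaN/None.
    risk_allele : the allele whose dosage increases the phenotype.
    mode : "additive", "dominant" or "recessive".
    alleles : optional declared allele pair; if given, risk_allele must be
        one of them and stray alleles in calls raise.

    Returns a float array with NaN for missing calls.
    """
    if mode not in MODES:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    if alleles is not None and risk_allele not in alleles:
        raise ValueError(
            f"risk allele {risk_allele!r} not in declared pair {alleles}")
    out = np.full(len(calls), np.nan)
    for i, call in enumerate(calls):
        if call is None or (isinstance(call, float) and np.isnan(call)):
            continue
        pair = str(call).split("/")
        if alleles is not None:
            stray = set(pair) - set(alleles)
            if stray:
                raise ValueError(
                    f"call {call!r} uses allele(s) {sorted(stray)} outside "
                    f"declared pair {alleles}")
        dose = pair.count(risk_allele)
        if mode == "additive":
            out[i] = dose
        elif mode == "dominant":
            out[i] = 1.0 if dose >= 1 else 0.0
        else:  # recessive
            out[i] = 1.0 if dose == 2 else 0.0
    return out


@dataclass(frozen=True)
class LinearFit:
    """OLS fit summary: per-coefficient stats plus fit-level R^2."""

    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r2: float
    n: int
    df_resid: int

    def coef(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        return dict(beta=float(self.params[i]), se=float(self.bse[i]),
                    t=float(self.tvalues[i]), p=float(self.pvalues[i]))


def fit_linear_model(y: Sequence[float], X: pd.DataFrame | np.ndarray,
                     names: Sequence[str] | None = None,
                     add_intercept: bool = True) -> LinearFit:
    """Ordinary least squares with t-based inference.

    Coefficient SEs use the unbiased residual variance (df = n - k);
    p-values are two-sided from the t distribution. R^2 = 1 - RSS/TSS.
    Raises on rank-deficient designs (naming the offending column) and on
    zero-variance responses.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names else [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + list(names)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} too small for {k} predictors")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        for j in range(1, k + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ValueError(f"rank-deficient design: column {names[j - 1]!r} "
                                 "is collinear with earlier columns")
    res = sm.OLS(y, X).fit()
    return LinearFit(names=tuple(names), params=np.asarray(res.params),
                     bse=np.asarray(res.bse), tvalues=np.asarray(res.tvalues),
                     pvalues=np.asarray(res.pvalues),
                     r2=float(res.rsquared), n=n, df_resid=int(res.df_resid))


@dataclass(frozen=True)
class AssociationResult:
    """Per SNP x phenotype x mode association summary.

    ``r2`` is the unadjusted genotype-only model R^2 (the marginal
    variance explained by the coded genotype); beta/se/t refer to the
    unadjusted fit's genotype coefficient, and both p-values are the
    genotype coefficient's p in the respective fit.
    """

    snp_id: str
    phenotype: str
    mode: str
    risk_allele: str
    n: int
    beta: float
    se: float
    t: float
    p_unadjusted: float
    p_adjusted: float
    r2: float


def _design_frame(matrix: GenotypeMatrix, phenotypes: pd.DataFrame,
                  snp: SNPInfo, phenotype: str, mode: str, risk_allele: str,
                  covariates: Sequence[str]) -> pd.DataFrame:
    if phenotype not in PHENOTYPES:
        raise ValueError(f"phenotype must be one of {PHENOTYPES}, got {phenotype!r}")
    calls = matrix.column(snp.snp_id).reindex(phenotypes.index)
    coded = code_genotypes(calls.tolist(), risk_allele, mode, snp.alleles)
    df = pd.DataFrame(index=phenotypes.index)
    df["geno"] = coded
    df["y"] = phenotypes[phenotype].astype(float)
    for cov in covariates:
        if cov == "sex":
            df["sex"] = phenotypes["sex"].map(SEX_CODES)
        else:
            df[cov] = phenotypes[cov].astype(float)
    return df.dropna()


def associate_snp(matrix: GenotypeMatrix, phenotypes: pd.DataFrame,
                  snp: SNPInfo, phenotype: str = "total",
                  mode: str = "additive", risk_allele: str | None = None,
                  adjust: bool = True,
                  covariates: Sequence[str] = DEFAULT_COVARIATES,
                  ) -> AssociationResult:
    """Associate one SNP with one craving phenotype under one mode.

    ``phenotypes`` must carry the scored phenotype columns plus the
    covariates (age, sex, bmi), indexed by sample id matching the matrix.
    When ``adjust`` is False the covariate fit is skipped and p_adjusted
    is NaN. The risk allele defaults to the SNP's minor allele.
    """
    risk_allele = risk_allele or snp.minor_allele
    covs = list(covariates) if adjust else []
    df = _design_frame(matrix, phenotypes, snp, phenotype, mode, risk_allele,
                       covs)
    if df["geno"].nunique() < 2:
        raise ValueError(f"{snp.snp_id}: no genotype variation under "
                         f"{mode} coding")
    unadj = fit_linear_model(df["y"], df[["geno"]])
    g = unadj.coef("geno")
    p_adj = np.nan
    if adjust:
        adj = fit_linear_model(df["y"], df[["geno"] + covs])
        p_adj = adj.coef("geno")["p"]
    return AssociationResult(
        snp_id=snp.snp_id, phenotype=phenotype, mode=mode,
        risk_allele=risk_allele, n=unadj.n, beta=g["beta"], se=g["se"],
        t=g["t"], p_unadjusted=g["p"], p_adjusted=p_adj, r2=unadj.r2)


def stratified_means(matrix: GenotypeMatrix, phenotypes: pd.DataFrame,
                     snp: SNPInfo, phenotype: str = "total") -> pd.DataFrame:
    """Per-genotype n, mean and sample SD of a phenotype.

    Returns three rows in (hom-major, het, hom-minor) order; empty
    genotype classes appear with n = 0.
    """
    calls = matrix.column(snp.snp_id).reindex(phenotypes.index)
    y = phenotypes[phenotype].astype(float)
    rows = []
    for geno in (snp.hom_major, snp.het, snp.hom_minor):
        vals = y[(calls == geno) & y.notna()]
        rows.append(dict(
            snp_id=snp.snp_id, genotype=geno, n=len(vals),
            mean=vals.mean() if len(vals) else np.nan,
            sd=vals.std(ddof=1) if len(vals) >= 2 else np.nan))
    return pd.DataFrame(rows)


def contingency_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction. Returns (chi_square, df, p)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero row/column marginal")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def two_sample_t(a: Sequence[float] | None = None,
                 b: Sequence[float] | None = None, *,
                 summary_a: tuple[int, float, float] | None = None,
                 summary_b: tuple[int, float, float] | None = None,
                 welch: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t test, pooled variance by default.

    Accepts either raw vectors (a, b) or summary triples (n, mean, sd);
    the two entry points agree on matching data. Returns (t, df, p).
    Zero pooled variance with equal means gives (0, df, 1); with unequal
    means it is an error.
    """
    if (a is None) != (b is None) or (summary_a is None) != (summary_b is None):
        raise ValueError("provide both groups via the same entry point")
    if a is not None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        summary_a = (len(a), float(a.mean()), float(a.std(ddof=1)))
        summary_b = (len(b), float(b.mean()), float(b.std(ddof=1)))
    elif summary_a is None:
        raise ValueError("no data provided")
    n1, m1, s1 = summary_a
    n2, m2, s2 = summary_b
    if n1 < 2 or n2 < 2 or s1 < 0 or s2 < 0:
        raise ValueError("invalid summary statistics")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            df = n1 + n2 - 2 if not welch else np.nan
            return 0.0, float(df), 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                      equal_var=not welch)
    if welch:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(t), float(df), float(p)


class SNPAssociation(BaseEstimator):
    """Estimator running single-SNP association across a panel.

    ``fit(matrix, phenotypes, snps=...)`` fits every SNP x phenotype x
    mode combination and stores a tidy results table.

    Parameters
    ----------
    phenotypes : phenotype names to analyse (default all three).
    modes : inheritance modes to fit per SNP (default all three).
    adjust : also fit the age/sex/BMI-adjusted model (default True).
    covariates : covariate columns used when adjusting.
    correction : optional multiple-testing correction over the unadjusted
        p-values: None, "bonferroni" or "bh" (Benjamini-Hochberg). Adds a
        p_corrected column; raw p-values are always reported.

    Attributes
    ----------
    results_ : tidy DataFrame, one row per SNP x phenotype x mode.
    """

    def __init__(self, phenotypes: Sequence[str] = PHENOTYPES,
                 modes: Sequence[str] = MODES, adjust: bool = True,
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 correction: str | None = None) -> None:
        self.phenotypes = phenotypes
        self.modes = modes
        self.adjust = adjust
        self.covariates = covariates
        self.correction = correction

    def fit(self, X: GenotypeMatrix, y: pd.DataFrame,
            snps: Sequence[SNPInfo] | Mapping[str, SNPInfo] = ()) -> "SNPAssociation":
        if isinstance(snps, Mapping):
            snps = list(snps.values())
        rows = []
        for snp in snps:
            for phenotype in self.phenotypes:
                for mode in self.modes:
                    try:
                        res = associate_snp(
                            X, y, snp, phenotype=phenotype, mode=mode,
                            adjust=self.adjust, covariates=self.covariates)
                    except ValueError:
                        continue  # e.g. monomorphic under this coding
                    rows.append(vars(res) | {"gene": snp.gene,
                                             "pathway": snp.pathway})
        results = pd.DataFrame(rows)
        if self.correction and len(results):
            from statsmodels.stats.multitest import multipletests
            method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[self.correction]
            results["p_corrected"] = multipletests(
                results["p_unadjusted"], method=method)[1]
        self.results_ = results
        return self
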