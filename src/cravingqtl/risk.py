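"""Unweighted genetic risk scores (GRS) for craving phenotypes.

Each SNP in a risk model carries a genotype -> integer code map derived
from its inheritance mode and risk allele: additive SNPs contribute 0/1/2
risk-allele copies, binary (dominant/recessive) SNPs contribute 0/1. The
GRS is the plain sum of per-SNP codes, and its dose-response effect on a
craving phenotype is tested by regressing the phenotype on the integer
score ("p for trend" = the score coefficient's p-value).

Risk directions can be learned from the cohort being scored (as candidate
-gene studies commonly do). That is circular — the same data pick the
direction and test the score — so every learned model carries a standing
warning, and a frozen externally derived model can be supplied instead.

The reference five-variant heroin-craving panel (GRIN3B rs2240158,
GRIN3A rs3983721, CYP2C19 rs6583954, TPH2 rs2129575, COMT rs174699) is
bundled as a frozen model; its codes span total scores 0..6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, SNPInfo, normalize_call
from .scoring import PHENOTYPES
from .association import (DEFAULT_COVARIATES, associate_snp,
                          fit_linear_model, stratified_means, SEX_CODES)

CIRCULARITY_WARNING = (
    "risk directions were learned from the cohort being scored; the trend "
    "test is optimistic. Supply a frozen RiskModel for unbiased testing.")


@dataclass(frozen=True)
class RiskCoding:
    """Genotype -> risk-code map for one SNP."""

    snp_id: str
    mode: str                     # additive | dominant | recessive
    risk_allele: str
    codes: Mapping[str, int]      # normalized genotype string -> code

    def __post_init__(self) -> None:
        if len(self.codes) != 3:
            raise ValueError(f"{self.snp_id}: coding map must cover all "
                             "three genotypes")
        expected_max = 2 if self.mode == "additive" else 1
        if max(self.codes.values()) != expected_max or min(self.codes.values()) != 0:
            raise ValueError(f"{self.snp_id}: {self.mode} codes must span "
                             f"0..{expected_max}")

    @property
    def max_code(self) -> int:
        return max(self.codes.values())

    def grouping_label(self) -> str:
        """Human-readable grouping, e.g. "TT(0) vs CC+CT(1)"."""
        by_code: dict[int, list[str]] = {}
        for geno, code in self.codes.items():
            by_code.setdefault(code, []).append(geno.replace("/", ""))
        parts = [f"{'+'.join(sorted(g))}({c})" for c, g in sorted(by_code.items())]
        return " vs ".join(parts)


@dataclass(frozen=True)
class RiskModel:
    """Ordered collection of per-SNP risk codings."""

    codings: tuple[RiskCoding, ...]
    learned_in_sample: bool = False

    @property
    def max_score(self) -> int:
        return sum(c.max_code for c in self.codings)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(c.snp_id for c in self.codings)

    def coding(self, snp_id: str) -> RiskCoding:
        for c in self.codings:
            if c.snp_id == snp_id:
                return c
        raise KeyError(snp_id)


def make_coding(snp: SNPInfo, mode: str, risk_allele: str) -> RiskCoding:
    """Build the genotype->code map implied by a mode and risk allele."""
    if risk_allele not in snp.alleles:
        raise ValueError(f"risk allele {risk_allele!r} not in declared pair "
                         f"{snp.alleles}")
    codes = {}
    for n_minor in (0, 1, 2):
        geno = snp.genotype(n_minor)
        dose = geno.split("/").count(risk_allele)
        if mode == "additive":
            codes[geno] = dose
        elif mode == "dominant":
            codes[geno] = int(dose >= 1)
        elif mode == "recessive":
            codes[geno] = int(dose == 2)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return RiskCoding(snp.snp_id, mode, risk_allele, codes)


def reference_risk_model() -> RiskModel:
    """The frozen five-variant heroin-craving panel.

    Codings follow the published genotype-stratified risk scores:
    GRIN3B rs2240158 C-carrier 1 (TT 0), GRIN3A rs3983721 TT 1,
    CYP2C19 rs6583954 additive in T (CC 0 / CT 1 / TT 2), TPH2 rs2129575
    TT 1, COMT rs174699 CC 1. Maximum total score 6.
    """
    return RiskModel(codings=(
        RiskCoding("rs2240158", "dominant", "C",
                   {"C/C": 1, "C/T": 1, "T/T": 0}),
        RiskCoding("rs3983721", "recessive", "T",
                   {"C/C": 0, "C/T": 0, "T/T": 1}),
        RiskCoding("rs6583954", "additive", "T",
                   {"C/C": 0, "C/T": 1, "T/T": 2}),
        RiskCoding("rs2129575", "recessive", "T",
                   {"G/G": 0, "G/T": 0, "T/T": 1}),
        RiskCoding("rs174699", "recessive", "C",
                   {"C/C": 1, "C/T": 0, "T/T": 0}),
    ))


def reference_panel() -> list[SNPInfo]:
    """SNP metadata for the five-variant panel (major > minor as annotated)."""
    return [
        SNPInfo.from_allele_string("rs2240158", "GRIN3B", "C > T",
                                   "Cognitive function"),
        SNPInfo.from_allele_string("rs3983721", "GRIN3A", "C > T",
                                   "Cognitive function"),
        SNPInfo.from_allele_string("rs6583954", "CYP2C19", "T > C",
                                   "Methadone-metabolizing enzymes"),
        SNPInfo.from_allele_string("rs2129575", "TPH2", "G > T",
                                   "Dopamine and serotonin pathway"),
        SNPInfo.from_allele_string("rs174699", "COMT", "C > T",
                                   "Dopamine and serotonin pathway"),
    ]


def _pooled_mean(strata: pd.DataFrame, rows: Sequence[int]) -> float:
    sub = strata.iloc[list(rows)]
    n = sub["n"].sum()
    if n == 0:
        return np.nan
    return float((sub["n"] * sub["mean"].fillna(0)).sum() / n)


def assign_risk_coding(matrix: GenotypeMatrix, phenotypes: pd.DataFrame,
                       snp: SNPInfo, phenotype: str = "total",
                       mode_policy: str = "best_fit") -> RiskCoding:
    """Infer a SNP's risk coding from genotype-stratified phenotype means.

    Policies
    --------
    "additive"
        Risk allele = the allele whose homozygote has the higher mean;
        codes count its copies 0/1/2.
    "recessive", "dominant", "binary"
        The paper-style binary grouping: one homozygote class versus the
        rest. The homozygote split with the larger absolute mean
        separation is chosen, and the higher-mean side is the risk (code
        1) group. The recorded mode reflects the realized orientation —
        "recessive" when the risk group is the lone homozygote,
        "dominant" when it is the carrier pair. (The two labels are
        orientation duals of the same grouping, so all three policy names
        select the same coding.)
    "best_fit"
        Fit the additive coding and both binary orientations and keep the
        smallest genotype-coefficient p, tie-broken by larger R^2, then
        by additive first.

    Exactly equal candidate means raise a tie error asking for an
    explicit coding.
    """
    strata = stratified_means(matrix, phenotypes, snp, phenotype)
    means, ns = strata["mean"], strata["n"]

    def additive_coding() -> RiskCoding:
        m_major, m_minor = means.iloc[0], means.iloc[2]
        if ns.iloc[0] and ns.iloc[2] and m_major == m_minor:
            raise ValueError(f"{snp.snp_id}: homozygote means tie; specify "
                             "the risk allele explicitly")
        if ns.iloc[0] == 0 or ns.iloc[2] == 0:  # fall back on het vs present hom
            present = 0 if ns.iloc[0] else 2
            risk = (snp.major_allele if present == 0 else snp.minor_allele)
            if means.iloc[1] > means.iloc[present]:
                risk = (snp.minor_allele if present == 0 else snp.major_allele)
        else:
            risk = snp.major_allele if m_major > m_minor else snp.minor_allele
        return make_coding(snp, "additive", risk)

    def binary_coding(hom_row: int) -> RiskCoding:
        rest = [i for i in range(3) if i != hom_row]
        m_hom = means.iloc[hom_row]
        m_rest = _pooled_mean(strata, rest)
        if np.isnan(m_hom) or np.isnan(m_rest):
            raise ValueError(f"{snp.snp_id}: empty genotype class")
        if m_hom == m_rest:
            raise ValueError(f"{snp.snp_id}: grouping means tie; specify "
                             "the risk coding explicitly")
        hom_allele = snp.major_allele if hom_row == 0 else snp.minor_allele
        other = snp.minor_allele if hom_row == 0 else snp.major_allele
        if m_hom > m_rest:
            return make_coding(snp, "recessive", hom_allele)
        return make_coding(snp, "dominant", other)

    def best_binary() -> RiskCoding:
        candidates = []
        for hom_row in (0, 2):
            try:
                coding = binary_coding(hom_row)
            except ValueError:
                continue
            rest = [i for i in range(3) if i != hom_row]
            sep = abs(means.iloc[hom_row] - _pooled_mean(strata, rest))
            candidates.append((sep, coding))
        if not candidates:
            raise ValueError(f"{snp.snp_id}: no valid binary grouping")
        seps = [c[0] for c in candidates]
        if len(candidates) == 2 and seps[0] == seps[1]:
            raise ValueError(f"{snp.snp_id}: binary groupings tie; specify "
                             "the risk coding explicitly")
        return max(candidates, key=lambda c: c[0])[1]

    if mode_policy == "additive":
        return additive_coding()
    if mode_policy in ("recessive", "dominant", "binary"):
        return best_binary()
    if mode_policy != "best_fit":
        raise ValueError(f"unknown mode_policy {mode_policy!r}")

    candidates: list[tuple[float, float, int, RiskCoding]] = []
    builders = [("additive", additive_coding),
                ("binary", best_binary)]
    order = 0
    for _, build in builders:
        try:
            coding = build()
        except ValueError:
            continue
        res = associate_snp(matrix, phenotypes, snp, phenotype=phenotype,
                            mode=coding.mode, risk_allele=coding.risk_allele,
                            adjust=False)
        candidates.append((res.p_unadjusted, -res.r2, order, coding))
        order += 1
    if not candidates:
        raise ValueError(f"{snp.snp_id}: no fittable coding")
    return min(candidates)[3]


@dataclass(frozen=True)
class GRSVector:
    """Per-subject integer genetic risk scores.

    ``scores`` holds NaN for subjects excluded under the "exclude"
    missing policy; ``n_missing`` counts missing component SNPs.
    """

    scores: pd.Series
    n_missing: pd.Series
    max_score: int


def compute_grs(matrix: GenotypeMatrix, model: RiskModel,
                missing_policy: str = "exclude") -> GRSVector:
    """Sum per-SNP risk codes into a subject-level score.

    missing_policy "exclude" (default) gives NaN to any subject missing a
    component genotype; "partial" sums over the non-missing components
    (scores are then not comparable across subjects — flagged via
    n_missing).
    """
    if missing_policy not in ("exclude", "partial"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    total = pd.Series(0.0, index=matrix.calls.index)
    n_missing = pd.Series(0, index=matrix.calls.index)
    for coding in model.codings:
        col = matrix.column(coding.snp_id)
        mapped = pd.Series(np.nan, index=col.index)
        present = col.notna()
        for geno, code in coding.codes.items():
            mapped[col == geno] = code
        unknown = present & mapped.isna()
        if unknown.any():
            bad = col[unknown].unique().tolist()
            raise ValueError(f"{coding.snp_id}: genotype(s) {bad} not in "
                             "coding map")
        n_missing += (~present).astype(int)
        total = total + mapped.fillna(0)
    if missing_policy == "exclude":
        total[n_missing > 0] = np.nan
    total.name = "grs"
    n_missing.name = "n_missing"
    return GRSVector(scores=total, n_missing=n_missing,
                     max_score=model.max_score)


@dataclass(frozen=True)
class TrendResult:
    """Dose-response (p for trend) test of phenotype on integer GRS."""

    phenotype: str
    beta: float
    se: float
    p_trend: float
    r2: float
    n: int
    adjusted: bool
    level_means: pd.DataFrame   # per GRS level: n, mean, sd


def grs_trend_test(grs: GRSVector, phenotypes: pd.DataFrame,
                   phenotype: str = "total", adjust: bool = False,
                   covariates: Sequence[str] = DEFAULT_COVARIATES,
                   ) -> TrendResult:
    """Linear trend of a craving phenotype over the integer GRS.

    The GRS enters as a continuous integer covariate; p_trend is its
    coefficient's two-sided p. R^2 is from the unadjusted (GRS-only)
    model. Also reports the per-level phenotype ladder (n, mean, SD).
    """
    df = pd.DataFrame(index=phenotypes.index)
    df["grs"] = grs.scores.reindex(phenotypes.index)
    df["y"] = phenotypes[phenotype].astype(float)
    covs = list(covariates) if adjust else []
    for cov in covs:
        df[cov] = (phenotypes["sex"].map(SEX_CODES) if cov == "sex"
                   else phenotypes[cov].astype(float))
    df = df.dropna()
    if df["grs"].nunique() < 2:
        raise ValueError("GRS is constant; trend undefined")
    unadj = fit_linear_model(df["y"], df[["grs"]])
    fit = unadj if not adjust else fit_linear_model(df["y"], df[["grs"] + covs])
    g = fit.coef("grs")
    levels = (df.groupby(df["grs"].astype(int))["y"]
              .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)))
    levels.index.name = "grs"
    return TrendResult(phenotype=phenotype, beta=g["beta"], se=g["se"],
                       p_trend=g["p"], r2=unadj.r2, n=fit.n,
                       adjusted=adjust, level_means=levels.reset_index())


def combined_report(matrix: GenotypeMatrix, phenotypes: pd.DataFrame,
                    snps: Sequence[SNPInfo], model: RiskModel,
                    phenotype_names: Sequence[str] = PHENOTYPES,
                    missing_policy: str = "exclude") -> pd.DataFrame:
    """Per-SNP and combined-GRS variance-explained report.

    One row per model SNP (its mode, grouping, and per-phenotype R^2 and
    p from the unadjusted coded-genotype fit) plus a final combined row
    with the GRS R^2 and p for trend per phenotype.
    """
    if not model.codings:
        raise ValueError("empty risk model")
    info = {s.snp_id: s for s in snps}
    rows = []
    for coding in model.codings:
        snp = info[coding.snp_id]
        row = dict(gene=snp.gene, snp_id=snp.snp_id, mode=coding.mode,
                   grouping=coding.grouping_label())
        for ph in phenotype_names:
            res = associate_snp(matrix, phenotypes, snp, phenotype=ph,
                                mode=coding.mode,
                                risk_allele=coding.risk_allele, adjust=False)
            row[f"r2_{ph}"] = res.r2
            row[f"p_{ph}"] = res.p_unadjusted
        rows.append(row)
    grs = compute_grs(matrix, model, missing_policy=missing_policy)
    row = dict(gene="Combined", snp_id="GRS", mode="additive",
               grouping=f"0-{model.max_score}")
    for ph in phenotype_names:
        trend = grs_trend_test(grs, phenotypes, phenotype=ph, adjust=False)
        row[f"r2_{ph}"] = trend.r2
        row[f"p_{ph}"] = trend.p_trend
    rows.append(row)
    report = pd.DataFrame(rows)
    if model.learned_in_sample:
        report.attrs["warning"] = CIRCULARITY_WARNING
    return report


class GeneticRiskScore(BaseEstimator):
    """Estimator learning per-SNP risk codings and scoring subjects.

    ``fit(matrix, phenotypes, snps=...)`` selects component SNPs (those
    with unadjusted p < alpha for the target phenotype under their
    inferred coding, plus any force-included ids), infers each one's risk
    coding from the stratified means, and freezes the model.
    ``transform(matrix)`` returns the per-subject integer GRS.

    A pre-specified frozen model can be passed via ``model=`` to skip
    in-sample learning (recommended for unbiased trend tests).

    Parameters
    ----------
    phenotype : target phenotype for coding inference ("total").
    mode_policy : "best_fit" (default), "additive" or "binary"-family.
    alpha : significance threshold for SNP inclusion (0.05).
    force_include : SNP ids kept regardless of p (e.g. borderline hits).
    missing_policy : "exclude" or "partial" GRS handling.
    model : optional frozen RiskModel; when given, fit only validates.

    Attributes
    ----------
    model_ : the RiskModel used for scoring.
    included_snps_, selection_ : inclusion decisions per candidate SNP.
    """

    def __init__(self, phenotype: str = "total", mode_policy: str = "best_fit",
                 alpha: float = 0.05, force_include: Sequence[str] = (),
                 missing_policy: str = "exclude",
                 model: RiskModel | None = None) -> None:
        self.phenotype = phenotype
        self.mode_policy = mode_policy
        self.alpha = alpha
        self.force_include = force_include
        self.missing_policy = missing_policy
        self.model = model

    def fit(self, X: GenotypeMatrix, y: pd.DataFrame | None = None,
            snps: Sequence[SNPInfo] = ()) -> "GeneticRiskScore":
        if self.model is not None:
            self.model_ = self.model
            self.selection_ = pd.DataFrame()
            self.included_snps_ = list(self.model_.snp_ids)
            return self
        if y is None or not len(snps):
            raise ValueError("learning a model requires phenotypes and snps")
        codings, rows = [], []
        for snp in snps:
            try:
                coding = assign_risk_coding(X, y, snp, self.phenotype,
                                            self.mode_policy)
            except ValueError as exc:
                rows.append(dict(snp_id=snp.snp_id, included=False,
                                 reason=str(exc), p=np.nan))
                continue
            res = associate_snp(X, y, snp, phenotype=self.phenotype,
                                mode=coding.mode,
                                risk_allele=coding.risk_allele, adjust=False)
            keep = (res.p_unadjusted < self.alpha
                    or snp.snp_id in self.force_include)
            rows.append(dict(snp_id=snp.snp_id, included=keep,
                             reason="" if keep else f"p >= {self.alpha}",
                             p=res.p_unadjusted, mode=coding.mode,
                             risk_allele=coding.risk_allele))
            if keep:
                codings.append(coding)
        if not codings:
            raise ValueError("no SNP met the inclusion rule; cannot build "
                             "a risk model")
        warnings.warn(CIRCULARITY_WARNING)
        self.model_ = RiskModel(codings=tuple(codings), learned_in_sample=True)
        self.selection_ = pd.DataFrame(rows)
        self.included_snps_ = list(self.model_.snp_ids)
        return self

    def transform(self, X: GenotypeMatrix) -> GRSVector:
        if not hasattr(self, "model_"):
            raise RuntimeError("GeneticRiskScore is not fitted")
        return compute_grs(X, self.model_, missing_policy=self.missing_policy)

    def fit_transform(self, X: GenotypeMatrix, y: pd.DataFrame | None = None,
                      **kw) -> GRSVector:
        return self.fit(X, y, **kw).transform(X)

    def trend_test(self, X: GenotypeMatrix, phenotypes: pd.DataFrame,
                   phenotype: str | None = None,
                   adjust: bool = False) -> TrendResult:
        grs = self.transform(X)
        return grs_trend_test(grs, phenotypes,
                              phenotype=phenotype or self.phenotype,
                              adjust=adjust)
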