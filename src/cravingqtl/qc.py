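"""Genotype quality control: HWE goodness-of-fit, allele frequencies,
duplicate concordance and threshold filtering.

The Hardy-Weinberg test is the plain 1-df chi-square goodness-of-fit
statistic sum((O-E)^2 / E) against expected genotype counts (n p^2, 2npq,
n q^2) at the estimated allele frequency — no continuity correction and no
exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, SNPInfo


@dataclass(frozen=True)
class HWEResult:
    """1-df chi-square goodness-of-fit result for one SNP."""

    snp_id: str
    observed: tuple[int, int, int]       # (hom-major, het, hom-minor)
    expected: tuple[float, float, float]
    chi_square: float
    p_value: float
    monomorphic: bool = False
    df: int = field(default=1)


def hwe_test(counts: Sequence[int], snp_id: str = "") -> HWEResult:
    """Test genotype counts (hom-major, het, hom-minor) for HWE.

    Allele frequencies are estimated from the counts themselves; the
    statistic is sum((O-E)^2/E) with 1 degree of freedom (3 genotype
    classes - 1 - 1 estimated frequency). Monomorphic SNPs (estimated
    frequency 0 or 1) get chi_square 0, p 1 and a monomorphic flag.
    """
    o = tuple(int(c) for c in counts)
    if len(o) != 3:
        raise ValueError("expected 3 genotype counts (hom-major, het, hom-minor)")
    if any(c < 0 for c in o):
        raise ValueError("genotype counts must be non-negative")
    n = sum(o)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p_hat = (2 * o[0] + o[1]) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = (n * p_hat ** 2, 2 * n * p_hat * q_hat, n * q_hat ** 2)
    if p_hat in (0.0, 1.0):
        return HWEResult(snp_id, o, expected, 0.0, 1.0, monomorphic=True)
    chi2 = sum((obs - exp) ** 2 / exp for obs, exp in zip(o, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(snp_id, o, expected, float(chi2), p)


def genotype_counts(matrix: GenotypeMatrix, snp: SNPInfo) -> tuple[int, int, int]:
    """Count (hom-major, het, hom-minor) non-missing calls for one SNP."""
    col = matrix.column(snp.snp_id).dropna()
    counts = col.value_counts()
    known = {snp.hom_major, snp.het, snp.hom_minor}
    stray = set(counts.index) - known
    if stray:
        raise ValueError(
            f"{snp.snp_id}: call(s) {sorted(stray)} use alleles outside "
            f"declared pair {snp.allele_string}")
    return (int(counts.get(snp.hom_major, 0)),
            int(counts.get(snp.het, 0)),
            int(counts.get(snp.hom_minor, 0)))


def allele_frequencies(matrix: GenotypeMatrix, snp_id: str) -> tuple[float, float]:
    """Return (maf, call_rate) for one SNP from non-missing calls.

    maf is the frequency of the rarer observed allele (0 for monomorphic
    SNPs); call_rate is the non-missing fraction of samples.
    """
    col = matrix.column(snp_id)
    non_missing = col.dropna()
    call_rate = len(non_missing) / len(col) if len(col) else 0.0
    if len(non_missing) == 0:
        raise ValueError(f"{snp_id}: all calls missing")
    allele_counts: dict[str, int] = {}
    for call in non_missing:
        for allele in call.split("/"):
            allele_counts[allele] = allele_counts.get(allele, 0) + 1
    total = sum(allele_counts.values())
    freqs = sorted(c / total for c in allele_counts.values())
    maf = 0.0 if len(freqs) == 1 else freqs[0]
    return maf, call_rate


def duplicate_concordance(
    matrix: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
) -> tuple[pd.Series, float]:
    """Concordance between duplicate sample pairs.

    For each SNP, concordance = matching pair-calls / jointly non-missing
    pair-calls. Returns (per-SNP Series, overall rate). Pairs with no
    jointly non-missing call contribute nothing (warned).
    """
    seen: set[str] = set()
    for a, b in pairs:
        for sid in (a, b):
            if sid not in matrix.calls.index:
                raise KeyError(f"sample {sid!r} not in matrix")
            if sid in seen:
                raise ValueError(f"sample {sid!r} appears in more than one pair")
            seen.add(sid)
    match = pd.Series(0, index=matrix.snp_ids, dtype=float)
    informative = pd.Series(0, index=matrix.snp_ids, dtype=float)
    for a, b in pairs:
        ca, cb = matrix.calls.loc[a], matrix.calls.loc[b]
        both = ca.notna() & cb.notna()
        if not both.any():
            warnings.warn(f"duplicate pair ({a}, {b}) has no jointly "
                          "non-missing calls; skipped")
            continue
        informative += both.astype(float)
        match += (both & (ca == cb)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = match / informative
    overall = float(match.sum() / informative.sum()) if informative.sum() else np.nan
    per_snp.name = "concordance"
    return per_snp, overall


def qc_report(matrix: GenotypeMatrix, snps: Sequence[SNPInfo], *,
              maf_min: float = 0.05, hwe_alpha: float = 1e-4,
              call_rate_min: float = 0.9) -> pd.DataFrame:
    """Per-SNP QC metrics and pass/fail status against thresholds."""
    rows = []
    for snp in snps:
        try:
            maf, call_rate = allele_frequencies(matrix, snp.snp_id)
        except ValueError:
            rows.append(dict(snp_id=snp.snp_id, maf=np.nan, call_rate=0.0,
                             hwe_chi2=np.nan, hwe_p=np.nan, status="fail",
                             reason="call_rate"))
            continue
        hwe = hwe_test(genotype_counts(matrix, snp), snp.snp_id)
        reasons = []
        if maf_min > 0 and maf <= maf_min:
            reasons.append("MAF")
        if not hwe.monomorphic and hwe.p_value < hwe_alpha:
            reasons.append("HWE")
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        rows.append(dict(snp_id=snp.snp_id, maf=maf, call_rate=call_rate,
                         hwe_chi2=hwe.chi_square, hwe_p=hwe.p_value,
                         status="pass" if not reasons else "fail",
                         reason=";".join(reasons)))
    return pd.DataFrame(rows)


def qc_filter(matrix: GenotypeMatrix, snps: Sequence[SNPInfo], *,
              maf_min: float = 0.05, hwe_alpha: float = 1e-4,
              call_rate_min: float = 0.9) -> tuple[list[str], pd.DataFrame]:
    """Drop SNPs failing MAF/HWE/call-rate thresholds.

    The MAF rule is strict (maf must exceed maf_min, mirroring the
    "minor allele frequency > 0.05" panel-selection convention); setting a
    threshold to 0 disables its check, so thresholds (0, 0, 0) retain
    every SNP. Returns (retained snp ids, report).
    """
    report = qc_report(matrix, snps, maf_min=maf_min, hwe_alpha=hwe_alpha,
                       call_rate_min=call_rate_min)
    retained = report.loc[report["status"] == "pass", "snp_id"].tolist()
    if not retained:
        warnings.warn("no SNPs passed QC")
    return retained, report


class GenotypeQC(BaseEstimator):
    """Estimator-style genotype QC filter.

    ``fit(matrix, snps)`` computes per-SNP MAF, call rate and HWE and
    decides which SNPs pass; ``transform(matrix)`` returns the matrix
    restricted to passing SNPs.

    Parameters
    ----------
    maf_min : float, default 0.05
        Minimum minor allele frequency (strict: maf must exceed it).
    hwe_alpha : float, default 1e-4
        HWE goodness-of-fit p-value below which a SNP is dropped.
    call_rate_min : float, default 0.9
        Minimum fraction of non-missing calls.

    Attributes
    ----------
    report_ : DataFrame with snp_id, maf, call_rate, hwe_chi2, hwe_p,
        status, reason.
    retained_snps_ : list of passing SNP ids.
    """

    def __init__(self, maf_min: float = 0.05, hwe_alpha: float = 1e-4,
                 call_rate_min: float = 0.9) -> None:
        self.maf_min = maf_min
        self.hwe_alpha = hwe_alpha
        self.call_rate_min = call_rate_min

    def fit(self, X: GenotypeMatrix, y: Sequence[SNPInfo] | None = None,
            snps: Sequence[SNPInfo] | None = None) -> "GenotypeQC":
        snps = snps if snps is not None else y
        if snps is None:
            raise ValueError("GenotypeQC.fit requires SNP metadata (snps=...)")
        self.retained_snps_, self.report_ = qc_filter(
            X, snps, maf_min=self.maf_min, hwe_alpha=self.hwe_alpha,
            call_rate_min=self.call_rate_min)
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "retained_snps_"):
            raise RuntimeError("GenotypeQC is not fitted")
        keep = [s for s in self.retained_snps_ if s in X.calls.columns]
        return X.subset_snps(keep)

    def fit_transform(self, X: GenotypeMatrix,
                      y: Sequence[SNPInfo] | None = None,
                      **kw) -> GenotypeMatrix:
        return self.fit(X, y, **kw).transform(X)
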