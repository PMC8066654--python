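"""Synthetic genotype-phenotype cohorts for craving-QTL analysis.

The generator produces cohorts with the statistical structure the
downstream linear-model analysis assumes: biallelic genotypes drawn as
Hardy-Weinberg trinomials at a configured minor allele frequency, a
latent continuous craving phenotype that is linear in coded genotypes and
(mean-centered) covariates plus Gaussian noise, and questionnaire items
allocated so the scored total equals the clipped, rounded latent value.

The default configuration mirrors the study conditions of the MMT cohort
the analysis models: n = 326 subjects, ~79% male, sex-specific age and
BMI distributions, mean total craving score ~27 with SD ~10, and the
five-variant reference panel with each SNP sized to explain about 4% of
phenotype variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SNPInfo
from .scoring import ITEM_COLUMNS, N_ITEMS, ITEM_MAX, TOTAL_MAX, score_table
from . import risk as _risk

MODES = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class SnpSimSpec:
    """Simulation parameters for one biallelic SNP."""

    snp_id: str
    minor_allele: str
    major_allele: str
    maf: float
    mode: str = "additive"
    effect_size: float = 0.0      # phenotype units per risk-code unit
    risk_allele: str | None = None  # defaults to the minor allele

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], "
                             f"got {self.maf}")
        if self.minor_allele == self.major_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if self.mode not in MODES:
            raise ValueError(f"{self.snp_id}: unknown mode {self.mode!r}")
        risk = self.risk_allele
        if risk is not None and risk not in (self.minor_allele,
                                             self.major_allele):
            raise ValueError(f"{self.snp_id}: risk allele {risk!r} not among "
                             "declared alleles")

    @property
    def resolved_risk_allele(self) -> str:
        return self.risk_allele or self.minor_allele

    @property
    def info(self) -> SNPInfo:
        return SNPInfo(self.snp_id, gene="", major_allele=self.major_allele,
                       minor_allele=self.minor_allele)

    def code_variance(self) -> float:
        """Population variance of the coded genotype under HWE."""
        q = self.maf
        p = 1 - q
        risk_freq = q if self.resolved_risk_allele == self.minor_allele else p
        if self.mode == "additive":
            return 2 * risk_freq * (1 - risk_freq)
        if self.mode == "dominant":
            carrier = 1 - (1 - risk_freq) ** 2
            return carrier * (1 - carrier)
        hom = risk_freq ** 2
        return hom * (1 - hom)

    def code_mean(self) -> float:
        q = self.maf
        p = 1 - q
        risk_freq = q if self.resolved_risk_allele == self.minor_allele else p
        if self.mode == "additive":
            return 2 * risk_freq
        if self.mode == "dominant":
            return 1 - (1 - risk_freq) ** 2
        return risk_freq ** 2


def effect_size_for_r2(target_r2: float, spec: SnpSimSpec,
                       total_sd: float) -> float:
    """Effect size making one SNP explain ``target_r2`` of total variance.

    Solves beta^2 * var(code) = target_r2 * total_sd^2 for beta, so the
    SNP's marginal (genotype-only) R^2 is approximately target_r2 when the
    realized total phenotype SD is total_sd.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    v = spec.code_variance()
    if v <= 0:
        raise ValueError(f"{spec.snp_id}: coded genotype has no variance")
    return float(total_sd * np.sqrt(target_r2 / v))


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a simulated cohort.

    Covariate effects apply to mean-centered covariates (sex coded
    0 = female, 1 = male) and genetic effects to mean-centered codes, so
    ``intercept`` is the population mean of the latent phenotype.
    """

    n_subjects: int = 326
    prop_male: float = 259 / 326
    age_mean_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"male": 43.2, "female": 37.8})
    age_sd_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"male": 7.2, "female": 6.3})
    bmi_mean_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"male": 23.0, "female": 21.6})
    bmi_sd_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"male": 2.8, "female": 2.8})
    snp_specs: tuple[SnpSimSpec, ...] = ()
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0, "bmi": 0.0})
    intercept: float = 27.3
    residual_sd: float = 9.9
    item_allocation: str = "round_robin"
    missing_rate: float = 0.0
    ascertainment: float | None = None   # lower-tail truncation quantile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.prop_male <= 1:
            raise ValueError("prop_male must be in [0, 1]")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ascertainment is not None and not 0 < self.ascertainment < 1:
            raise ValueError("ascertainment quantile must be in (0, 1)")
        if self.item_allocation != "round_robin":
            raise ValueError(f"unknown item_allocation "
                             f"{self.item_allocation!r}")
        for sd_map in (self.age_sd_by_sex, self.bmi_sd_by_sex):
            if any(v <= 0 for v in sd_map.values()):
                raise ValueError("covariate SDs must be > 0")
        ids = [s.snp_id for s in self.snp_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in snp_specs")


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth that produced it."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame     # covariates + items + scored phenotypes
    truth: dict


def default_cohort_config(seed: int = 0, target_r2: float = 0.04,
                          total_sd: float = 9.9,
                          n_subjects: int = 326) -> CohortConfig:
    """Study-condition defaults: the five-variant panel, each SNP sized
    to explain ~``target_r2`` of variance, residual noise filling the
    rest of a total SD of ``total_sd``."""
    raw_specs = [
        SnpSimSpec("rs2240158", minor_allele="T", major_allele="C", maf=0.20,
                   mode="dominant", risk_allele="C"),
        SnpSimSpec("rs3983721", minor_allele="T", major_allele="C", maf=0.35,
                   mode="recessive", risk_allele="T"),
        SnpSimSpec("rs6583954", minor_allele="C", major_allele="T", maf=0.35,
                   mode="additive", risk_allele="T"),
        SnpSimSpec("rs2129575", minor_allele="T", major_allele="G", maf=0.35,
                   mode="recessive", risk_allele="T"),
        SnpSimSpec("rs174699", minor_allele="T", major_allele="C", maf=0.25,
                   mode="recessive", risk_allele="C"),
    ]
    specs = tuple(
        replace(s, effect_size=effect_size_for_r2(target_r2, s, total_sd))
        for s in raw_specs)
    genetic_var = sum(s.effect_size ** 2 * s.code_variance() for s in specs)
    residual_sd = float(np.sqrt(max(total_sd ** 2 - genetic_var, 1e-6)))
    return CohortConfig(n_subjects=n_subjects, snp_specs=specs,
                        residual_sd=residual_sd, seed=seed)


def allocate_items(totals: np.ndarray) -> np.ndarray:
    """Distribute integer totals (0..56) over 14 items, round-robin.

    Each unit of score is dealt to items 1..14 in turn, so item i gets
    floor(t/14) + 1 extra point if i < t mod 14; every item stays within
    0..4 and the items sum exactly to the total.
    """
    t = np.asarray(totals, dtype=int)
    if (t < 0).any() or (t > TOTAL_MAX).any():
        raise ValueError(f"totals must lie in 0..{TOTAL_MAX}")
    base = t // N_ITEMS
    rem = t % N_ITEMS
    items = base[:, None] + (np.arange(N_ITEMS)[None, :] < rem[:, None])
    assert items.max(initial=0) <= ITEM_MAX
    return items


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw one cohort from the generative model.

    Independent substreams (genotypes, covariates, noise, missingness)
    are spawned from the single seed, so changing e.g. the missing rate
    does not perturb the genotype draw. Deterministic given (config,
    seed).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_cov, rng_noise, rng_miss = (
        np.random.default_rng(child) for child in ss.spawn(4))
    n = config.n_subjects
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # covariates
    male = rng_cov.random(n) < config.prop_male
    sex = np.where(male, "male", "female")
    age = np.where(
        male,
        rng_cov.normal(config.age_mean_by_sex["male"],
                       config.age_sd_by_sex["male"], n),
        rng_cov.normal(config.age_mean_by_sex["female"],
                       config.age_sd_by_sex["female"], n))
    bmi = np.where(
        male,
        rng_cov.normal(config.bmi_mean_by_sex["male"],
                       config.bmi_sd_by_sex["male"], n),
        rng_cov.normal(config.bmi_mean_by_sex["female"],
                       config.bmi_sd_by_sex["female"], n))
    age = np.clip(age, 18.0, None)
    bmi = np.clip(bmi, 14.0, None)

    # genotypes: HWE trinomial per SNP
    calls = {}
    coded_centered = np.zeros(n)
    realized_freqs = {}
    for spec in config.snp_specs:
        q = spec.maf
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
        n_minor = rng_geno.choice(3, size=n, p=probs)
        info = spec.info
        calls[spec.snp_id] = [info.genotype(int(m)) for m in n_minor]
        realized_freqs[spec.snp_id] = float(n_minor.mean() / 2)
        risk = spec.resolved_risk_allele
        dose = n_minor if risk == spec.minor_allele else 2 - n_minor
        if spec.mode == "additive":
            code = dose.astype(float)
        elif spec.mode == "dominant":
            code = (dose >= 1).astype(float)
        else:
            code = (dose == 2).astype(float)
        coded_centered += spec.effect_size * (code - spec.code_mean())

    # latent phenotype
    pop_age_mean = (config.prop_male * config.age_mean_by_sex["male"]
                    + (1 - config.prop_male) * config.age_mean_by_sex["female"])
    pop_bmi_mean = (config.prop_male * config.bmi_mean_by_sex["male"]
                    + (1 - config.prop_male) * config.bmi_mean_by_sex["female"])
    eff = dict(config.covariate_effects)
    latent = (config.intercept
              + coded_centered
              + eff.get("age", 0.0) * (age - pop_age_mean)
              + eff.get("sex", 0.0) * (male.astype(float) - config.prop_male)
              + eff.get("bmi", 0.0) * (bmi - pop_bmi_mean)
              + rng_noise.normal(0.0, config.residual_sd, n))
    clipped = np.clip(latent, 0.0, float(TOTAL_MAX))
    totals = np.rint(clipped).astype(int)
    items = allocate_items(totals)

    phen = pd.DataFrame({"age": np.round(age, 1), "sex": sex,
                         "bmi": np.round(bmi, 1)}, index=sample_ids)
    for j, col in enumerate(ITEM_COLUMNS):
        phen[col] = items[:, j]
    phen.index.name = "sample_id"
    phen = score_table(phen)

    matrix = GenotypeMatrix(
        pd.DataFrame(calls, index=sample_ids), validate=False)
    if config.missing_rate > 0:
        matrix = inject_missingness(matrix, config.missing_rate,
                                    rng=rng_miss)
    truth = dict(config=config, realized_allele_freqs=realized_freqs,
                 latent=latent, ascertainment_threshold=None)
    cohort = SimulatedCohort(genotypes=matrix, phenotypes=phen, truth=truth)
    if config.ascertainment is not None:
        cohort = apply_extreme_sampling(cohort, config.ascertainment)
    return cohort


def apply_extreme_sampling(cohort: SimulatedCohort,
                           quantile: float) -> SimulatedCohort:
    """Keep subjects in the upper tail of the total craving score.

    Retains subjects whose total score is at or above the given cohort
    quantile, emulating recruitment from the extreme margin of the
    phenotype range. The truncation threshold is recorded in truth.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    totals = cohort.phenotypes["total"].astype(float)
    threshold = float(np.quantile(totals.dropna(), quantile))
    keep = totals >= threshold
    kept_ids = list(cohort.phenotypes.index[keep])
    truth = dict(cohort.truth)
    truth["ascertainment_threshold"] = threshold
    truth["latent"] = np.asarray(truth["latent"])[np.asarray(keep)]
    return SimulatedCohort(
        genotypes=cohort.genotypes.subset_samples(kept_ids),
        phenotypes=cohort.phenotypes.loc[kept_ids],
        truth=truth)


def inject_missingness(matrix: GenotypeMatrix, rate: float,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> GenotypeMatrix:
    """Independently blank each call with the given probability."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return matrix
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random(matrix.calls.shape) < rate
    blanked = matrix.calls.mask(pd.DataFrame(
        mask, index=matrix.calls.index, columns=matrix.calls.columns))
    return GenotypeMatrix(blanked, validate=False)


def panel_snp_info() -> list[SNPInfo]:
    """SNP annotations matching the default simulation panel."""
    return _risk.reference_panel()
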