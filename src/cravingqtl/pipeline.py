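"""End-to-end pipeline: simulate/load -> QC -> score -> associate ->
risk score -> reports.

Every run writes a fixed set of TSV outputs into the run directory:

- qc_report.tsv            per-SNP MAF / call rate / HWE status
- association_results.tsv  SNP x phenotype x mode tidy results
- stratified_means.tsv     per-genotype phenotype means (ladder style)
- risk_model.tsv           the learned (or supplied) genotype->code maps
- grs.tsv                  per-subject integer risk scores
- combined_report.tsv      per-SNP and combined-GRS R^2 / p table
- run_log.txt              seed, config echo, version, per-stage n

Outputs are deterministic for a given config and seed (no timestamps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import io as io_formats
from .association import SNPAssociation, stratified_means
from .containers import GenotypeMatrix, SNPInfo
from .qc import GenotypeQC
from .risk import GeneticRiskScore, RiskModel, combined_report, grs_trend_test
from .scoring import HUCScorer, PHENOTYPES, summarize_scores
from .simulate import (CohortConfig, SnpSimSpec, default_cohort_config,
                       simulate_cohort)


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    genotype_path: str | None = None
    phenotype_path: str | None = None
    snp_table_path: str | None = None
    risk_model_path: str | None = None   # frozen model; skips learning
    simulate: bool = False               # ignore paths, use the simulator
    n_subjects: int = 326
    maf_min: float = 0.05
    hwe_alpha: float = 1e-4
    call_rate_min: float = 0.9
    phenotypes: tuple[str, ...] = PHENOTYPES
    target_phenotype: str = "total"
    mode_policy: str = "best_fit"
    adjust: bool = True
    alpha: float = 0.05
    correction: str | None = None        # none | bonferroni | bh
    force_include: tuple[str, ...] = ()
    missing_policy: str = "exclude"
    out_dir: str = "runs/run"
    seed: int = 0


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def read_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse the flat ``key = value`` config file.

    One option per line; '#' starts a comment; list-valued options
    (phenotypes, force_include) are comma-separated; booleans are
    true/false. Relative input paths are resolved against the config
    file's directory. Unknown keys are an error.
    """
    base = Path(path).resolve().parent
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value
    cfg = PipelineConfig()
    valid = {f.name: f for f in fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in valid:
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if key in ("phenotypes", "force_include"):
            parsed: object = tuple(v.strip() for v in value.split(",")
                                   if v.strip())
        elif isinstance(current, bool):
            parsed = _BOOL[value.lower()]
        elif isinstance(current, int):
            parsed = int(value)
        elif isinstance(current, float):
            parsed = float(value)
        elif value.lower() in ("none", ""):
            parsed = None
        else:
            parsed = value
            if key.endswith("_path") and parsed is not None:
                p = Path(parsed)
                parsed = str(p if p.is_absolute() else base / p)
        setattr(cfg, key, parsed)
    return cfg


def _config_echo(config: PipelineConfig) -> str:
    lines = []
    for f in fields(config):
        if f.name == "out_dir":   # run-relative; keep outputs byte-stable
            continue
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = ",".join(map(str, value))
        lines.append(f"{f.name} = {value}")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and write the run directory. Returns its path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"cravingqtl {__version__}", f"seed = {config.seed}",
                      "", "[config]", _config_echo(config), "", "[stages]"]

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        sim_config = default_cohort_config(seed=config.seed,
                                           n_subjects=config.n_subjects)
        cohort = simulate_cohort(sim_config)
        matrix, phenotypes = cohort.genotypes, cohort.phenotypes
        from .simulate import panel_snp_info
        snps = panel_snp_info()
        log.append(f"simulate: n={matrix.n_samples} subjects, "
                   f"{matrix.n_snps} SNPs")
    else:
        for label, p in (("genotype", config.genotype_path),
                         ("phenotype", config.phenotype_path),
                         ("snp table", config.snp_table_path)):
            if not p:
                raise FileNotFoundError(f"{label} path not configured")
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        matrix = io_formats.read_genotype_table(config.genotype_path)
        phenotypes = io_formats.read_phenotype_table(config.phenotype_path)
        snps = io_formats.read_snp_table(config.snp_table_path)
        log.append(f"load: n={matrix.n_samples} subjects, "
                   f"{matrix.n_snps} SNPs")

    # ---- QC ---------------------------------------------------------------
    qc = GenotypeQC(maf_min=config.maf_min, hwe_alpha=config.hwe_alpha,
                    call_rate_min=config.call_rate_min)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix_qc = qc.fit(matrix, snps=snps).transform(matrix)
    io_formats.write_table(qc.report_, out / "qc_report.tsv")
    snps_qc = [s for s in snps if s.snp_id in set(qc.retained_snps_)]
    log.append(f"qc: retained {len(snps_qc)}/{len(snps)} SNPs")

    # ---- scoring ----------------------------------------------------------
    scorer = HUCScorer().fit(phenotypes)
    phenotypes = scorer.transform(phenotypes)
    n_scored = int(phenotypes["total"].notna().sum())
    log.append(f"score: {n_scored}/{scorer.n_records_} records scored "
               f"({scorer.n_unscorable_} dropped: missing items)")
    io_formats.write_table(
        summarize_scores(phenotypes, phenotypes["sex"]).reset_index(),
        out / "score_summary.tsv")

    # ---- single-SNP association ------------------------------------------
    assoc = SNPAssociation(phenotypes=config.phenotypes,
                           adjust=config.adjust,
                           correction=(None if config.correction
                                       in (None, "none")
                                       else config.correction))
    assoc.fit(matrix_qc, phenotypes, snps=snps_qc)
    if assoc.results_.empty:
        raise RuntimeError("association stage produced no results")
    io_formats.write_association_results(assoc.results_,
                                         out / "association_results.tsv")
    log.append(f"associate: {len(assoc.results_)} fits "
               f"(min n = {int(assoc.results_['n'].min())})")
    if config.correction not in (None, "none"):
        log.append(f"associate: multiple-testing correction = "
                   f"{config.correction} (raw p reported alongside)")

    strata = pd.concat([stratified_means(matrix_qc, phenotypes, s,
                                         config.target_phenotype)
                        for s in snps_qc], ignore_index=True)
    io_formats.write_table(strata, out / "stratified_means.tsv")

    # ---- risk score -------------------------------------------------------
    frozen: RiskModel | None = None
    if config.risk_model_path:
        frozen = io_formats.read_risk_model(config.risk_model_path)
    grs_est = GeneticRiskScore(phenotype=config.target_phenotype,
                               mode_policy=config.mode_policy,
                               alpha=config.alpha,
                               force_include=config.force_include,
                               missing_policy=config.missing_policy,
                               model=frozen)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grs_est.fit(matrix_qc, phenotypes, snps=snps_qc)
    except ValueError as exc:
        log.append(f"grs: skipped ({exc})")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        return out
    io_formats.write_risk_model(grs_est.model_, snps_qc + list(snps),
                                out / "risk_model.tsv")
    grs = grs_est.transform(matrix_qc)
    grs_df = pd.DataFrame({"grs": grs.scores, "n_missing": grs.n_missing})
    grs_df.index.name = "sample_id"
    io_formats.write_table(grs_df.reset_index(), out / "grs.tsv")
    log.append(f"grs: {len(grs_est.model_.codings)} SNPs, max score "
               f"{grs_est.model_.max_score}, "
               f"{int(grs.scores.notna().sum())} subjects scored")
    if getattr(grs_est.model_, "learned_in_sample", False):
        from .risk import CIRCULARITY_WARNING
        log.append(f"grs: WARNING {CIRCULARITY_WARNING}")

    report = combined_report(matrix_qc, phenotypes, snps_qc + list(snps),
                             grs_est.model_,
                             phenotype_names=config.phenotypes,
                             missing_policy=config.missing_policy)
    io_formats.write_table(report, out / "combined_report.tsv")
    trend = grs_trend_test(grs, phenotypes, config.target_phenotype,
                           adjust=False)
    log.append(f"trend: beta={trend.beta:.4g} p={trend.p_trend:.4g} "
               f"r2={trend.r2:.4g} n={trend.n}")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out


def make_fixtures(outdir: str | Path, seed: int = 0) -> Path:
    """Write a small bundled example dataset (60 subjects, 8 SNPs).

    The panel is the five reference SNPs (with their published codings
    as simulation truth) plus three null SNPs. Files: genotypes.tsv,
    phenotypes.csv, snps.tsv, risk_model.tsv, config.txt.
    """
    from .risk import reference_risk_model
    from .simulate import panel_snp_info, SnpSimSpec, effect_size_for_r2

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = default_cohort_config(seed=seed, n_subjects=60)
    null_specs = tuple(
        SnpSimSpec(snp_id, minor_allele=minor, major_allele=major, maf=maf)
        for snp_id, minor, major, maf in (
            ("rs1000001", "A", "G", 0.30),
            ("rs1000002", "C", "A", 0.45),
            ("rs1000003", "T", "A", 0.25)))
    config = CohortConfig(
        n_subjects=60, snp_specs=base.snp_specs + null_specs,
        residual_sd=base.residual_sd, seed=seed)
    cohort = simulate_cohort(config)
    snps = panel_snp_info() + [
        SNPInfo("rs1000001", "NULL1", "G", "A", "synthetic null"),
        SNPInfo("rs1000002", "NULL2", "A", "C", "synthetic null"),
        SNPInfo("rs1000003", "NULL3", "A", "T", "synthetic null")]
    io_formats.write_genotype_table(cohort.genotypes, outdir / "genotypes.tsv")
    io_formats.write_phenotype_table(cohort.phenotypes,
                                     outdir / "phenotypes.csv")
    io_formats.write_snp_table(snps, outdir / "snps.tsv")
    io_formats.write_risk_model(reference_risk_model(), snps,
                                outdir / "risk_model.tsv")
    (outdir / "config.txt").write_text(
        "# cravingqtl pipeline config (flat key = value)\n"
        "# relative paths resolve against this file's directory\n"
        "genotype_path = genotypes.tsv\n"
        "phenotype_path = phenotypes.csv\n"
        "snp_table_path = snps.tsv\n"
        "risk_model_path = risk_model.tsv\n"
        "maf_min = 0.05\nhwe_alpha = 0.0001\ncall_rate_min = 0.9\n"
        f"seed = {seed}\n")
    return outdir
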