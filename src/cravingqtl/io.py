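"""File formats: genotype TSV, phenotype CSV, VCF (read-only), SNP
annotation TSV, association-results TSV and risk-model TSV.

The native genotype interchange format is a TSV with a "sample_id" header
column followed by one column per SNP; cells are "A/G"-style allele pairs
(order-insensitive, normalized alphabetically on read) or "./." for
missing. VCF reading (GT field only, biallelic records) is provided for
convenience; nothing is written back as VCF.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SNPInfo, MISSING_CODE, normalize_call
from .scoring import ITEM_COLUMNS, ITEM_MAX
from .association import AssociationResult
from .risk import RiskCoding, RiskModel

REQUIRED_PHENOTYPE_COLUMNS = ("sample_id", "age", "sex", "bmi") + ITEM_COLUMNS
OPTIONAL_PHENOTYPE_COLUMNS = ("mmt_max_dose", "onset_age", "use_duration",
                              "education", "marital")
RESULT_COLUMNS = ("snp", "gene", "pathway", "phenotype", "mode", "n", "beta",
                  "se", "t", "p_unadjusted", "p_adjusted", "r2")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line."""


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read the genotype TSV dialect into a GenotypeMatrix."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if not header or header[0] != "sample_id":
            raise ParseError(f"{path}:1: header must start with 'sample_id'")
        snp_ids = header[1:]
        if len(set(snp_ids)) != len(snp_ids):
            raise ParseError(f"{path}:1: duplicate SNP column")
        rows, index = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} "
                                 f"fields, got {len(row)}")
            sid = row[0]
            if sid in index:
                raise ParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            try:
                rows.append([normalize_call(c) for c in row[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            index.append(sid)
    frame = pd.DataFrame(rows, index=index, columns=snp_ids, dtype=object)
    frame.index.name = "sample_id"
    return GenotypeMatrix(frame, validate=False)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = matrix.calls.fillna(MISSING_CODE)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_vcf_genotypes(path: str | Path,
                       snp_ids: Sequence[str]) -> GenotypeMatrix:
    """Read GT calls for the requested record IDs from a VCF.

    Phase separators are ignored ("0|1" == "0/1"); "./." and half-missing
    calls map to missing. A requested record with more than one ALT
    allele is an error. Requested ids absent from the VCF yield all-
    missing columns.
    """
    from cyvcf2 import VCF

    wanted = list(snp_ids)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, list] = {}
    for record in vcf:
        if record.ID not in wanted:
            continue
        if len(record.ALT) != 1:
            raise ParseError(f"record {record.ID} is multiallelic "
                             f"(ALT={record.ALT})")
        alleles = (record.REF, record.ALT[0])
        calls = []
        for gt in record.genotypes:   # [a0, a1, phased]
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                calls.append(None)
            else:
                calls.append("/".join(sorted((alleles[a0], alleles[a1]))))
        columns[record.ID] = calls
    vcf.close()
    frame = pd.DataFrame(index=samples, columns=wanted, dtype=object)
    frame.index.name = "sample_id"
    for snp_id, calls in columns.items():
        frame[snp_id] = calls
    return GenotypeMatrix(frame, validate=False)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the phenotype CSV.

    Required columns: sample_id, age, sex (male/female), bmi and the 14
    item columns huc01..huc14. Optional clinical columns are kept when
    present. Items must be integers 0..4 (blank = missing, allowed but
    record is later unscorable); age and bmi must be positive.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_PHENOTYPE_COLUMNS
                    if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required column(s) {missing_cols}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample id(s) {dupes}")
    df = df.set_index("sample_id")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        row = df.index[bad_sex][0]
        raise ParseError(f"{path}: row {row!r}, column 'sex': expected "
                         "male/female")
    for col in ("age", "bmi"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(f"{path}: row {row!r}, column {col!r}: must be "
                             "a positive number")
        df[col] = vals
    for col in ITEM_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.notna()
        bad = present & (~vals.isin(range(ITEM_MAX + 1)))
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(f"{path}: row {row!r}, column {col!r}: item "
                             f"score must be an integer 0..{ITEM_MAX}")
        df[col] = vals
    keep = [c for c in df.columns
            if c in REQUIRED_PHENOTYPE_COLUMNS
            or c in OPTIONAL_PHENOTYPE_COLUMNS]
    return df[keep]


def write_phenotype_table(phenotypes: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in phenotypes.columns
            if c in REQUIRED_PHENOTYPE_COLUMNS
            or c in OPTIONAL_PHENOTYPE_COLUMNS]
    out = phenotypes[cols].copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_snp_table(path: str | Path) -> list[SNPInfo]:
    """Read the SNP annotation TSV: snp_id, gene, alleles, pathway."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_id", "gene", "alleles"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["snp_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate snp_id")
    out = []
    for _, row in df.iterrows():
        out.append(SNPInfo.from_allele_string(
            str(row["snp_id"]), str(row["gene"]), str(row["alleles"]),
            str(row.get("pathway", "") or "")))
    return out


def write_snp_table(snps: Sequence[SNPInfo], path: str | Path) -> None:
    pd.DataFrame([dict(snp_id=s.snp_id, gene=s.gene, alleles=s.allele_string,
                       pathway=s.pathway) for s in snps]
                 ).to_csv(path, sep="\t", index=False)


def _fmt(value: object) -> str:
    if isinstance(value, float):
        if np.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_association_results(results: Sequence[AssociationResult] | pd.DataFrame,
                              path: str | Path) -> None:
    """Write association results as a deterministic TSV.

    Columns: snp, gene, pathway, phenotype, mode, n, beta, se, t,
    p_unadjusted, p_adjusted, r2 — numbers at 6 significant digits. An
    empty result set is an error, not an empty file.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if "snp" not in df.columns and "snp_id" in df.columns:
            df = df.rename(columns={"snp_id": "snp"})
    else:
        df = pd.DataFrame([dict(snp=r.snp_id, gene="", pathway="",
                                phenotype=r.phenotype, mode=r.mode, n=r.n,
                                beta=r.beta, se=r.se, t=r.t,
                                p_unadjusted=r.p_unadjusted,
                                p_adjusted=r.p_adjusted, r2=r.r2)
                           for r in results])
    if df.empty:
        raise ValueError("no association results to write")
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("gene", "pathway") else np.nan
    df = df[list(RESULT_COLUMNS)]
    with Path(path).open("w", newline="") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_risk_model(model: RiskModel, snps: Sequence[SNPInfo],
                     path: str | Path) -> None:
    """Serialize a RiskModel as TSV (one row per component SNP)."""
    info = {s.snp_id: s for s in snps}
    rows = []
    for coding in model.codings:
        snp = info[coding.snp_id]
        rows.append(dict(snp_id=snp.snp_id, major_allele=snp.major_allele,
                         minor_allele=snp.minor_allele, mode=coding.mode,
                         risk_allele=coding.risk_allele,
                         code_hom_major=coding.codes[snp.hom_major],
                         code_het=coding.codes[snp.het],
                         code_hom_minor=coding.codes[snp.hom_minor]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_risk_model(path: str | Path) -> RiskModel:
    df = pd.read_csv(path, sep="\t")
    codings = []
    for _, row in df.iterrows():
        snp = SNPInfo(str(row["snp_id"]), gene="",
                      major_allele=str(row["major_allele"]),
                      minor_allele=str(row["minor_allele"]))
        codes = {snp.hom_major: int(row["code_hom_major"]),
                 snp.het: int(row["code_het"]),
                 snp.hom_minor: int(row["code_hom_minor"])}
        codings.append(RiskCoding(snp.snp_id, str(row["mode"]),
                                  str(row["risk_allele"]), codes))
    return RiskModel(codings=tuple(codings))


def write_table(df: pd.DataFrame, path: str | Path,
                index: bool = False) -> None:
    """Deterministic TSV writer for report tables (6 sig. digits)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", na_rep="NA")
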