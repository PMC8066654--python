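"""Core in-memory containers: genotype matrices and SNP metadata.

Genotype calls are unordered allele pairs ("A/G" means the same diploid
genotype as "G/A"); they are normalized to alphabetical order on entry so
that string equality is genotype equality. Missing calls are stored as NaN
internally and rendered as "./." on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_CODE = "./."
VALID_ALLELES = frozenset("ACGT")


def normalize_call(call: object) -> str | None:
    """Normalize a diploid call string to alphabetical allele order.

    Returns None for missing calls (None, NaN, "", or "./.").
    Raises ValueError for malformed calls or non-ACGT alleles.
    """
    if call is None:
        return None
    if isinstance(call, float) and np.isnan(call):
        return None
    s = str(call).strip()
    if s in ("", MISSING_CODE, "."):
        return None
    parts = s.replace("|", "/").split("/")
    if len(parts) != 2:
        raise ValueError(f"malformed genotype call {call!r}: expected 'X/Y'")
    a, b = parts[0].strip().upper(), parts[1].strip().upper()
    if a == "." and b == ".":
        return None
    for allele in (a, b):
        if allele not in VALID_ALLELES:
            raise ValueError(f"unknown allele character {allele!r} in call {call!r}")
    return "/".join(sorted((a, b)))


@dataclass(frozen=True)
class SNPInfo:
    """Per-SNP metadata: gene, declared allele pair, pathway label.

    ``major_allele``/``minor_allele`` follow the annotation table's
    "major > minor" allele string (e.g. "T > C" gives major T, minor C).
    """

    snp_id: str
    gene: str
    major_allele: str
    minor_allele: str
    pathway: str = ""

    def __post_init__(self) -> None:
        for allele in (self.major_allele, self.minor_allele):
            if allele not in VALID_ALLELES:
                raise ValueError(f"{self.snp_id}: invalid allele {allele!r}")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: alleles must be distinct")

    @classmethod
    def from_allele_string(cls, snp_id: str, gene: str, alleles: str,
                           pathway: str = "") -> "SNPInfo":
        """Build from a "T > C" style major>minor allele string."""
        parts = [p.strip() for p in alleles.split(">")]
        if len(parts) != 2:
            raise ValueError(f"{snp_id}: cannot parse allele string {alleles!r}")
        return cls(snp_id, gene, parts[0], parts[1], pathway)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.major_allele, self.minor_allele)

    @property
    def allele_string(self) -> str:
        return f"{self.major_allele} > {self.minor_allele}"

    def genotype(self, n_minor: int) -> str:
        """Normalized genotype string carrying ``n_minor`` minor alleles."""
        if n_minor not in (0, 1, 2):
            raise ValueError("minor-allele count must be 0, 1 or 2")
        calls = [self.major_allele] * (2 - n_minor) + [self.minor_allele] * n_minor
        return "/".join(sorted(calls))

    @property
    def hom_major(self) -> str:
        return self.genotype(0)

    @property
    def het(self) -> str:
        return self.genotype(1)

    @property
    def hom_minor(self) -> str:
        return self.genotype(2)


class GenotypeMatrix:
    """Samples x SNPs matrix of normalized diploid calls.

    Wraps a pandas DataFrame (index = sample ids, columns = SNP ids, values
    normalized call strings or NaN for missing). Construction validates and
    normalizes every call.
    """

    def __init__(self, calls: pd.DataFrame, *, validate: bool = True) -> None:
        if calls.index.has_duplicates:
            dupes = calls.index[calls.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        if calls.columns.has_duplicates:
            dupes = calls.columns[calls.columns.duplicated()].tolist()
            raise ValueError(f"duplicate SNP id(s): {dupes}")
        if validate:
            calls = calls.map(normalize_call)
        self.calls = calls.astype(object).where(calls.notna(), np.nan)

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_samples(self) -> int:
        return len(self.calls.index)

    @property
    def n_snps(self) -> int:
        return len(self.calls.columns)

    def column(self, snp_id: str) -> pd.Series:
        if snp_id not in self.calls.columns:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
        return self.calls[snp_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(sample_ids)], validate=False)

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[list(snp_ids)], validate=False)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.calls.equals(other.calls)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"
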