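"""Data model, validation and delimited-file I/O for GWAS summary statistics.

The canonical on-disk format is a tab-separated file with header
``SNP CHR POS EA OA EAF BETA SE P N`` and ``NA`` for missing values:
one row per SNP, effect sizes on the log-odds scale for binary traits and
in SD units for quantitative traits. Positions are 1-based. Only
single-nucleotide A/C/G/T alleles are accepted; the harmonization rules
downstream are defined for SNPs only.

Validation is total: any text file either yields a fully validated
:class:`GwasDataset` or raises a typed error; invalid rows are dropped
with a logged count, never partially kept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]
VALID_ALLELES = frozenset("ACGT")

#: Accepted spellings for column-map targets (field name -> canonical column).
_FIELD_ALIASES = {
    "snp_id": "SNP", "snp": "SNP", "rsid": "SNP",
    "chrom": "CHR", "chr": "CHR", "chromosome": "CHR",
    "pos": "POS", "position": "POS", "bp": "POS",
    "effect_allele": "EA", "ea": "EA", "a1": "EA",
    "other_allele": "OA", "oa": "OA", "a2": "OA",
    "eaf": "EAF", "effect_allele_frequency": "EAF",
    "beta": "BETA", "effect": "BETA",
    "se": "SE", "standard_error": "SE",
    "pval": "P", "p": "P", "p_value": "P", "pvalue": "P",
    "n": "N", "sample_size": "N", "samplesize": "N",
}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int | None = None
    eaf: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: non-finite beta")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: SE must be positive")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: p-value outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: EAF outside (0, 1)")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.snp_id}: sample size must be positive")


@dataclass
class GwasDataset:
    """A validated set of summary statistics for one trait.

    ``table`` holds the canonical columns (``CANONICAL_COLUMNS``) with one
    unique SNP per row. ``trait_type`` is ``"binary"`` (betas on the
    log-odds scale) or ``"quantitative"`` (SD units).
    """

    trait_id: str
    trait_type: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if len(self.table) == 0:
            raise EmptyInputError(f"{self.trait_id}: dataset has no records")
        if self.table["SNP"].duplicated().any():
            raise ValueError(f"{self.trait_id}: duplicate SNP identifiers")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"{self.trait_id}: missing columns {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["SNP"]

    def subset(self, snp_ids: Iterable[str], *, trait_id: str | None = None) -> "GwasDataset":
        """Rows for ``snp_ids``, preserving this dataset's row order."""
        wanted = set(snp_ids)
        sub = self.table[self.table["SNP"].isin(wanted)]
        if len(sub) == 0:
            raise EmptyInputError(f"{self.trait_id}: subset is empty")
        return GwasDataset(trait_id or self.trait_id, self.trait_type, sub.reset_index(drop=True))

    def records(self) -> Iterator[SummaryStatRecord]:
        for row in self.table.itertuples(index=False):
            yield SummaryStatRecord(
                snp_id=row.SNP, chrom=str(row.CHR), pos=int(row.POS),
                effect_allele=row.EA, other_allele=row.OA,
                beta=float(row.BETA), se=float(row.SE), pval=float(row.P),
                n=None if pd.isna(row.N) else int(row.N),
                eaf=None if pd.isna(row.EAF) else float(row.EAF),
            )

    @classmethod
    def from_records(cls, trait_id: str, trait_type: str,
                     records: Iterable[SummaryStatRecord]) -> "GwasDataset":
        rows = []
        for r in records:
            r.validate()
            rows.append((r.snp_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
                         np.nan if r.eaf is None else r.eaf, r.beta, r.se, r.pval,
                         pd.NA if r.n is None else r.n))
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        df["POS"] = df["POS"].astype("int64")
        df["N"] = df["N"].astype("Int64")
        return cls(trait_id, trait_type, df)


def _normalise_column_map(column_map: Mapping[str, str] | None,
                          file_columns: Iterable[str]) -> dict[str, str]:
    """Map *file* column names to canonical column names."""
    if column_map is None:
        return {c: c for c in file_columns if c in CANONICAL_COLUMNS}
    out = {}
    for file_col, target in column_map.items():
        key = target.strip().lower()
        if target in CANONICAL_COLUMNS:
            out[file_col] = target
        elif key in _FIELD_ALIASES:
            out[file_col] = _FIELD_ALIASES[key]
        else:
            raise ConfigurationError(f"unknown target field {target!r} in column map")
    return out


def _validate_table(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Vectorised record validation; returns the valid rows only."""
    ok = (
        df["SNP"].notna()
        & df["EA"].isin(list(VALID_ALLELES))
        & df["OA"].isin(list(VALID_ALLELES))
        & (df["EA"] != df["OA"])
        & np.isfinite(df["BETA"].to_numpy(dtype=float, na_value=np.nan))
        & (df["SE"] > 0)
        & (df["P"] > 0) & (df["P"] <= 1)
        & (df["EAF"].isna() | ((df["EAF"] > 0) & (df["EAF"] < 1)))
        & (df["N"].isna() | (df["N"] > 0))
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) violating record invariants", trait_id, n_bad)
    df = df[ok]
    dup = df["SNP"].duplicated()
    if dup.any():
        logger.warning("%s: dropped %d duplicate SNP id(s), keeping first occurrence",
                       trait_id, int(dup.sum()))
        df = df[~dup]
    return df


def read_gwas(path: str | Path, column_map: Mapping[str, str] | None = None, *,
              trait_id: str | None = None, trait_type: str = "quantitative",
              sep: str = "\t") -> GwasDataset:
    """Read a delimited summary-statistics file into a validated dataset.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Optional mapping of *file* column names to field names
        (``snp_id``, ``effect_allele`` …) or canonical column names, used
        to ingest common header dialects (e.g. ``{"A1": "effect_allele"}``).
        When omitted the canonical header is assumed.
    trait_id, trait_type:
        Trait metadata; ``trait_id`` defaults to the file stem.

    Raises
    ------
    ConfigurationError
        If a mandatory column (SNP, EA, OA, BETA, SE, P) cannot be resolved.
    EmptyInputError
        If no row survives validation.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA"])
    rename = _normalise_column_map(column_map, raw.columns)
    raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path.name}: cannot resolve mandatory column(s) {missing}")

    df = pd.DataFrame({"SNP": raw["SNP"].astype(str)})
    df["CHR"] = raw["CHR"].astype(str) if "CHR" in raw.columns else "0"
    df["POS"] = (pd.to_numeric(raw["POS"], errors="coerce").fillna(0).astype("int64")
                 if "POS" in raw.columns else 0)
    df["EA"] = raw["EA"].str.upper()
    df["OA"] = raw["OA"].str.upper()
    df["EAF"] = (pd.to_numeric(raw["EAF"], errors="coerce")
                 if "EAF" in raw.columns else np.nan)
    for col in ("BETA", "SE", "P"):
        df[col] = pd.to_numeric(raw[col], errors="coerce")
    df["N"] = (pd.to_numeric(raw["N"], errors="coerce").round().astype("Int64")
               if "N" in raw.columns else pd.NA)
    df["N"] = df["N"].astype("Int64")

    df = _validate_table(df, trait_id or path.stem)
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: no valid rows")
    return GwasDataset(trait_id or path.stem, trait_type, df.reset_index(drop=True))


def write_gwas(dataset: GwasDataset, path: str | Path) -> None:
    """Write a dataset to the canonical tab-separated format.

    ``read_gwas(write_gwas(d))`` reproduces ``d`` exactly, including
    missing-EAF sentinels (``NA``).
    """
    if len(dataset.table) == 0:  # pragma: no cover - unreachable via GwasDataset
        raise EmptyInputError("refusing to write an empty dataset")
    dataset.table.to_csv(path, sep="\t", index=False, na_rep="NA",
                         columns=CANONICAL_COLUMNS)
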