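"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS report a SNP relative to an arbitrary effect allele and strand;
before MR the outcome effect must be expressed per copy of the exposure's
effect allele. For each SNP shared by id:

a. same allele pair, same orientation — kept as is;
b. same pair, swapped orientation — outcome beta sign-flipped, EAF
   complemented;
c. alleles match only after strand complementation — complemented, then
   (a)/(b);
d. palindromic pairs (A/T, C/G) — strand cannot be resolved from the
   letters; orientation is inferred by requiring the two allele
   frequencies to fall on the same side of 0.5, and the SNP is dropped
   when either EAF is missing or lies inside the ambiguity window
   (default (0.42, 0.58));
e. anything else — unmatchable, dropped.

An audit of flip/drop counts is recorded on the result.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NoInstrumentsError
from .io import GwasDataset

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_WINDOW_DEFAULT = (0.42, 0.58)


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP exposure/outcome effect pairs ready for MR.

    ``table`` columns: snp_id, beta_exp, se_exp, beta_out, se_out,
    eaf_exp, eaf_out. ``audit`` counts the harmonization actions.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame = field(repr=False)
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise NoInstrumentsError(
                f"{self.exposure_id} -> {self.outcome_id}: no harmonized SNPs")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in harmonized set")
        if not ((self.table["se_exp"] > 0).all() and (self.table["se_out"] > 0).all()):
            raise ValueError("non-positive SE in harmonized set")

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = self.table
        return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
                t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))

    def drop(self, snp_ids) -> "HarmonizedInstrumentSet":
        keep = ~self.table["snp_id"].isin(set(snp_ids))
        return HarmonizedInstrumentSet(self.exposure_id, self.outcome_id,
                                       self.table[keep].reset_index(drop=True),
                                       dict(self.audit))

    def subset_without(self, index: int) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(
            self.exposure_id, self.outcome_id,
            self.table.drop(self.table.index[index]).reset_index(drop=True),
            dict(self.audit))


def _complement(series: pd.Series) -> pd.Series:
    return series.map(_COMPLEMENT)


def harmonize(exposure: GwasDataset, outcome: GwasDataset,
              palindromic_eaf_window: tuple[float, float] = PALINDROMIC_WINDOW_DEFAULT,
              ) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    Raises :class:`NoInstrumentsError` when no shared SNP survives, the
    signal on which a screening pipeline excludes the exposure.
    """
    lo, hi = palindromic_eaf_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("palindromic window must satisfy 0 <= lo < hi <= 1")

    merged = exposure.table.merge(outcome.table, on="SNP", suffixes=("_x", "_y"))
    if len(merged) == 0:
        raise NoInstrumentsError(
            f"{exposure.trait_id} -> {outcome.trait_id}: no shared SNPs")

    ea_x, oa_x = merged["EA_x"], merged["OA_x"]
    ea_y, oa_y = merged["EA_y"], merged["OA_y"]
    c_ea_y, c_oa_y = _complement(ea_y), _complement(oa_y)

    pal = (ea_x + oa_x).isin(["AT", "TA", "CG", "GC"]).to_numpy()
    same = ((ea_y == ea_x) & (oa_y == oa_x)).to_numpy()
    swap = ((ea_y == oa_x) & (oa_y == ea_x)).to_numpy()
    csame = ((c_ea_y == ea_x) & (c_oa_y == oa_x)).to_numpy()
    cswap = ((c_ea_y == oa_x) & (c_oa_y == ea_x)).to_numpy()

    fx = merged["EAF_x"].to_numpy(float)
    fy = merged["EAF_y"].to_numpy(float)
    by = merged["BETA_y"].to_numpy(float)

    # Non-palindromic resolution by allele letters alone.
    np_keep = ~pal & (same | csame)
    np_flip = ~pal & ~(same | csame) & (swap | cswap)
    np_strand = ~pal & ~(same | swap) & (csame | cswap)
    np_unmatch = ~pal & ~(same | swap | csame | cswap)

    # Palindromic: letters only align up to strand, orient by EAF side.
    pal_letters = pal & (same | swap)
    eaf_missing = np.isnan(fx) | np.isnan(fy)
    eaf_ambig = ((fx > lo) & (fx < hi)) | ((fy > lo) & (fy < hi))
    pal_drop = pal_letters & (eaf_missing | eaf_ambig)
    pal_keep = pal_letters & ~pal_drop
    pal_unmatch = pal & ~pal_letters

    # Letter-level alignment for palindromic keepers (A/T vs T/A).
    fy_aligned = np.where(pal_keep & swap, 1.0 - fy, fy)
    by_aligned = np.where(pal_keep & swap, -by, by)
    side_mismatch = pal_keep & ((fx < 0.5) != (fy_aligned < 0.5))
    pal_by = np.where(side_mismatch, -by_aligned, by_aligned)
    pal_fy = np.where(side_mismatch, 1.0 - fy_aligned, fy_aligned)

    beta_out = np.where(np_flip, -by, by)
    eaf_out = np.where(np_flip, 1.0 - fy, fy)
    beta_out = np.where(pal_keep, pal_by, beta_out)
    eaf_out = np.where(pal_keep, pal_fy, eaf_out)

    kept = np_keep | np_flip | pal_keep
    pal_net_flip = pal_keep & (swap != side_mismatch)

    audit = {
        "n_shared": int(len(merged)),
        "n_kept": int(kept.sum()),
        "n_sign_flipped": int(np_flip.sum() + pal_net_flip.sum()),
        "n_strand_corrected": int(np_strand.sum()),
        "n_palindromic_kept": int(pal_keep.sum()),
        "n_dropped_palindromic": int(pal_drop.sum()),
        "n_dropped_unmatchable": int((np_unmatch | pal_unmatch).sum()),
    }
    if audit["n_dropped_palindromic"]:
        logger.warning("%s -> %s: dropped %d ambiguous palindromic SNP(s)",
                       exposure.trait_id, outcome.trait_id,
                       audit["n_dropped_palindromic"])
    if audit["n_dropped_unmatchable"]:
        logger.warning("%s -> %s: dropped %d unmatchable SNP(s)",
                       exposure.trait_id, outcome.trait_id,
                       audit["n_dropped_unmatchable"])

    table = pd.DataFrame({
        "snp_id": merged["SNP"],
        "beta_exp": merged["BETA_x"].to_numpy(float),
        "se_exp": merged["SE_x"].to_numpy(float),
        "beta_out": beta_out,
        "se_out": merged["SE_y"].to_numpy(float),
        "eaf_exp": fx,
        "eaf_out": eaf_out,
    })[kept].reset_index(drop=True)

    if len(table) == 0:
        raise NoInstrumentsError(
            f"{exposure.trait_id} -> {outcome.trait_id}: all shared SNPs dropped")
    return HarmonizedInstrumentSet(exposure.trait_id, outcome.trait_id, table, audit)
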