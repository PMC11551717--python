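"""Instrumental-variable selection for two-sample MR.

Implements the conventional screening funnel: genome-wide association
threshold (p < 1e-5 for under-powered exposures such as microbial taxa),
greedy LD clumping against a reference panel (r² < 0.001 within 10 Mb,
keeping the lowest-p SNP of every linked group), per-SNP instrument
strength F = (β/SE)² with an F ≥ 10 cut-off, and a user-supplied
confounder exclusion list (the pluggable stand-in for a PhenoScanner
lookup).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable, Mapping

import pandas as pd

from .exceptions import NoInstrumentsError
from .io import GwasDataset, SummaryStatRecord

logger = logging.getLogger(__name__)

_R2_CAP = 1.0 - 1e-12


@dataclass(frozen=True)
class InstrumentRecord:
    """A candidate instrument annotated with strength statistics.

    ``r_squared`` (variance explained, ``2·EAF·(1−EAF)·β²`` for a
    standardized trait) is ``None`` when the record has no EAF.
    """

    record: SummaryStatRecord
    f_statistic: float
    r_squared: float | None


class LdPanel:
    """Pairwise r² lookup for SNPs, the interface to an LD reference panel.

    Pairs absent from the table are treated as unlinked (r² = 0); a SNP is
    *known* to the panel if it appears in the panel's SNP set. ``r²(x, x)``
    is 1 by definition.
    """

    def __init__(self, r2_pairs: Mapping[tuple[str, str], float] | None = None,
                 snps: Iterable[str] | None = None):
        self._r2: dict[frozenset, float] = {}
        known = set() if snps is None else set(snps)
        for (a, b), r2 in (r2_pairs or {}).items():
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"r2 outside [0, 1] for pair ({a}, {b})")
            self._r2[frozenset((a, b))] = r2
            known.update((a, b))
        self._snps = known

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdPanel":
        """Load a 3-column TSV (snp_a, snp_b, r2) with a header row."""
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        pairs = {(str(r.snp_a), str(r.snp_b)): float(r.r2)
                 for r in df.itertuples(index=False)}
        return cls(pairs)

    @classmethod
    def independent(cls, snp_ids: Iterable[str]) -> "LdPanel":
        """A panel in which every listed SNP is unlinked from every other."""
        return cls({}, snps=snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._snps

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)


def select_by_pvalue(dataset: GwasDataset, threshold: float = 1e-5) -> GwasDataset:
    """Keep SNPs with p strictly below ``threshold``."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    mask = dataset.table["P"] < threshold
    if not mask.any():
        raise NoInstrumentsError(
            f"{dataset.trait_id}: no SNP passes p < {threshold:g}")
    return GwasDataset(dataset.trait_id, dataset.trait_type,
                       dataset.table[mask].reset_index(drop=True))


def ld_clump(dataset: GwasDataset, panel: LdPanel | None,
             r2_threshold: float = 0.001, window_kb: int = 10_000) -> GwasDataset:
    """Greedy LD clumping: retain independent SNPs with the lowest p-values.

    SNPs are visited in ascending p-value order (ties broken by smaller SE,
    then lexicographic SNP id, for determinism); each kept SNP removes all
    unkept SNPs on the same chromosome within ``window_kb`` whose r²
    against it reaches ``r2_threshold``. SNPs the panel does not know are
    dropped with a warning (conservative). ``panel=None`` declares all
    SNPs independent, the correct statement for the LD-free synthetic data.
    Output preserves the original dataset order.
    """
    if panel is None:
        return dataset
    tab = dataset.table
    known = tab["SNP"].map(lambda s: s in panel)
    if not known.all():
        logger.warning("%s: dropped %d SNP(s) absent from the LD panel",
                       dataset.trait_id, int((~known).sum()))
        tab = tab[known]
    if len(tab) == 0:
        raise NoInstrumentsError(f"{dataset.trait_id}: no SNP present in the LD panel")

    order = tab.sort_values(["P", "SE", "SNP"], kind="mergesort")
    window_bp = window_kb * 1000
    kept: list[str] = []
    removed: set[str] = set()
    rows = list(order.itertuples(index=False))
    for i, row in enumerate(rows):
        if row.SNP in removed:
            continue
        kept.append(row.SNP)
        for other in rows[i + 1:]:
            if other.SNP in removed or other.CHR != row.CHR:
                continue
            if abs(int(other.POS) - int(row.POS)) <= window_bp \
                    and panel.r2(row.SNP, other.SNP) >= r2_threshold:
                removed.add(other.SNP)
    keep_mask = dataset.table["SNP"].isin(kept)
    return GwasDataset(dataset.trait_id, dataset.trait_type,
                       dataset.table[keep_mask].reset_index(drop=True))


def compute_strength(record: SummaryStatRecord, n: int | None = None) -> InstrumentRecord:
    """Annotate one record with its per-SNP F statistic and explained variance.

    F = (β/SE)². R² uses the standardized-trait approximation
    2·EAF·(1−EAF)·β², capped just below 1; it is reported missing when the
    record carries no EAF (the SNP is not excluded on that basis).
    ``n`` is accepted for interface symmetry with sample-size-based R²
    formulas but is not needed by these estimators.
    """
    f = (record.beta / record.se) ** 2
    if record.eaf is None:
        r2 = None
    else:
        r2 = min(2.0 * record.eaf * (1.0 - record.eaf) * record.beta ** 2, _R2_CAP)
    return InstrumentRecord(record=record, f_statistic=f, r_squared=r2)


def filter_by_f(instruments: Collection[InstrumentRecord],
                cutoff: float = 10.0) -> list[InstrumentRecord]:
    """Keep instruments with F ≥ cutoff (boundary inclusive)."""
    kept = [ins for ins in instruments if ins.f_statistic >= cutoff]
    if not kept:
        raise NoInstrumentsError(f"no instrument reaches F >= {cutoff:g}")
    return kept


def strength_table(dataset: GwasDataset) -> pd.DataFrame:
    """Vectorised F and R² for a whole dataset (columns SNP, F, R2)."""
    tab = dataset.table
    f = (tab["BETA"] / tab["SE"]) ** 2
    r2 = (2.0 * tab["EAF"] * (1.0 - tab["EAF"]) * tab["BETA"] ** 2).clip(upper=_R2_CAP)
    return pd.DataFrame({"SNP": tab["SNP"], "F": f, "R2": r2})


def filter_dataset_by_f(dataset: GwasDataset, cutoff: float = 10.0) -> GwasDataset:
    """Dataset-level F filter, the screening counterpart of :func:`filter_by_f`."""
    mask = (dataset.table["BETA"] / dataset.table["SE"]) ** 2 >= cutoff
    if not mask.any():
        raise NoInstrumentsError(
            f"{dataset.trait_id}: no instrument reaches F >= {cutoff:g}")
    return GwasDataset(dataset.trait_id, dataset.trait_type,
                       dataset.table[mask].reset_index(drop=True))


def apply_exclusion_list(dataset: GwasDataset,
                         excluded_snps: Collection[str]) -> GwasDataset:
    """Remove listed SNPs (e.g. known confounder associations).

    Unknown ids are ignored with a log line; removing every SNP raises the
    no-instruments signal.
    """
    excluded = set(excluded_snps)
    present = set(dataset.table["SNP"])
    unknown = excluded - present
    if unknown:
        logger.info("%s: %d excluded SNP id(s) not present in dataset",
                    dataset.trait_id, len(unknown))
    mask = ~dataset.table["SNP"].isin(excluded)
    if not mask.any():
        raise NoInstrumentsError(f"{dataset.trait_id}: exclusion list removes all SNPs")
    return GwasDataset(dataset.trait_id, dataset.trait_type,
                       dataset.table[mask].reset_index(drop=True))
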