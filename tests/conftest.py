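"""Shared fixtures and small dataset builders for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrmediate.harmonize import HarmonizedInstrumentSet
from mrmediate.io import CANONICAL_COLUMNS, GwasDataset


def make_dataset(trait_id="trait", trait_type="quantitative", *, snp, beta, se,
                 pval=None, ea=None, oa=None, eaf=None, chrom=None, pos=None,
                 n=None) -> GwasDataset:
    """Build a GwasDataset from parallel arrays with sensible defaults."""
    m = len(snp)
    from scipy import stats
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pval is None:
        pval = np.clip(2 * stats.norm.sf(np.abs(beta) / se), 5e-324, 1.0)
    df = pd.DataFrame({
        "SNP": list(snp),
        "CHR": list(chrom) if chrom is not None else ["1"] * m,
        "POS": list(pos) if pos is not None else list(range(1, m + 1)),
        "EA": list(ea) if ea is not None else ["A"] * m,
        "OA": list(oa) if oa is not None else ["G"] * m,
        "EAF": list(eaf) if eaf is not None else [0.3] * m,
        "BETA": beta, "SE": se, "P": np.asarray(pval, float),
        "N": pd.array([10_000] * m if n is None else list(n), dtype="Int64"),
    }, columns=CANONICAL_COLUMNS)
    return GwasDataset(trait_id, trait_type, df)


def make_hset(bx, sx, by, sy, snp=None, exposure_id="exp", outcome_id="out",
              eaf_exp=None, eaf_out=None) -> HarmonizedInstrumentSet:
    """Build a harmonized instrument set directly from effect arrays."""
    m = len(bx)
    table = pd.DataFrame({
        "snp_id": list(snp) if snp is not None else [f"rs{i}" for i in range(m)],
        "beta_exp": np.asarray(bx, float), "se_exp": np.asarray(sx, float),
        "beta_out": np.asarray(by, float), "se_out": np.asarray(sy, float),
        "eaf_exp": list(eaf_exp) if eaf_exp is not None else [0.3] * m,
        "eaf_out": list(eaf_out) if eaf_out is not None else [0.3] * m,
    })
    return HarmonizedInstrumentSet(exposure_id, outcome_id, table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_hset(rng):
    """A generic heterogeneous 6-SNP instrument set."""
    m = 6
    bx = rng.normal(0.2, 0.05, m)
    return make_hset(bx, np.full(m, 0.01), 0.4 * bx + rng.normal(0, 0.02, m),
                     rng.uniform(0.01, 0.03, m))
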