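"""Instrument selection: p-value screen, LD clumping, strength filters."""
import logging

import numpy as np
import pytest

from mrmediate.exceptions import NoInstrumentsError
from mrmediate.instruments import (LdPanel, apply_exclusion_list, compute_strength,
                                   filter_by_f, filter_dataset_by_f, ld_clump,
                                   select_by_pvalue, strength_table)
from mrmediate.io import SummaryStatRecord

from conftest import make_dataset


def _record(beta, se, eaf=0.3, snp="rs1"):
    return SummaryStatRecord(snp_id=snp, chrom="1", pos=1, effect_allele="A",
                             other_allele="G", beta=beta, se=se, pval=0.5,
                             n=1000, eaf=eaf)


# ---------------------------------------------------------------- p-value screen

def test_pvalue_selection_is_strict_and_signals_empty():
    ds = make_dataset(snp=["rs1", "rs2"], beta=[0.1, 0.1], se=[0.01, 0.01],
                      pval=[1e-6, 1e-4])
    assert select_by_pvalue(ds, 1e-5).snp_ids.tolist() == ["rs1"]
    assert select_by_pvalue(ds, 1.0).n_snps == 2
    with pytest.raises(NoInstrumentsError):
        select_by_pvalue(ds, 1e-7)
    # strict inequality at the boundary
    ds_b = make_dataset(snp=["rs1"], beta=[0.1], se=[0.01], pval=[1e-5])
    with pytest.raises(NoInstrumentsError):
        select_by_pvalue(ds_b, 1e-5)


# ------------------------------------------------------------------- LD clumping

def _clump_fixture(pvals, chrom=None, pos=None):
    m = len(pvals)
    return make_dataset(snp=[f"rs{i}" for i in range(m)], beta=[0.1] * m,
                        se=[0.01] * m, pval=pvals, chrom=chrom,
                        pos=pos if pos is not None else [1000 * i for i in range(1, m + 1)])


def test_clump_keeps_lowest_p_of_linked_pair():
    ds = _clump_fixture([1e-8, 1e-6])
    panel = LdPanel({("rs0", "rs1"): 0.5})
    assert ld_clump(ds, panel).snp_ids.tolist() == ["rs0"]


def test_clump_retains_pairs_below_r2_threshold():
    ds = _clump_fixture([1e-8, 1e-6])
    panel = LdPanel({("rs0", "rs1"): 0.0005})
    assert ld_clump(ds, panel, r2_threshold=0.001).n_snps == 2


def test_clump_window_limits_linkage():
    # strongly linked but 20 Mb apart: both kept under a 10 Mb window
    ds = _clump_fixture([1e-8, 1e-6], pos=[1, 20_000_001])
    panel = LdPanel({("rs0", "rs1"): 0.9})
    assert ld_clump(ds, panel, window_kb=10_000).n_snps == 2
    assert ld_clump(ds, panel, window_kb=30_000).n_snps == 1


def test_snp_missing_from_panel_is_dropped_with_warning(caplog):
    ds = _clump_fixture([1e-8, 1e-6])
    panel = LdPanel({}, snps={"rs0"})
    with caplog.at_level(logging.WARNING):
        kept = ld_clump(ds, panel)
    assert kept.snp_ids.tolist() == ["rs0"]
    assert any("absent from the LD panel" in r.message for r in caplog.records)


def _greedy_oracle(ds, panel, r2_threshold, window_bp):
    """Independent characterisation: a SNP is kept iff it is not linked to
    any kept SNP with smaller (p, se, id)."""
    rows = ds.table.sort_values(["P", "SE", "SNP"], kind="mergesort")
    kept = []
    for row in rows.itertuples(index=False):
        linked = any(k.CHR == row.CHR and abs(int(k.POS) - int(row.POS)) <= window_bp
                     and panel.r2(k.SNP, row.SNP) >= r2_threshold for k in kept)
        if not linked:
            kept.append(row)
    return sorted(k.SNP for k in kept)


@pytest.mark.parametrize("seed", range(8))
def test_clump_matches_bruteforce_oracle_on_small_fixtures(seed):
    rng = np.random.default_rng(seed)
    m = 6
    ds = make_dataset(snp=[f"rs{i}" for i in range(m)], beta=rng.normal(0, 0.1, m),
                      se=rng.uniform(0.005, 0.02, m),
                      pval=rng.uniform(1e-9, 1e-4, m),
                      chrom=rng.choice(["1", "2"], m),
                      pos=rng.integers(1, 5_000_000, m))
    pairs = {}
    ids = ds.snp_ids.tolist()
    for i in range(m):
        for j in range(i + 1, m):
            pairs[(ids[i], ids[j])] = float(rng.uniform(0, 1) * (rng.random() < 0.5))
    panel = LdPanel(pairs)
    kept = ld_clump(ds, panel, 0.1, 10_000)
    assert sorted(kept.snp_ids) == _greedy_oracle(ds, panel, 0.1, 10_000_000)
    # invariant: no kept pair on the same chromosome within window is linked
    tab = kept.table
    for i in range(len(tab)):
        for j in range(i + 1, len(tab)):
            a, b = tab.iloc[i], tab.iloc[j]
            if a.CHR == b.CHR and abs(int(a.POS) - int(b.POS)) <= 10_000_000:
                assert panel.r2(a.SNP, b.SNP) < 0.1


def test_clump_preserves_original_order():
    ds = _clump_fixture([1e-4, 1e-8, 1e-6])
    panel = LdPanel.independent(ds.snp_ids)
    assert ld_clump(ds, panel).snp_ids.tolist() == ["rs0", "rs1", "rs2"]


# ------------------------------------------------------------ instrument strength

def test_f_statistic_and_r2_arithmetic():
    assert compute_strength(_record(0.05, 0.01)).f_statistic == pytest.approx(25.0)
    assert compute_strength(_record(0.03, 0.03)).f_statistic == pytest.approx(1.0)
    assert compute_strength(_record(0.1, 0.01, eaf=0.5)).r_squared == pytest.approx(0.005)
    assert compute_strength(_record(0.1, 0.01, eaf=None)).r_squared is None


def test_strength_invariant_to_allele_reorientation():
    a = compute_strength(_record(0.1, 0.01, eaf=0.2))
    b = compute_strength(_record(-0.1, 0.01, eaf=0.8))
    assert a.f_statistic == pytest.approx(b.f_statistic)
    # eaf complement leaves 2*eaf*(1-eaf) unchanged
    assert a.r_squared == pytest.approx(b.r_squared)


def test_f_filter_boundary_is_inclusive():
    recs = [compute_strength(_record(b, 0.01, snp=f"rs{i}"))
            for i, b in enumerate([0.05, 0.03, np.sqrt(10) * 0.01])]
    kept = filter_by_f(recs, 10.0)
    assert len(kept) == 2
    assert filter_by_f(recs, 0.0) == recs
    with pytest.raises(NoInstrumentsError):
        filter_by_f(recs, 1e6)


def test_dataset_f_filter_agrees_with_per_record_path(rng):
    m = 40
    ds = make_dataset(snp=[f"rs{i}" for i in range(m)],
                      beta=rng.normal(0, 0.05, m), se=rng.uniform(0.005, 0.03, m))
    kept = filter_dataset_by_f(ds, 10.0)
    oracle = {r.snp_id for r in ds.records()
              if compute_strength(r).f_statistic >= 10.0}
    assert set(kept.snp_ids) == oracle
    tab = strength_table(ds)
    assert np.allclose(tab.F, (ds.table.BETA / ds.table.SE) ** 2)


# ----------------------------------------------------------------- exclusion list

def test_exclusion_list_behaviour():
    ds = make_dataset(snp=["rs1", "rs2"], beta=[0.1, 0.2], se=[0.01, 0.01])
    assert apply_exclusion_list(ds, set()).n_snps == 2
    assert apply_exclusion_list(ds, {"rs1", "rs_unknown"}).snp_ids.tolist() == ["rs2"]
    with pytest.raises(NoInstrumentsError):
        apply_exclusion_list(ds, {"rs1", "rs2"})
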