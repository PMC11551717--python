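"""Heterogeneity and pleiotropy diagnostics for an MR analysis.

Cochran's Q over per-SNP Wald ratios, leave-one-out influence analysis,
and a residual-bootstrap outlier test in the style of MR-PRESSO: the
observed weighted residual sum of squares around leave-one-out IVW fits
is compared to its parametric simulation distribution (global test), and
each SNP's residual term to its own simulated distribution with
Bonferroni correction (outlier test). Monte-Carlo p-values use the
add-one (r+1)/(n+1) rule so they are never exactly zero.

The distortion step of the original MR-PRESSO procedure (re-estimating
the causal effect after outlier removal) is deliberately not part of the
report: the diagnostics here gate claims, they do not correct estimates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import egger, ivw
from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedInstrumentSet

PRESSO_NSIM_DEFAULT = 5000
OUTLIER_SIGNIFICANCE_DEFAULT = 0.05


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one harmonized instrument set."""

    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outlier_snps: list = field(default_factory=list)
    loo_table: pd.DataFrame | None = None
    heterogeneous: bool = False
    pleiotropic: bool = False


def cochran_q(instrument_set: HarmonizedInstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios: (Q, df, p).

    Q = Σ w_j (r_j − β_IVW,fixed)² with r_j = beta_out/beta_exp and
    w_j = beta_exp²/se_out²; p from the chi-square with n−1 df.
    """
    n = instrument_set.n_snp
    if n < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    bx, _, by, sy = instrument_set.arrays()
    w = 1.0 / sy ** 2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = n - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(instrument_set: HarmonizedInstrumentSet,
                  mode: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn.

    Returns a table (snp_id, beta_without, se_without, pval_without) with
    exactly one row per SNP.
    """
    n = instrument_set.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 instruments")
    rows = []
    for i in range(n):
        est = ivw(instrument_set.subset_without(i), mode=mode)
        rows.append((instrument_set.table["snp_id"].iloc[i],
                     est.beta, est.se, est.pval))
    return pd.DataFrame(rows, columns=["snp_id", "beta_without",
                                       "se_without", "pval_without"])


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope with SNP j removed, for every j, in one pass."""
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx * bx) - w * bx * bx
    return num / den


def mr_presso(instrument_set: HarmonizedInstrumentSet,
              n_sim: int = PRESSO_NSIM_DEFAULT,
              outlier_significance: float = OUTLIER_SIGNIFICANCE_DEFAULT,
              seed: int = 0) -> tuple[float, list[tuple[str, float]]]:
    """Residual-bootstrap pleiotropy test (global + per-SNP outliers).

    Observed statistic: RSS_obs = Σ_j w_j (beta_out_j − β(−j)·beta_exp_j)²
    with w_j = 1/se_out_j² and β(−j) the leave-one-out fixed IVW estimate.
    Each simulation redraws beta_exp* ~ N(beta_exp, se_exp²) and
    beta_out* ~ N(β(−j)·beta_exp_j, se_out²), then recomputes the same
    statistic on the simulated study. The global p is the add-one tail
    fraction of RSS* ≥ RSS_obs; per-SNP residual terms get the same
    treatment with Bonferroni at ``outlier_significance`` across SNPs.

    Returns ``(global_p, flagged)`` with ``flagged`` a list of
    (snp_id, outlier_p) pairs. Deterministic given ``seed``.
    """
    n = instrument_set.n_snp
    if n < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")

    bx, sx, by, sy = instrument_set.arrays()
    w = 1.0 / sy ** 2
    beta_loo = _loo_ivw_betas(bx, by, w)
    resid_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, n))
    by_star = rng.normal(beta_loo * bx, sy, size=(n_sim, n))

    w_row = w[None, :]
    num = np.sum(w_row * bx_star * by_star, axis=1, keepdims=True) \
        - w_row * bx_star * by_star
    den = np.sum(w_row * bx_star * bx_star, axis=1, keepdims=True) \
        - w_row * bx_star * bx_star
    beta_loo_star = num / den
    resid_star = w_row * (by_star - beta_loo_star * bx_star) ** 2
    rss_star = np.sum(resid_star, axis=1)

    global_p = (int(np.sum(rss_star >= rss_obs)) + 1) / (n_sim + 1)

    outlier_p = (np.sum(resid_star >= resid_obs[None, :], axis=0) + 1) / (n_sim + 1)
    threshold = outlier_significance / n
    snp_ids = instrument_set.table["snp_id"].to_numpy()
    flagged = [(str(snp_ids[j]), float(outlier_p[j]))
               for j in np.nonzero(outlier_p < threshold)[0]]
    return float(global_p), flagged


def sensitivity_report(instrument_set: HarmonizedInstrumentSet,
                       n_sim: int = PRESSO_NSIM_DEFAULT,
                       outlier_significance: float = OUTLIER_SIGNIFICANCE_DEFAULT,
                       seed: int = 0, alpha: float = 0.05) -> SensitivityReport:
    """Run every diagnostic the instrument count allows and set the flags.

    ``heterogeneous`` means Q p < alpha; ``pleiotropic`` means the Egger
    intercept test or the PRESSO global test rejects at alpha — the rule
    used to gate causal claims in the screening pipeline.
    """
    report = SensitivityReport(n_snp=instrument_set.n_snp)
    if instrument_set.n_snp >= 2:
        report.q_stat, report.q_df, report.q_pval = cochran_q(instrument_set)
        report.heterogeneous = report.q_pval < alpha
    if instrument_set.n_snp >= 3:
        _, intercept = egger(instrument_set)
        report.egger_intercept = intercept.beta
        report.egger_intercept_se = intercept.se
        report.egger_intercept_pval = intercept.pval
        report.loo_table = leave_one_out(instrument_set)
    if instrument_set.n_snp >= 4:
        report.presso_global_pval, report.presso_outlier_snps = mr_presso(
            instrument_set, n_sim=n_sim,
            outlier_significance=outlier_significance, seed=seed)
    report.pleiotropic = bool(
        (report.egger_intercept_pval is not None and report.egger_intercept_pval < alpha)
        or (report.presso_global_pval is not None and report.presso_global_pval < alpha))
    return report
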