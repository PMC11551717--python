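"""Core two-sample MR estimators: Wald ratio, IVW, MR-Egger.

All estimators act on a :class:`~mrmediate.harmonize.HarmonizedInstrumentSet`
and return :class:`MrEstimate` objects carrying the effect on the
log-odds/SD scale together with its odds-ratio representation. Inference
uses the normal approximation throughout (1.96 quantile for 95% CIs,
two-sided normal p-values), matching how OR/CI arithmetic is conventionally
printed from summary-data MR.

The IVW estimator is weighted least squares of outcome on exposure effects
through the origin with weights 1/se_out²; equivalently the inverse
variance weighted mean of per-SNP Wald ratios r_j with weights
w_j = beta_exp_j²/se_out_j². The default multiplicative random-effects
mode inflates the fixed-effect SE by max(1, sqrt(Q/(n−1))), which is
robust to heterogeneity; fixed-effect is available explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import (DegenerateInputError, InsufficientInstrumentsError,
                         NoInstrumentsError, UndefinedRatioError)
from .harmonize import HarmonizedInstrumentSet

Z95 = 1.96
_MIN_P = 5e-324


@dataclass(frozen=True)
class MrEstimate:
    """A causal estimate on the log-odds (binary outcome) or SD scale."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def _two_sided_p(z: float) -> float:
    return float(min(max(2.0 * stats.norm.sf(abs(z)), _MIN_P), 1.0))


def to_odds_ratio(estimate: MrEstimate) -> MrEstimate:
    """Fill the OR and 95% CI fields from beta and SE."""
    return replace(estimate,
                   odds_ratio=float(np.exp(estimate.beta)),
                   ci_low=float(np.exp(estimate.beta - Z95 * estimate.se)),
                   ci_high=float(np.exp(estimate.beta + Z95 * estimate.se)))


def _estimate(method: str, n_snp: int, beta: float, se: float) -> MrEstimate:
    est = MrEstimate(method=method, n_snp=n_snp, beta=float(beta), se=float(se),
                     pval=_two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else _MIN_P))
    return to_odds_ratio(est)


def wald_ratio(entry: Mapping | "object") -> MrEstimate:
    """Single-SNP causal estimate beta_out/beta_exp.

    ``entry`` is one harmonized SNP entry (mapping, Series or namedtuple
    with fields beta_exp, se_exp, beta_out, se_out). The SE is the
    first-order delta approximation se_out/|beta_exp|.
    """
    get = entry.__getitem__ if hasattr(entry, "__getitem__") else \
        lambda k: getattr(entry, k)
    bx, by, sy = float(get("beta_exp")), float(get("beta_out")), float(get("se_out"))
    if bx == 0.0:
        raise UndefinedRatioError("Wald ratio undefined: beta_exp is zero")
    return _estimate("wald_ratio", 1, by / bx, sy / abs(bx))


def ivw(instrument_set: HarmonizedInstrumentSet,
        mode: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted estimate over all instruments.

    A single-SNP set delegates to :func:`wald_ratio` exactly.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    n = instrument_set.n_snp
    if n < 1:  # pragma: no cover - HarmonizedInstrumentSet forbids this
        raise NoInstrumentsError("IVW needs at least one instrument")
    if n == 1:
        return wald_ratio(instrument_set.table.iloc[0])

    bx, _, by, sy = instrument_set.arrays()
    w = 1.0 / sy ** 2
    swxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / swxx
    se = 1.0 / np.sqrt(swxx)
    method = "ivw_fixed"
    if mode == "multiplicative_random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (n - 1)))
        method = "ivw_mre"
    return _estimate(method, n, beta, se)


def egger(instrument_set: HarmonizedInstrumentSet) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Each SNP is re-oriented so beta_exp ≥ 0 (fixing the intercept's sign
    convention), then outcome effects are regressed on exposure effects
    with an unconstrained intercept, weights 1/se_out². Both SEs carry the
    multiplicative dispersion floor max(1, sqrt(Q_egger/(n−2))). The
    intercept's p-value is the directional-pleiotropy test.
    """
    n = instrument_set.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = instrument_set.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = sign * bx, sign * by
    w = 1.0 / sy ** 2

    sw = float(np.sum(w))
    swx = float(np.sum(w * x))
    swy = float(np.sum(w * y))
    swxx = float(np.sum(w * x * x))
    swxy = float(np.sum(w * x * y))
    det = sw * swxx - swx ** 2
    if det <= np.finfo(float).eps * sw * swxx:
        raise DegenerateInputError("MR-Egger undefined: no spread in exposure effects")

    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    q_e = float(np.sum(w * (y - intercept - slope * x) ** 2))
    scale = max(1.0, np.sqrt(q_e / (n - 2)))
    se_slope = np.sqrt(sw / det) * scale
    se_int = np.sqrt(swxx / det) * scale
    return (_estimate("egger_slope", n, slope, se_slope),
            _estimate("egger_intercept", n, intercept, se_int))
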