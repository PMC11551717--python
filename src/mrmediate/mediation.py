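"""Two-step mediation decomposition of a total MR effect.

The total exposure→outcome effect β_total is decomposed into an indirect
component transmitted through the mediator, estimated by the product
method β_A·β_B (β_A: exposure→mediator MR; β_B: mediator→outcome MR using
the mediator's own instruments), and the direct remainder
β_direct = β_total − β_A·β_B. The indirect effect's SE is the first-order
delta (Sobel) formula; its confidence interval and the mediated
proportion's interval come from Monte-Carlo propagation of the product
(and ratio) of normal draws, the distribution-of-product approach.

A pathway is reported *significant* when the indirect-effect p-value is
below 0.05 and the mediated proportion lies strictly between 0 and 100%.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import LegFailureError, NoInstrumentsError, UndefinedProportionError

_MIN_P = 5e-324
PRODUCT_DRAWS_DEFAULT = 100_000


@dataclass(frozen=True)
class MediationResult:
    """Effect decomposition for one exposure→mediator→outcome pathway."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    se_total: float
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    beta_indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    indirect_pval: float
    beta_direct: float
    proportion: float
    proportion_ci: tuple[float, float]
    significant: bool


def indirect_effect(beta_a: float, se_a: float, beta_b: float, se_b: float,
                    ) -> tuple[float, float, float]:
    """Product-method indirect effect with Sobel SE and normal p.

    beta_indirect = β_A·β_B;
    SE = sqrt(β_A²·se_B² + β_B²·se_A²) (first-order delta).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    ab = beta_a * beta_b
    se = float(np.sqrt(beta_a ** 2 * se_b ** 2 + beta_b ** 2 * se_a ** 2))
    if se == 0.0:
        p = 1.0 if ab == 0.0 else _MIN_P
    else:
        p = float(min(max(2.0 * stats.norm.sf(abs(ab) / se), _MIN_P), 1.0))
    return float(ab), se, p


def product_ci(beta_a: float, se_a: float, beta_b: float, se_b: float,
               n_draws: int = PRODUCT_DRAWS_DEFAULT, seed: int = 0,
               level: float = 0.95) -> tuple[float, float]:
    """Monte-Carlo distribution-of-product confidence interval for β_A·β_B.

    Draws a* ~ N(β_A, se_A²) and b* ~ N(β_B, se_B²) independently and
    takes the empirical (α/2, 1−α/2) quantiles of a*·b*. Deterministic
    given ``seed``. With zero SEs the interval degenerates to the point.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10,000")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    prod = rng.normal(beta_a, se_a, n_draws) * rng.normal(beta_b, se_b, n_draws)
    alpha = 1.0 - level
    lo, hi = np.quantile(prod, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def mediated_proportion(beta_indirect: float, beta_total: float, *,
                        beta_a: float, se_a: float, beta_b: float, se_b: float,
                        se_total: float, n_draws: int = PRODUCT_DRAWS_DEFAULT,
                        seed: int = 0, level: float = 0.95,
                        ) -> tuple[float, tuple[float, float]]:
    """Share of the total effect transmitted through the mediator.

    The point value is the signed ratio β_indirect/β_total; its interval
    divides each Monte-Carlo product draw by an independent draw of the
    total effect (N(β_total, se_total²)).
    """
    if beta_total == 0.0:
        raise UndefinedProportionError("mediated proportion undefined: total effect is 0")
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10,000")
    proportion = beta_indirect / beta_total
    rng = np.random.default_rng(seed)
    prod = rng.normal(beta_a, se_a, n_draws) * rng.normal(beta_b, se_b, n_draws)
    total = rng.normal(beta_total, se_total, n_draws)
    ratio = prod / total
    alpha = 1.0 - level
    lo, hi = np.quantile(ratio, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(proportion), (float(lo), float(hi))


def assemble_mediation(exposure_id: str, mediator_id: str, outcome_id: str, *,
                       beta_total: float, se_total: float,
                       beta_a: float, se_a: float, beta_b: float, se_b: float,
                       n_draws: int = PRODUCT_DRAWS_DEFAULT, seed: int = 0,
                       alpha: float = 0.05) -> MediationResult:
    """Combine three leg estimates into a full mediation decomposition."""
    ab, ab_se, ab_p = indirect_effect(beta_a, se_a, beta_b, se_b)
    ci = product_ci(beta_a, se_a, beta_b, se_b, n_draws=n_draws, seed=seed)
    prop, prop_ci = mediated_proportion(
        ab, beta_total, beta_a=beta_a, se_a=se_a, beta_b=beta_b, se_b=se_b,
        se_total=se_total, n_draws=n_draws, seed=seed)
    return MediationResult(
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        beta_total=beta_total, se_total=se_total,
        beta_a=beta_a, se_a=se_a, beta_b=beta_b, se_b=se_b,
        beta_indirect=ab, indirect_se=ab_se, indirect_ci=ci, indirect_pval=ab_p,
        beta_direct=beta_total - ab,
        proportion=prop, proportion_ci=prop_ci,
        significant=bool(ab_p < alpha and 0.0 < prop < 1.0))


def run_mediation(exposure, mediator, outcome, config=None,
                  panel=None) -> MediationResult:
    """Estimate all three MR legs from raw datasets and decompose.

    Legs: β_total (exposure→outcome), β_A (exposure→mediator) and β_B
    (mediator→outcome, univariable, with the mediator's own instruments).
    Each leg runs the full selection → clumping → F-filter → harmonization
    → IVW/Wald funnel under ``config`` (a ScreenConfig; defaults apply when
    omitted). A leg with no surviving instruments raises
    :class:`LegFailureError` naming the leg.
    """
    from .pipeline import ScreenConfig, single_trait_mr  # deferred: avoids cycle

    config = config or ScreenConfig()
    legs = {}
    for name, (exp_ds, out_ds) in {
            "total": (exposure, outcome),
            "a": (exposure, mediator),
            "b": (mediator, outcome)}.items():
        try:
            est, _ = single_trait_mr(exp_ds, out_ds, config, panel=panel)
        except NoInstrumentsError as err:
            raise LegFailureError(name, f"leg {name!r}: {err}") from err
        legs[name] = est
    return assemble_mediation(
        exposure.trait_id, mediator.trait_id, outcome.trait_id,
        beta_total=legs["total"].beta, se_total=legs["total"].se,
        beta_a=legs["a"].beta, se_a=legs["a"].se,
        beta_b=legs["b"].beta, se_b=legs["b"].se,
        n_draws=config.mediation_draws, seed=config.seed,
        alpha=config.mr_significance)
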