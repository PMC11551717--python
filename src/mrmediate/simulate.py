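"""Synthetic exposure/mediator/outcome GWAS triples with known causal structure.

The generator emulates the summary statistics an analyst would download for
a two-step Mendelian randomization study of gut microbiota (exposure),
a plasma metabolite (mediator) and a binary disease outcome:

* Each trait has its own block of instrument SNPs. Exposure-block SNPs
  carry a true exposure effect ``gamma_j ~ Normal(0, instrument_strength_sd^2)``,
  propagate ``effect_a * gamma_j`` to the mediator and
  ``(direct_effect + effect_a * effect_b) * gamma_j`` plus horizontal
  pleiotropy ``alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd^2)`` to the
  outcome (balanced when the mean is zero, directional otherwise; the
  pleiotropic shift is defined relative to the exposure-increasing allele,
  the orientation in which MR-Egger measures it). Mediator-block SNPs affect the mediator directly and reach
  the outcome only through it (``effect_b`` per mediator SD); outcome-block
  SNPs affect the outcome directly and feed back on the exposure with
  ``reverse_effect`` (zero by default), giving the reverse-direction screen
  ground truth.
* Reported effects are the true values plus ``Normal(0, se^2)`` estimation
  noise with the standardized-trait approximation
  ``se = 1 / sqrt(2 * n * eaf * (1 - eaf))``, ``eaf ~ Uniform(0.05, 0.95)``;
  p-values come from the two-sided normal test. Binary-outcome effects are
  treated on the log-odds scale under the same Gaussian approximation.
* SNPs are simulated without LD (independent); allele pairs are
  non-palindromic by construction so that allele chaos below is the only
  source of strand ambiguity.

Everything is deterministic given ``SimulationTruth.seed``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CANONICAL_COLUMNS, GwasDataset

#: Ordered non-palindromic allele pairs (effect, other).
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_MIN_P = 5e-324  # smallest subnormal double; keeps p-values inside (0, 1]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of one simulated exposure→mediator→outcome study.

    ``causal_effect_total`` is derived as ``direct_effect + effect_a * effect_b``
    when not given; when given it must satisfy that identity exactly.
    Sample sizes default to the cohort sizes typical of consortium microbiome,
    plasma-metabolite and disease GWAS (18,340 / 8,299 / 456,348).
    Per-block instrument strengths default to a weak-ish microbiome signal
    (sd 0.10 SD per allele), a strong metabolite signal (sd 0.30) and a
    modest disease signal (sd 0.05 log-odds).
    """

    n_snps: int = 30
    effect_a: float = 0.3
    effect_b: float = 0.4
    direct_effect: float = 0.2
    causal_effect_total: float | None = None
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    instrument_strength_sd: float = 0.10
    mediator_instrument_sd: float = 0.30
    outcome_instrument_sd: float = 0.05
    n_exposure: int = 18340
    n_mediator: int = 8299
    n_outcome: int = 456348
    n_mediator_snps: int | None = None
    n_outcome_snps: int = 0
    reverse_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n < 100:
                raise ValueError("sample sizes must be >= 100")
        expected = self.direct_effect + self.effect_a * self.effect_b
        if self.causal_effect_total is None:
            object.__setattr__(self, "causal_effect_total", expected)
        elif self.causal_effect_total != expected:
            raise ValueError(
                "bookkeeping identity violated: total must equal "
                "direct_effect + effect_a * effect_b")

    @property
    def n_mediator_block(self) -> int:
        return self.n_snps if self.n_mediator_snps is None else self.n_mediator_snps


@dataclass
class SimulatedStudy:
    """Three linked GWAS datasets plus the truth that generated them."""

    exposure: GwasDataset
    mediator: GwasDataset
    outcome: GwasDataset
    truth: SimulationTruth
    chaos_ledger: dict | None = None
    outlier_ledger: list | None = None


def summary_se(n: int | np.ndarray, eaf: np.ndarray) -> np.ndarray:
    """Standard error of a per-allele effect on a standardized trait."""
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _MIN_P, 1.0)


def _make_dataset(trait_id: str, trait_type: str, snp: np.ndarray, chrom: np.ndarray,
                  pos: np.ndarray, ea: np.ndarray, oa: np.ndarray, eaf: np.ndarray,
                  beta: np.ndarray, se: np.ndarray, n: int) -> GwasDataset:
    df = pd.DataFrame({
        "SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
        "EAF": eaf, "BETA": beta, "SE": se, "P": _two_sided_p(beta, se),
        "N": pd.array(np.full(len(snp), n), dtype="Int64"),
    }, columns=CANONICAL_COLUMNS)
    return GwasDataset(trait_id, trait_type, df)


def simulate_triangle(truth: SimulationTruth) -> SimulatedStudy:
    """Generate one linked exposure/mediator/outcome study.

    All three datasets share the same SNP universe (exposure + mediator +
    outcome instrument blocks) with identical alleles and allele
    frequencies, as for three GWAS drawn from the same population.
    """
    rng = np.random.default_rng(truth.seed)
    n_e, n_m, n_o = truth.n_snps, truth.n_mediator_block, truth.n_outcome_snps
    m = n_e + n_m + n_o

    eaf = rng.uniform(0.05, 0.95, m)
    gamma = rng.normal(0.0, truth.instrument_strength_sd, n_e)
    delta = rng.normal(0.0, truth.mediator_instrument_sd, n_m)
    eps = rng.normal(0.0, truth.outcome_instrument_sd, n_o)
    alpha = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, n_e)

    # Pleiotropy is attached to the exposure-increasing allele: a directional
    # mean biases the outcome consistently in the orientation MR analyses use,
    # which is what makes it detectable by the Egger intercept.
    alpha_oriented = np.where(gamma < 0, -1.0, 1.0) * alpha
    true_exp = np.concatenate([gamma, np.zeros(n_m), truth.reverse_effect * eps])
    true_med = np.concatenate([truth.effect_a * gamma, delta, np.zeros(n_o)])
    true_out = np.concatenate([truth.causal_effect_total * gamma + alpha_oriented,
                               truth.effect_b * delta, eps])

    idx = np.arange(m)
    snp = np.array([f"rs{j + 1:06d}" for j in idx])
    chrom = ((idx % 22) + 1).astype(str)
    pos = (idx // 22 + 1) * 1_000_000
    pair = rng.integers(0, len(_NONPALINDROMIC_PAIRS), m)
    ea = np.array([_NONPALINDROMIC_PAIRS[k][0] for k in pair])
    oa = np.array([_NONPALINDROMIC_PAIRS[k][1] for k in pair])

    datasets = {}
    for trait_id, trait_type, true_beta, n in (
            ("exposure", "quantitative", true_exp, truth.n_exposure),
            ("mediator", "quantitative", true_med, truth.n_mediator),
            ("outcome", "binary", true_out, truth.n_outcome)):
        se = summary_se(n, eaf)
        beta = true_beta + rng.normal(0.0, se)
        datasets[trait_id] = _make_dataset(trait_id, trait_type, snp, chrom, pos,
                                           ea, oa, eaf, beta, se, n)
    return SimulatedStudy(datasets["exposure"], datasets["mediator"],
                          datasets["outcome"], truth)


def _clone(dataset: GwasDataset) -> pd.DataFrame:
    return dataset.table.copy(deep=True)


def inject_allele_chaos(study: SimulatedStudy, fraction_swapped: float = 0.0,
                        fraction_strand_flipped: float = 0.0,
                        fraction_palindromic: float = 0.0,
                        seed: int = 0) -> SimulatedStudy:
    """Perturb allele representations to exercise harmonization.

    Three disjoint SNP subsets are modified:

    * *swapped*: in the outcome dataset the effect/other alleles are
      exchanged, the beta sign flipped and the EAF complemented — a pure
      representation change;
    * *strand flipped*: the outcome alleles are replaced by their reverse
      strand complements;
    * *palindromic*: the SNP is re-coded as an A/T or C/G pair in all three
      datasets (same orientation, same EAF), so it can only be oriented by
      allele frequency downstream.

    The modification ledger is kept on the returned study for test assertions.
    """
    fracs = (fraction_swapped, fraction_strand_flipped, fraction_palindromic)
    if any(f < 0 or f > 1 for f in fracs):
        raise ValueError("fractions must lie in [0, 1]")
    if sum(fracs) > 1:
        raise ValueError("fractions overlap: their sum exceeds 1")

    rng = np.random.default_rng(seed)
    m = len(study.outcome.table)
    order = rng.permutation(m)
    n_sw = int(round(fraction_swapped * m))
    n_fl = int(round(fraction_strand_flipped * m))
    n_pal = int(round(fraction_palindromic * m))
    i_sw, i_fl, i_pal = (order[:n_sw], order[n_sw:n_sw + n_fl],
                         order[n_sw + n_fl:n_sw + n_fl + n_pal])

    out = _clone(study.outcome)
    exp = _clone(study.exposure)
    med = _clone(study.mediator)

    out.loc[i_sw, ["EA", "OA"]] = out.loc[i_sw, ["OA", "EA"]].to_numpy()
    out.loc[i_sw, "BETA"] = -out.loc[i_sw, "BETA"]
    out.loc[i_sw, "EAF"] = 1.0 - out.loc[i_sw, "EAF"]

    out.loc[i_fl, "EA"] = out.loc[i_fl, "EA"].map(_COMPLEMENT)
    out.loc[i_fl, "OA"] = out.loc[i_fl, "OA"].map(_COMPLEMENT)

    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), n_pal)
    pal_ea = np.array([_PALINDROMIC_PAIRS[k][0] for k in pal_choice])
    pal_oa = np.array([_PALINDROMIC_PAIRS[k][1] for k in pal_choice])
    for df in (exp, med, out):
        df.loc[i_pal, "EA"] = pal_ea
        df.loc[i_pal, "OA"] = pal_oa

    ledger = {
        "swapped": sorted(study.outcome.table["SNP"].iloc[i_sw]),
        "strand_flipped": sorted(study.outcome.table["SNP"].iloc[i_fl]),
        "palindromic": sorted(study.outcome.table["SNP"].iloc[i_pal]),
    }
    return SimulatedStudy(
        GwasDataset(study.exposure.trait_id, study.exposure.trait_type, exp),
        GwasDataset(study.mediator.trait_id, study.mediator.trait_type, med),
        GwasDataset(study.outcome.trait_id, study.outcome.trait_type, out),
        study.truth, chaos_ledger=ledger, outlier_ledger=study.outlier_ledger)


def inject_outliers(study: SimulatedStudy, n_outliers: int, offset: float,
                    seed: int = 0) -> SimulatedStudy:
    """Add ``offset`` to the outcome beta of ``n_outliers`` random SNPs.

    Emulates gross horizontal pleiotropy at a few variants; the ledger of
    perturbed SNP ids is retained for outlier-test power checks.
    """
    m = len(study.outcome.table)
    if n_outliers >= m:
        raise ValueError("n_outliers must be smaller than the number of SNPs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(m, size=n_outliers, replace=False)
    out = _clone(study.outcome)
    out.loc[idx, "BETA"] = out.loc[idx, "BETA"] + offset
    ledger = sorted(study.outcome.table["SNP"].iloc[idx])
    return SimulatedStudy(study.exposure, study.mediator,
                          GwasDataset(study.outcome.trait_id, study.outcome.trait_type, out),
                          study.truth, chaos_ledger=study.chaos_ledger,
                          outlier_ledger=ledger)


def truth_to_dict(truth: SimulationTruth) -> dict:
    return dataclasses.asdict(truth)
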