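"""Orchestration of the full screening workflow.

Forward MR screens of many exposures against one outcome, reverse-direction
MR of the outcome against the forward hits, sensitivity gating, mediator
triage and product-method mediation — the two-step design in which
exposures (e.g. gut microbial taxa) act on a binary outcome partly through
quantitative mediators (e.g. plasma metabolites).

Gating rules (config switches, defaults mirroring common screening
practice): claims require IVW p below ``mr_significance`` with no
multiple-testing correction; exposures flagged pleiotropic (Egger
intercept or PRESSO global) are excluded from claims, mediators are
retained despite Egger-only pleiotropy to maximise discovery; targets with
a significant, sensitivity-clean reverse estimate are flagged
bidirectional and excluded from mediation.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, LegFailureError, NoInstrumentsError
from .harmonize import PALINDROMIC_WINDOW_DEFAULT, HarmonizedInstrumentSet, harmonize
from .instruments import (LdPanel, apply_exclusion_list, filter_dataset_by_f,
                          ld_clump, select_by_pvalue)
from .io import GwasDataset, read_gwas
from .estimators import MrEstimate, ivw
from .mediation import run_mediation
from .sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger(__name__)

MR_COLUMNS = ["exposure", "outcome", "method", "nsnp", "b", "se", "pval",
              "or", "or_lci95", "or_uci95"]
SENS_COLUMNS = ["q_stat", "q_df", "q_pval", "egger_intercept",
                "egger_intercept_pval", "presso_global_pval",
                "heterogeneous", "pleiotropic"]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and settings of one screening run."""

    iv_pval_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    f_cutoff: float = 10.0
    mr_significance: float = 0.05
    presso_nsim: int = 5000
    mediation_draws: int = 100_000
    seed: int = 0
    palindromic_window: tuple[float, float] = PALINDROMIC_WINDOW_DEFAULT
    ivw_mode: str = "multiplicative_random"
    exclude_snps: tuple[str, ...] = ()
    exclude_pleiotropic_exposures: bool = True
    exclude_pleiotropic_mediators: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.iv_pval_threshold <= 1):
            raise ConfigurationError("iv_pval_threshold must lie in (0, 1]")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigurationError("clump_r2 must lie in [0, 1]")
        if not (0 < self.mr_significance < 1):
            raise ConfigurationError("mr_significance must lie in (0, 1)")
        if self.f_cutoff < 0 or self.clump_kb <= 0:
            raise ConfigurationError("f_cutoff must be >= 0 and clump_kb > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "palindromic_window" in raw:
            raw["palindromic_window"] = tuple(raw["palindromic_window"])
        if "exclude_snps" in raw:
            raw["exclude_snps"] = tuple(raw["exclude_snps"])
        return cls(**raw)


def single_trait_mr(exposure: GwasDataset, outcome: GwasDataset,
                    config: ScreenConfig, panel: LdPanel | None = None,
                    ) -> tuple[MrEstimate, HarmonizedInstrumentSet]:
    """Run one exposure→outcome MR through the full selection funnel.

    select (p) → exclusion list → LD clump → F filter → harmonize → IVW
    (delegating to the Wald ratio for a single instrument). Raises
    :class:`NoInstrumentsError` when any stage empties the instrument set.
    """
    ds = select_by_pvalue(exposure, config.iv_pval_threshold)
    if config.exclude_snps:
        ds = apply_exclusion_list(ds, config.exclude_snps)
    ds = ld_clump(ds, panel, config.clump_r2, config.clump_kb)
    ds = filter_dataset_by_f(ds, config.f_cutoff)
    hset = harmonize(ds, outcome, config.palindromic_window)
    return ivw(hset, mode=config.ivw_mode), hset


def _screen_row(trait_id: str, outcome_id: str, est: MrEstimate | None,
                report: SensitivityReport | None, reason: str | None) -> dict:
    row = {"exposure": trait_id, "outcome": outcome_id, "status": "ok" if est else "excluded",
           "reason": reason or ""}
    if est is not None:
        row.update(method=est.method, nsnp=est.n_snp, b=est.beta, se=est.se,
                   pval=est.pval, **{"or": est.odds_ratio,
                                     "or_lci95": est.ci_low, "or_uci95": est.ci_high})
    if report is not None:
        row.update(q_stat=report.q_stat, q_df=report.q_df, q_pval=report.q_pval,
                   egger_intercept=report.egger_intercept,
                   egger_intercept_pval=report.egger_intercept_pval,
                   presso_global_pval=report.presso_global_pval,
                   heterogeneous=report.heterogeneous,
                   pleiotropic=report.pleiotropic)
    return row


def forward_screen(exposures: Sequence[GwasDataset], outcome: GwasDataset,
                   config: ScreenConfig, panel: LdPanel | None = None,
                   ) -> pd.DataFrame:
    """Screen every exposure against the outcome; one row per exposure.

    Per-exposure failures are recorded (status ``excluded`` with reason),
    never fatal. ``significant`` applies the IVW p < ``mr_significance``
    rule.
    """
    rows = []
    for exposure in exposures:
        try:
            est, hset = single_trait_mr(exposure, outcome, config, panel)
        except NoInstrumentsError as err:
            logger.info("%s excluded: %s", exposure.trait_id, err)
            rows.append(_screen_row(exposure.trait_id, outcome.trait_id,
                                    None, None, "no instruments"))
            continue
        report = sensitivity_report(hset, n_sim=config.presso_nsim,
                                    seed=config.seed, alpha=config.mr_significance)
        rows.append(_screen_row(exposure.trait_id, outcome.trait_id, est, report, None))
    out = pd.DataFrame(rows)
    out["significant"] = (out.get("pval") < config.mr_significance).fillna(False) \
        if "pval" in out.columns else False
    return out


def reverse_screen(outcome_as_exposure: GwasDataset,
                   targets: Sequence[GwasDataset], config: ScreenConfig,
                   panel: LdPanel | None = None) -> pd.DataFrame:
    """Reverse-direction MR: the outcome acting on each forward hit.

    The same machinery runs with roles swapped (instruments are the
    outcome's own variants at the usual p threshold). A target is flagged
    ``bidirectional`` when its reverse estimate is significant *and*
    passes reverse sensitivity (not pleiotropic); such targets are
    excluded from mediation by the caller.
    """
    rows = []
    for target in targets:
        try:
            est, hset = single_trait_mr(outcome_as_exposure, target, config, panel)
        except NoInstrumentsError as err:
            logger.info("reverse %s excluded: %s", target.trait_id, err)
            rows.append(_screen_row(outcome_as_exposure.trait_id, target.trait_id,
                                    None, None, "no instruments"))
            continue
        report = sensitivity_report(hset, n_sim=config.presso_nsim,
                                    seed=config.seed, alpha=config.mr_significance)
        rows.append(_screen_row(outcome_as_exposure.trait_id, target.trait_id,
                                est, report, None))
    out = pd.DataFrame(rows)
    if "pval" in out.columns:
        sig = (out["pval"] < config.mr_significance).fillna(False)
        clean = ~out.get("pleiotropic", pd.Series(False, index=out.index)).fillna(False)
        out["bidirectional"] = (sig & clean & (out["status"] == "ok"))
    else:
        out["bidirectional"] = False
    return out


def _load_manifest(manifest: Mapping | str | Path) -> dict:
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, Mapping):
        raise ConfigurationError("manifest must be a mapping or a YAML file of one")
    out = dict(manifest)
    for key in ("exposures", "mediators"):
        entries = out.get(key) or {}
        if isinstance(entries, Sequence) and not isinstance(entries, Mapping):
            entries = {Path(p).stem: p for p in entries}
        out[key] = dict(entries)
    if "outcome" not in out:
        raise ConfigurationError("manifest must name an outcome file")
    missing = [str(p) for p in
               [*out["exposures"].values(), *out["mediators"].values(), out["outcome"]]
               if not Path(p).is_file()]
    if missing:
        raise ConfigurationError(f"manifest files not found: {missing}")
    return out


def full_run(config: ScreenConfig, manifest: Mapping | str | Path,
             out_dir: str | Path, panel: LdPanel | None = None) -> dict:
    """Execute the complete two-step workflow and write the report bundle.

    Steps: forward screen of exposures on the outcome; reverse screen of
    the outcome on the forward hits (bidirectional flagging); mediator
    screen on the outcome; exposure→mediator MR restricted to surviving
    pairs; mediation on triples whose three legs are all significant and
    whose exposure carries no gating flag. Writes ``forward_mr.tsv``,
    ``reverse_mr.tsv``, ``mediator_mr.tsv``, ``exposure_mediator_mr.tsv``,
    ``mediation.tsv``, ``audit_log.tsv`` and ``run_meta.json``; identical
    config + manifest + seed give a byte-identical bundle.
    """
    manifest = _load_manifest(manifest)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exposures = [read_gwas(p, trait_id=tid)
                 for tid, p in manifest["exposures"].items()]
    mediators = [read_gwas(p, trait_id=tid)
                 for tid, p in manifest["mediators"].items()]
    outcome = read_gwas(manifest["outcome"], trait_id=Path(manifest["outcome"]).stem,
                        trait_type="binary")

    audit: list[dict] = []

    forward = forward_screen(exposures, outcome, config, panel)
    sig_forward = forward[forward["significant"]]
    if config.exclude_pleiotropic_exposures and "pleiotropic" in forward.columns:
        gated = sig_forward[sig_forward["pleiotropic"].fillna(False)]["exposure"]
        for tid in gated:
            audit.append({"trait": tid, "role": "exposure", "kept": False,
                          "reason": "pleiotropy"})
        sig_forward = sig_forward[~sig_forward["pleiotropic"].fillna(False)]
    kept_exposures = [e for e in exposures if e.trait_id in set(sig_forward["exposure"])]

    reverse = reverse_screen(outcome, kept_exposures, config, panel) \
        if kept_exposures else pd.DataFrame(columns=["outcome", "bidirectional"])
    bidirectional = set(reverse[reverse["bidirectional"]]["outcome"]) \
        if len(reverse) else set()

    mediator_screen = forward_screen(mediators, outcome, config, panel) \
        if mediators else pd.DataFrame(columns=["exposure", "significant", "pleiotropic"])
    sig_med = mediator_screen[mediator_screen.get("significant", pd.Series(dtype=bool))] \
        if len(mediator_screen) else mediator_screen
    if config.exclude_pleiotropic_mediators and "pleiotropic" in sig_med.columns:
        sig_med = sig_med[~sig_med["pleiotropic"].fillna(False)]
    kept_mediators = [m for m in mediators
                      if len(sig_med) and m.trait_id in set(sig_med["exposure"])]

    for e in exposures:
        status = forward.loc[forward["exposure"] == e.trait_id].iloc[0]
        if e.trait_id in bidirectional:
            audit.append({"trait": e.trait_id, "role": "exposure", "kept": False,
                          "reason": "bidirectional"})
        elif any(a["trait"] == e.trait_id for a in audit):
            pass
        else:
            kept = e.trait_id in {k.trait_id for k in kept_exposures}
            audit.append({"trait": e.trait_id, "role": "exposure", "kept": kept,
                          "reason": "" if kept else
                          (status["reason"] or "not significant")})
    for m in mediators:
        kept = m.trait_id in {k.trait_id for k in kept_mediators}
        row = mediator_screen.loc[mediator_screen["exposure"] == m.trait_id].iloc[0]
        audit.append({"trait": m.trait_id, "role": "mediator", "kept": kept,
                      "reason": "" if kept else (row["reason"] or "not significant")})
    audit.append({"trait": outcome.trait_id, "role": "outcome", "kept": True,
                  "reason": ""})

    # Exposure→mediator legs and mediation on fully significant triples.
    em_rows, mediation_rows = [], []
    mediation_exposures = [e for e in kept_exposures
                           if e.trait_id not in bidirectional]
    for e in mediation_exposures:
        for m in kept_mediators:
            try:
                est, _ = single_trait_mr(e, m, config, panel)
            except NoInstrumentsError:
                em_rows.append(_screen_row(e.trait_id, m.trait_id, None, None,
                                           "no instruments"))
                continue
            em_rows.append(_screen_row(e.trait_id, m.trait_id, est, None, None))
            if est.pval >= config.mr_significance:
                continue
            try:
                res = run_mediation(e, m, outcome, config, panel)
            except LegFailureError as err:
                logger.info("mediation %s via %s skipped: %s",
                            e.trait_id, m.trait_id, err)
                continue
            mediation_rows.append({
                "exposure": res.exposure_id, "mediator": res.mediator_id,
                "outcome": res.outcome_id, "beta_total": res.beta_total,
                "se_total": res.se_total, "beta_a": res.beta_a, "se_a": res.se_a,
                "beta_b": res.beta_b, "se_b": res.se_b,
                "beta_indirect": res.beta_indirect, "indirect_se": res.indirect_se,
                "indirect_lci95": res.indirect_ci[0],
                "indirect_uci95": res.indirect_ci[1],
                "indirect_pval": res.indirect_pval, "beta_direct": res.beta_direct,
                "proportion": res.proportion,
                "proportion_lci95": res.proportion_ci[0],
                "proportion_uci95": res.proportion_ci[1],
                "significant": res.significant,
            })

    bundle = {
        "forward_mr": forward,
        "reverse_mr": reverse,
        "mediator_mr": mediator_screen,
        "exposure_mediator_mr": pd.DataFrame(em_rows),
        "mediation": pd.DataFrame(mediation_rows),
        "audit_log": pd.DataFrame(audit),
    }
    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    meta = {"config": dataclasses.asdict(config), "manifest": {
        "exposures": {k: str(v) for k, v in manifest["exposures"].items()},
        "mediators": {k: str(v) for k, v in manifest["mediators"].items()},
        "outcome": str(manifest["outcome"])},
        "package_version": __version__}
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return bundle
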