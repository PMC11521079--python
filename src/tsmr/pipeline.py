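"""One-call orchestration of the full two-sample MR workflow.

``run_analysis`` goes read → harmonize/screen → estimate (IVW, weighted
median, MR-Egger) → diagnostics (Cochran Q, Egger intercept, MR-PRESSO,
leave-one-out, single-SNP and funnel tables) → instrument strength / power →
report, logging each stage and recording every seed and threshold in the
output so a run is reproducible from its report alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from . import __version__
from .datamodel import SummaryStatsTable
from .diagnostics import (
    cochran_q,
    egger_intercept_test,
    funnel_table,
    leave_one_out,
    mr_presso,
    single_snp_table,
)
from .errors import AnalysisError
from .estimators import egger, ivw, weighted_median
from .harmonize import HarmonizationConfig, harmonize
from .io import read_deny_list, read_summary_stats
from .report import write_report
from .simulate import SyntheticTruth
from .strength import PowerInput, power_binary, strength_summary

__all__ = ["RunConfig", "run_analysis", "analyze_tables"]

log = logging.getLogger("tsmr")


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on, seeds included."""

    exposure_path: Union[str, Path, None] = None
    outcome_path: Union[str, Path, None] = None
    exposure_label: Optional[str] = None
    outcome_label: Optional[str] = None
    exposure_columns: Optional[Mapping[str, str]] = None
    outcome_columns: Optional[Mapping[str, str]] = None
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    deny_list_path: Union[str, Path, None] = None
    ivw_mode: str = "multiplicative_random_effects"
    n_boot: int = 1000
    n_sim: int = 2000
    presso_significance: float = 0.05
    seed: int = 0
    out_dir: Union[str, Path, None] = None
    exposure_n: Optional[int] = None
    r2: Optional[float] = None
    power: Optional[PowerInput] = None


def _child_seeds(root: int, n: int = 2) -> list[int]:
    """Independent sub-seeds derived from one root seed."""
    state = np.random.SeedSequence(root).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def analyze_tables(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    cfg: RunConfig = RunConfig(),
    truth: Optional[SyntheticTruth] = None,
) -> dict:
    """Run the post-read part of the pipeline on in-memory tables.

    Returns the machine-readable report as a dict; writes the report bundle
    when ``cfg.out_dir`` is set. ``truth`` (from :mod:`tsmr.simulate`)
    attaches a truth-vs-estimate comparison block.
    """
    wm_seed, presso_seed = _child_seeds(cfg.seed)
    log.info("harmonizing %s (%d SNPs) with %s (%d SNPs)",
             exposure.trait_label, len(exposure), outcome.trait_label, len(outcome))
    try:
        ds = harmonize(exposure, outcome, cfg.harmonization)
    except AnalysisError as exc:
        raise AnalysisError(f"harmonization stage: {exc}") from exc
    log.info("harmonization kept %d instruments, excluded %d", len(ds), len(ds.exclusions))
    for rsid, reason in ds.exclusions:
        log.debug("excluded %s: %s", rsid, reason)
    if len(ds) == 0:
        raise AnalysisError(
            "harmonization stage: no instruments survived screening "
            f"({len(ds.exclusions)} excluded)"
        )

    try:
        est_ivw = ivw(ds, mode=cfg.ivw_mode)
        est_wm = weighted_median(ds, n_boot=cfg.n_boot, seed=wm_seed)
        fit, est_egger = egger(ds, mode=cfg.ivw_mode)
    except AnalysisError as exc:
        raise AnalysisError(f"estimation stage: {exc}") from exc
    log.info("IVW OR %.3f, weighted-median OR %.3f, MR-Egger OR %.3f",
             est_ivw.or_, est_wm.or_, est_egger.or_)

    try:
        het_ivw = cochran_q(ds, "ivw")
        het_egger = cochran_q(ds, "egger")
        pleio = egger_intercept_test(fit)
        presso = mr_presso(
            ds, n_sim=cfg.n_sim, significance=cfg.presso_significance, seed=presso_seed
        )
        loo = leave_one_out(ds, mode=cfg.ivw_mode)
        snp_tab = single_snp_table(ds)
        fun_tab = funnel_table(ds)
    except AnalysisError as exc:
        raise AnalysisError(f"diagnostics stage: {exc}") from exc
    log.info("Cochran Q %.2f (p=%.3f); Egger intercept %.4f (p=%.3f); PRESSO global p %.3f",
             het_ivw.Q, het_ivw.p, pleio.intercept, pleio.p, presso.global_p)

    report: dict = {
        "tool": {"name": "tsmr", "version": __version__},
        "config": {
            "exposure": exposure.trait_label,
            "outcome": outcome.trait_label,
            "ivw_mode": cfg.ivw_mode,
            "n_boot": cfg.n_boot,
            "n_sim": cfg.n_sim,
            "presso_significance": cfg.presso_significance,
            "seed": cfg.seed,
            "weighted_median_seed": wm_seed,
            "presso_seed": presso_seed,
            "palindrome_policy": cfg.harmonization.palindrome_policy,
            "ambiguous_eaf_window": list(cfg.harmonization.ambiguous_eaf_window),
            "pval_threshold": cfg.harmonization.pval_threshold,
            "deny_list": sorted(cfg.harmonization.deny_list),
            "egger_orientation": "exposure effects oriented non-negative",
        },
        "n_instruments": len(ds),
        "instruments": ds.rsids,
        "exclusions": [list(e) for e in ds.exclusions],
        "estimates": [e.to_dict() for e in (est_ivw, est_wm, est_egger)],
        "egger_fit": fit.to_dict(),
        "heterogeneity": [het_ivw.to_dict(), het_egger.to_dict()],
        "pleiotropy": pleio.to_dict(),
        "mr_presso": presso.to_dict(),
        "leave_one_out": loo.to_dict(orient="records"),
        "single_snp": snp_tab.to_dict(orient="records"),
        "funnel": fun_tab.to_dict(orient="records"),
    }

    if cfg.exposure_n is not None:
        strength = strength_summary(ds, N=cfg.exposure_n, r2=cfg.r2)
        report["strength"] = strength.to_dict()
    if cfg.power is not None:
        report["power"] = {
            "inputs": cfg.power.to_dict(),
            "power": power_binary(cfg.power),
        }
    if truth is not None:
        report["truth_comparison"] = {
            "true_theta": truth.config.theta,
            "invalid_rsids": list(truth.invalid_rsids),
            "oriented_mean_alpha": truth.oriented_mean_alpha,
            "ivw_error": est_ivw.beta - truth.config.theta,
            "weighted_median_error": est_wm.beta - truth.config.theta,
            "egger_error": est_egger.beta - truth.config.theta,
            "egger_intercept_minus_mean_alpha": fit.intercept - truth.oriented_mean_alpha,
        }

    if cfg.out_dir is not None:
        paths = write_report(report, cfg.out_dir)
        loo.to_csv(Path(cfg.out_dir) / "leave_one_out.tsv", sep="\t", index=False)
        snp_tab.to_csv(Path(cfg.out_dir) / "single_snp.tsv", sep="\t", index=False)
        fun_tab.to_csv(Path(cfg.out_dir) / "funnel.tsv", sep="\t", index=False)
        log.info("report written to %s", paths["json"])
    return report


def run_analysis(cfg: RunConfig) -> dict:
    """Read the configured inputs and run the full workflow."""
    if cfg.exposure_path is None or cfg.outcome_path is None:
        raise AnalysisError("run_analysis needs exposure_path and outcome_path")
    exposure = read_summary_stats(
        cfg.exposure_path, cfg.exposure_columns, trait_label=cfg.exposure_label
    )
    outcome = read_summary_stats(
        cfg.outcome_path, cfg.outcome_columns, trait_label=cfg.outcome_label
    )
    harmo = cfg.harmonization
    if cfg.deny_list_path is not None:
        extra = read_deny_list(cfg.deny_list_path)
        from dataclasses import replace

        harmo = replace(harmo, deny_list=frozenset(harmo.deny_list) | extra)
        cfg = replace(cfg, harmonization=harmo)
    return analyze_tables(exposure, outcome, cfg)
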