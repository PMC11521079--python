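"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Covers the sensitivity battery of a two-sample MR analysis: Cochran Q for
the IVW model and Rucker Q' for the Egger model, the Egger intercept test
for directional pleiotropy, the MR-PRESSO resampling framework (global
heterogeneity test, per-SNP outlier test, distortion test), leave-one-out
influence, and plot-ready single-SNP / funnel tables. No figures are
rendered; every diagnostic is emitted as a table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import HarmonizedDataset
from .errors import AnalysisError, ConfigurationError
from .estimators import EggerFit, _ivw_core, egger, ivw

__all__ = [
    "HeterogeneityResult",
    "PleiotropyResult",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "funnel_table",
    "single_snp_table",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran-type heterogeneity statistic with its chi-square p-value."""

    method: str  # "ivw" or "egger"
    Q: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"method": self.method, "Q": self.Q, "df": self.df, "p": self.p}


@dataclass(frozen=True)
class PleiotropyResult:
    """Egger-intercept test for directional pleiotropy."""

    intercept: float
    se: float
    p: float
    df: int
    suspected: bool  # p < 0.05

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "se": self.se,
            "p": self.p,
            "df": self.df,
            "pleiotropy_suspected": self.suspected,
        }


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_observed: float
    global_p: float
    n_sim: int
    outlier_pvalues: dict[str, float] = field(default_factory=dict)
    outliers: tuple[str, ...] = ()
    distortion_p: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "rss_observed": self.rss_observed,
            "global_p": self.global_p,
            "n_sim": self.n_sim,
            "outlier_pvalues": dict(self.outlier_pvalues),
            "outliers": list(self.outliers),
            "distortion_p": self.distortion_p,
        }


def cochran_q(ds: HarmonizedDataset, method: str = "ivw") -> HeterogeneityResult:
    """Heterogeneity of the per-SNP ratios under the IVW or Egger model.

    For ``"ivw"``: Q = sum_j w_j (ratio_j - beta_IVW)^2 with first-order
    weights w_j = (sigma_Gj/|gamma_j|)^-2 about the *fixed-effect* IVW
    estimate, referred to chi-square with L-1 df. For ``"egger"``: the
    weighted residual sum of squares of the oriented intercept model
    (Rucker's Q'), with L-2 df.
    """
    L = len(ds)
    if method == "ivw":
        if L < 2:
            raise AnalysisError("Cochran Q requires at least 2 instruments")
        g, _, G, sG = ds.arrays()
        beta, _ = _ivw_core(g, sG, G)
        q = float(np.sum(sG**-2.0 * (G - beta * g) ** 2))
        df = L - 1
    elif method == "egger":
        if L < 3:
            raise AnalysisError("Egger Q' requires at least 3 instruments")
        fit, _ = egger(ds, mode="fixed")
        q = fit.phi**2 * fit.df
        df = fit.df
    else:
        raise ConfigurationError(f"unknown heterogeneity method {method!r}")
    return HeterogeneityResult(
        method=method, Q=q, df=df, p=float(stats.chi2.sf(q, df))
    )


def egger_intercept_test(fit: EggerFit) -> PleiotropyResult:
    """Repackage the Egger intercept as a directional-pleiotropy test."""
    return PleiotropyResult(
        intercept=fit.intercept,
        se=fit.intercept_se,
        p=fit.intercept_p,
        df=fit.df,
        suspected=fit.intercept_p < 0.05,
    )


def _loo_betas(g: np.ndarray, sG: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW estimates omitting each SNP in turn, via sum updates.

    Works on stacked replicates: inputs of shape (..., L) give outputs of the
    same shape.
    """
    w = sG**-2.0
    num = np.sum(w * g * G, axis=-1, keepdims=True)
    den = np.sum(w * g * g, axis=-1, keepdims=True)
    return (num - w * g * G) / (den - w * g * g)


def mr_presso(
    ds: HarmonizedDataset,
    n_sim: int = 2000,
    significance: float = 0.05,
    seed: Optional[int] = None,
) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares pleiotropy test with outlier search.

    The observed statistic is RSS = sum_j w_j r_j^2 with w_j = sigma_Gj^-2
    and leave-one-out residuals r_j = Gamma_j - beta_(-j) gamma_j, where
    beta_(-j) is the fixed-effect IVW estimate without SNP j. The null
    distribution comes from ``n_sim`` parametric replicates drawing
    Gamma*_j ~ N(beta_(-j) gamma_j, sigma_Gj) and gamma*_j ~ N(gamma_j,
    sigma_gj) and recomputing RSS identically. All p-values use the add-one
    estimator, so the global p is never below 1/(n_sim+1). Per-SNP outlier
    p-values are Bonferroni-adjusted across instruments; when outliers are
    found, the distortion test compares the full-data IVW against the
    outlier-free IVW, referenced to random same-size removals.
    """
    L = len(ds)
    if L < 4:
        raise AnalysisError(f"MR-PRESSO requires at least 4 instruments, got {L}")
    if 1.0 / (n_sim + 1) > significance:
        raise ConfigurationError(
            f"n_sim = {n_sim} cannot resolve significance {significance}: "
            f"minimum attainable p is {1.0 / (n_sim + 1):.4g}"
        )
    if seed is None:
        raise ConfigurationError("mr_presso requires an explicit seed")
    g, sg, G, sG = ds.arrays()
    w = sG**-2.0
    beta_loo = _loo_betas(g, sG, G)
    resid = G - beta_loo * g
    rss_obs = float(np.sum(w * resid**2))

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sg, size=(n_sim, L))
    G_star = rng.normal(beta_loo * g, sG, size=(n_sim, L))
    beta_loo_star = _loo_betas(g_star, sG, G_star)
    resid_star = G_star - beta_loo_star * g_star
    rss_star = np.sum(w * resid_star**2, axis=1)
    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    # per-SNP: compare each weighted squared residual against its own null
    per_snp = (1 + np.sum(w * resid_star**2 >= w * resid**2, axis=0)) / (n_sim + 1)
    adjusted = np.minimum(1.0, per_snp * L)
    rsids = ds.rsids
    outlier_pvalues = {rsid: float(p) for rsid, p in zip(rsids, adjusted)}
    outliers = tuple(r for r, p in outlier_pvalues.items() if p < significance)

    distortion_p: Optional[float] = None
    if outliers:
        beta_full = ivw(ds).beta
        beta_clean = ivw(ds.drop(outliers)).beta
        d_obs = abs(beta_full - beta_clean)
        k = len(outliers)
        d_null = np.empty(n_sim)
        idx = np.arange(L)
        for s in range(n_sim):
            drop = rng.choice(idx, size=k, replace=False)
            keep = np.setdiff1d(idx, drop, assume_unique=True)
            b_sub, _ = _ivw_core(g[keep], sG[keep], G[keep])
            d_null[s] = abs(beta_full - b_sub)
        distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))

    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        distortion_p=distortion_p,
    )


def leave_one_out(ds: HarmonizedDataset, mode: str = "multiplicative_random_effects") -> pd.DataFrame:
    """IVW re-estimated with each instrument omitted in turn.

    Returns one row per omitted rsid with columns ``rsid``, ``beta``, ``se``,
    ``p``, ``or``; exactly L rows.
    """
    L = len(ds)
    if L < 3:
        raise AnalysisError(f"leave-one-out requires at least 3 instruments, got {L}")
    rows = []
    for inst in ds.instruments:
        est = ivw(ds.drop([inst.rsid]), mode=mode)
        rows.append(
            {
                "rsid": inst.rsid,
                "beta": est.beta,
                "se": est.se,
                "p": est.p,
                "or": est.or_,
            }
        )
    return pd.DataFrame(rows, columns=["rsid", "beta", "se", "p", "or"])


def single_snp_table(ds: HarmonizedDataset) -> pd.DataFrame:
    """Per-SNP Wald ratios with SEs — the forest/scatter plot data."""
    if len(ds) < 1:
        raise AnalysisError("single-SNP table requires at least 1 instrument")
    g, _, G, sG = ds.arrays()
    if np.any(g == 0):
        raise AnalysisError("ratio undefined with a zero exposure effect")
    ratio = G / g
    se = sG / np.abs(g)
    return pd.DataFrame(
        {
            "rsid": ds.rsids,
            "ratio": ratio,
            "se": se,
            "or": np.exp(ratio),
        }
    )


def funnel_table(ds: HarmonizedDataset) -> pd.DataFrame:
    """Per-SNP (ratio, precision) pairs — the funnel plot data.

    Precision is the reciprocal ratio SE, |gamma_j| / sigma_Gj; a symmetric
    scatter of ratios about the combined estimate across precisions is the
    visual no-directional-pleiotropy check.
    """
    tab = single_snp_table(ds)
    return pd.DataFrame(
        {
            "rsid": tab["rsid"],
            "ratio": tab["ratio"],
            "precision": 1.0 / tab["se"],
        }
    )
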