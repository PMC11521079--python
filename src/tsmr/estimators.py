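"""Causal-effect estimators for two-sample summary-statistics MR.

Implements the Wald ratio, inverse-variance-weighted (IVW) combination,
MR-Egger regression, and the interpolated weighted median with a parametric
bootstrap standard error.

Model: for instrument j with SNP→exposure effect gamma_j (SE sigma_gj) and
SNP→outcome effect Gamma_j (SE sigma_Gj), a valid instrument satisfies
Gamma_j = theta * gamma_j, so theta is estimated from the per-SNP ratios
Gamma_j / gamma_j. IVW is the inverse-variance-weighted average of those
ratios (equivalently, zero-intercept weighted least squares of Gamma on
gamma with weights sigma_Gj^-2); MR-Egger adds a free intercept that absorbs
directional pleiotropy; the weighted median is consistent whenever
instruments carrying at least half of the total weight are valid.

Conventions (shared by the published analysis this package reproduces):

* IVW default mode is multiplicative random effects: the fixed-effect SE is
  inflated by phi = sqrt(Q / (L - 1)) when phi > 1 and never deflated.
* IVW and weighted-median p-values are standard normal; MR-Egger uses the
  t distribution with L - 2 df and its 95% CIs use the matching t quantile.
* MR-Egger is fit after orienting every instrument so gamma_j >= 0 (negating
  both betas where needed); the intercept's sign is only interpretable under
  a declared orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .datamodel import HarmonizedDataset, HarmonizedInstrument
from .errors import AnalysisError, ConfigurationError

__all__ = [
    "MrEstimate",
    "EggerFit",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_median_point",
]

Z975 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate on the log-odds-per-SD scale.

    ``or_``, ``or_low`` and ``or_high`` are the exponentiated point estimate
    and 95% CI, the scale on which binary-outcome MR results are reported.
    """

    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "or": self.or_,
            "or_low": self.or_low,
            "or_high": self.or_high,
        }


@dataclass(frozen=True)
class EggerFit:
    """MR-Egger regression fit: slope (causal), intercept (pleiotropy), scale."""

    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_p: float
    df: int
    phi: float  # sqrt(mean weighted squared residual), before the >=1 floor

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_p": self.slope_p,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
            "df": self.df,
            "phi": self.phi,
        }


def _normal_estimate(method: str, n: int, beta: float, se: float) -> MrEstimate:
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return MrEstimate(
        method=method,
        n_snps=n,
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        p=max(float(p), 5e-324),
    )


def wald_ratio(inst: HarmonizedInstrument) -> MrEstimate:
    """Single-instrument ratio estimate Gamma/gamma, first-order delta SE."""
    if inst.beta_exp == 0:
        raise AnalysisError(f"{inst.rsid}: Wald ratio undefined for beta_exp = 0")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return _normal_estimate("wald_ratio", 1, beta, se)


def _ivw_core(g: np.ndarray, sG: np.ndarray, G: np.ndarray) -> tuple[float, float]:
    """Fixed-effect IVW slope and SE (zero-intercept WLS, weights sG^-2)."""
    w = sG**-2.0
    den = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / den
    return beta, den**-0.5


def cochran_q_statistic(g: np.ndarray, sG: np.ndarray, G: np.ndarray) -> float:
    """Cochran Q of the Wald ratios about the fixed-effect IVW estimate.

    Weights are the first-order ratio weights (sigma_Gj / |gamma_j|)^-2;
    algebraically identical to the weighted residual sum of squares of the
    zero-intercept regression.
    """
    beta, _ = _ivw_core(g, sG, G)
    w = sG**-2.0
    return float(np.sum(w * (G - beta * g) ** 2))


def ivw(ds: HarmonizedDataset, mode: str = "multiplicative_random_effects") -> MrEstimate:
    """Inverse-variance-weighted estimate over all instruments.

    Parameters
    ----------
    ds
        Harmonized dataset with L >= 2 instruments.
    mode
        ``"fixed"`` for the fixed-effect SE, or
        ``"multiplicative_random_effects"`` (default) which inflates it by
        max(1, sqrt(Q / (L - 1))).
    """
    if mode not in ("fixed", "multiplicative_random_effects"):
        raise ConfigurationError(f"unknown IVW mode {mode!r}")
    L = len(ds)
    # fixed mode degenerates gracefully to the Wald ratio at L = 1; the
    # random-effects dispersion Q/(L-1) needs at least 2 instruments.
    if L < 1 or (L < 2 and mode == "multiplicative_random_effects"):
        raise AnalysisError(f"IVW requires at least 2 instruments, got {L}")
    g, _, G, sG = ds.arrays()
    if np.any(g == 0):
        raise AnalysisError("IVW undefined with a zero exposure effect")
    beta, se_fixed = _ivw_core(g, sG, G)
    se = se_fixed
    if mode == "multiplicative_random_effects":
        phi2 = cochran_q_statistic(g, sG, G) / (L - 1)
        se = se_fixed * max(1.0, math.sqrt(phi2))
    name = "ivw_fixed" if mode == "fixed" else "ivw_mre"
    return _normal_estimate(name, L, beta, se)


def egger(
    ds: HarmonizedDataset, mode: str = "multiplicative_random_effects"
) -> tuple[EggerFit, MrEstimate]:
    """MR-Egger regression: weighted fit of Gamma on gamma with an intercept.

    All instruments are first oriented so gamma_j >= 0 (both betas negated
    where gamma_j < 0). Returns the full fit plus the causal estimate built
    from the slope, with t(L-2) p-values and CIs.
    """
    if mode not in ("fixed", "multiplicative_random_effects"):
        raise ConfigurationError(f"unknown Egger mode {mode!r}")
    L = len(ds)
    if L < 3:
        raise AnalysisError(f"MR-Egger requires at least 3 instruments, got {L}")
    g, _, G, sG = ds.arrays()
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    if np.allclose(g, g[0]):
        raise AnalysisError("MR-Egger is collinear: all oriented exposure effects equal")
    w = sG**-2.0
    X = np.column_stack([np.ones(L), g])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * G))
    resid = G - X @ coef
    q_prime = float(np.sum(w * resid**2))
    df = L - 2
    phi = math.sqrt(q_prime / df)
    scale = max(1.0, phi) if mode == "multiplicative_random_effects" else 1.0
    cov = np.linalg.inv(xtwx) * scale**2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tq = float(stats.t.ppf(0.975, df))
    slope_p = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    intercept_p = float(2.0 * stats.t.sf(abs(intercept) / se_int, df))
    fit = EggerFit(
        slope=slope,
        slope_se=se_slope,
        slope_p=max(slope_p, 5e-324),
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=max(intercept_p, 5e-324),
        df=df,
        phi=phi,
    )
    est = MrEstimate(
        method="egger",
        n_snps=L,
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        p=fit.slope_p,
    )
    return fit, est


def _ratio_arrays(ds: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray]:
    g, _, G, sG = ds.arrays()
    if np.any(g == 0):
        raise AnalysisError("ratio estimates undefined with a zero exposure effect")
    return G / g, sG / np.abs(g)


def weighted_median_point(ratios: np.ndarray, ratio_ses: np.ndarray) -> float:
    """Interpolated weighted median of per-SNP ratios.

    Weights are inverse-variance, normalized to sum 1; ratios are sorted and
    the weighted empirical CDF, evaluated at the cumulative midpoint
    percentiles p_k = sum_{i<=k} w_i - w_k / 2, is linearly interpolated and
    inverted at 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(ratio_ses, dtype=float)[order] ** -2.0
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def weighted_median(
    ds: HarmonizedDataset,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is deterministic. Its SE is the standard deviation of
    the estimate across ``n_boot`` replicates in which each ratio is redrawn
    normal around its observed value with SD sigma_Gj/|gamma_j| while the
    weights stay fixed; ``seed`` makes the bootstrap reproducible and is
    required.
    """
    L = len(ds)
    if L < 3:
        raise AnalysisError(f"weighted median requires at least 3 instruments, got {L}")
    if n_boot < 100:
        raise ConfigurationError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise ConfigurationError("weighted_median requires an explicit seed")
    ratios, ratio_ses = _ratio_arrays(ds)
    estimate = weighted_median_point(ratios, ratio_ses)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_ses, size=(n_boot, L))
    order = np.argsort(draws, axis=1, kind="stable")
    r_sorted = np.take_along_axis(draws, order, axis=1)
    w = ratio_ses**-2.0
    w = w / w.sum()
    w_sorted = np.take_along_axis(np.broadcast_to(w, draws.shape), order, axis=1)
    p = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    boots = np.array(
        [np.interp(0.5, p[i], r_sorted[i]) for i in range(n_boot)], dtype=float
    )
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", L, estimate, se)
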