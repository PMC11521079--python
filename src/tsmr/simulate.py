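"""Synthetic two-sample summary statistics with known ground truth.

Generates paired exposure/outcome GWAS summary tables under the linear
instrumental-variable model

    Gamma_j = theta * gamma_j + alpha_j,

where theta is the causal effect, gamma_j the true SNP→exposure effect, and
alpha_j a direct (horizontally pleiotropic) SNP→outcome effect that is zero
for valid instruments. Observed effects are the truths plus per-study
Gaussian sampling noise with standard errors driven by allele frequency and
sample size, sigma = 1 / sqrt(2 p (1-p) n_eff); for a binary outcome the
effective size is n * K(1-K) with case fraction K, putting the outcome on
the log-odds scale. Direct effects are drawn independently of instrument
strength, so the InSIDE condition holds by construction.

Generator output is a valid pipeline input: the tables round-trip through
:mod:`tsmr.io` and harmonize cleanly (alleles are emitted pre-aligned, with
a configurable share of palindromic A/T / C/G assignments for exercising the
harmonization filters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .datamodel import SnpAssociation, SummaryStatsTable
from .errors import ConfigurationError
from .fixtures import EXPOSURE_N, OUTCOME_N_CASES, OUTCOME_N_CONTROLS

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_pair", "lst_dr_scenario"]

_NONPALINDROMIC = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
_PALINDROMIC = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated two-sample dataset.

    Parameters
    ----------
    L
        Number of instruments.
    theta
        True causal effect (outcome units per exposure SD).
    gamma_mean, gamma_sd
        Mean and SD of the per-SNP exposure-effect *magnitudes*;
        ``gamma_sign`` ("negative", "positive" or "mixed") sets the sign
        convention of the emitted effects.
    maf_range
        Uniform range for minor-allele frequencies, within (0, 0.5].
    n_exp, n_out
        Study sample sizes driving the SE magnitudes.
    case_fraction
        Outcome case fraction K for a binary outcome (SEs scale with
        n_out * K(1-K)); ``None`` means a continuous outcome.
    invalid_fraction, alpha_mean, alpha_sd
        round(invalid_fraction * L) instruments receive a direct effect
        alpha_j ~ N(alpha_mean, alpha_sd); the rest have alpha_j = 0.
    palindromic_fraction
        Share of SNPs assigned A/T or C/G allele pairs.
    seed
        RNG seed; identical configs produce byte-identical tables.
    """

    L: int = 63
    theta: float = 0.0
    gamma_mean: float = 0.028
    gamma_sd: float = 0.006
    gamma_sign: str = "negative"
    maf_range: tuple[float, float] = (0.02, 0.10)
    n_exp: int = EXPOSURE_N
    n_out: int = OUTCOME_N_CASES + OUTCOME_N_CONTROLS
    case_fraction: Optional[float] = OUTCOME_N_CASES / (OUTCOME_N_CASES + OUTCOME_N_CONTROLS)
    invalid_fraction: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        for name in ("invalid_fraction", "palindromic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.gamma_sign not in ("negative", "positive", "mixed"):
            raise ConfigurationError(f"unknown gamma_sign {self.gamma_sign!r}")
        if self.n_exp < 2 or self.n_out < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ConfigurationError("case_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """What the generator actually drew, for estimator-recovery checks."""

    config: SimulationConfig
    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    invalid_rsids: tuple[str, ...]

    @property
    def oriented_mean_alpha(self) -> float:
        """Mean direct effect in the gamma >= 0 orientation (the frame in
        which the Egger intercept is interpreted)."""
        signs = np.where(np.asarray(self.gamma) < 0, -1.0, 1.0)
        return float(np.mean(signs * np.asarray(self.alpha)))


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SyntheticTruth]:
    """Draw one exposure/outcome summary-statistics pair plus its truth."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.L
    maf = rng.uniform(*cfg.maf_range, size=L)
    mag = np.abs(rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=L))
    mag = np.maximum(mag, 1e-6)  # guard exact zeros; ratios must exist
    if cfg.gamma_sign == "negative":
        gamma = -mag
    elif cfg.gamma_sign == "positive":
        gamma = mag
    else:
        gamma = mag * rng.choice([-1.0, 1.0], size=L)

    n_invalid = round(cfg.invalid_fraction * L)
    invalid_idx = np.sort(rng.choice(L, size=n_invalid, replace=False))
    alpha = np.zeros(L)
    if n_invalid:
        alpha[invalid_idx] = rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=n_invalid)
    Gamma = cfg.theta * gamma + alpha

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exp)
    n_eff_out = cfg.n_out * (
        cfg.case_fraction * (1.0 - cfg.case_fraction) if cfg.case_fraction is not None else 1.0
    )
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff_out)
    g_hat = rng.normal(gamma, se_exp)
    G_hat = rng.normal(Gamma, se_out)
    p_exp = _two_sided_p(g_hat / se_exp)
    p_out = _two_sided_p(G_hat / se_out)

    n_pal = round(cfg.palindromic_fraction * L)
    pal_flags = np.zeros(L, dtype=bool)
    if n_pal:
        pal_flags[rng.choice(L, size=n_pal, replace=False)] = True

    rsids = [f"rs{900000 + j}" for j in range(L)]
    exposure = SummaryStatsTable("simulated_exposure")
    outcome = SummaryStatsTable("simulated_outcome")
    for j in range(L):
        pool = _PALINDROMIC if pal_flags[j] else _NONPALINDROMIC
        ea, oa = pool[int(rng.integers(len(pool)))]
        exposure.add(
            SnpAssociation(
                rsid=rsids[j],
                effect_allele=ea,
                other_allele=oa,
                beta=float(g_hat[j]),
                se=float(se_exp[j]),
                pval=float(p_exp[j]),
                eaf=float(maf[j]),
                n=cfg.n_exp,
            )
        )
        outcome.add(
            SnpAssociation(
                rsid=rsids[j],
                effect_allele=ea,
                other_allele=oa,
                beta=float(G_hat[j]),
                se=float(se_out[j]),
                pval=float(p_out[j]),
                eaf=float(maf[j]),
                n=cfg.n_out,
            )
        )
    truth = SyntheticTruth(
        config=cfg,
        gamma=tuple(float(x) for x in gamma),
        alpha=tuple(float(x) for x in alpha),
        invalid_rsids=tuple(rsids[i] for i in invalid_idx),
    )
    return exposure, outcome, truth


def lst_dr_scenario(theta: float = 0.2, seed: int = 0, **overrides) -> SimulationConfig:
    """Config emulating the dimensions of the packaged LST→DR dataset.

    63 instruments, a 703,901-person exposure GWAS, and a binary outcome
    with 10,413 cases / 308,633 controls. The MAF range (0.02, 0.10) is
    chosen so generated exposure SEs land in the published 0.003-0.015
    range at the full meta-analysis sample size, and effect magnitudes
    mirror the published |beta| ~ 0.028 (negative sign convention).
    Keyword overrides are forwarded to :class:`SimulationConfig`.
    """
    base = dict(
        L=63,
        theta=theta,
        gamma_mean=0.028,
        gamma_sd=0.006,
        gamma_sign="negative",
        maf_range=(0.02, 0.10),
        n_exp=EXPOSURE_N,
        n_out=OUTCOME_N_CASES + OUTCOME_N_CONTROLS,
        case_fraction=OUTCOME_N_CASES / (OUTCOME_N_CASES + OUTCOME_N_CONTROLS),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
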