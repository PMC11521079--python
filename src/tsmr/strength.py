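"""Instrument strength (F statistics, variance explained) and binary-outcome power.

Weak instruments bias two-sample MR estimates toward the null; the
conventional screen is F > 10. The overall F statistic for k instruments
jointly explaining a fraction R^2 of the exposure variance in a sample of
size N is

    F = (N - k - 1) / k * R^2 / (1 - R^2).

Per-SNP strength is summarized by the squared z statistic (beta/se)^2, a
first-order approximation to the single-instrument regression F; it is
reported as approximate because it ignores the per-SNP R^2 term.

Statistical power for a binary outcome uses the standard normal
approximation for an instrumented continuous exposure:

    power = Phi( sqrt(n * R^2 * K(1-K)) * |ln OR| - z_{1-alpha/2} )

with n the outcome-GWAS size, K its case fraction, R^2 the variance in the
exposure explained by the instruments, and OR the odds ratio per exposure SD
under the alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .datamodel import HarmonizedDataset, HarmonizedInstrument
from .errors import ConfigurationError

__all__ = ["StrengthSummary", "PowerInput", "f_overall", "f_per_snp", "power_binary", "strength_summary"]


@dataclass(frozen=True)
class StrengthSummary:
    """Overall instrument strength for one exposure dataset."""

    N: int
    k: int
    r2: float
    f_overall: float
    per_snp_f_approx: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "k": self.k,
            "r2": self.r2,
            "f_overall": self.f_overall,
            "per_snp_f_approx": dict(self.per_snp_f_approx),
            "per_snp_f_note": "approximate (beta/se)^2; not a joint regression F",
        }


@dataclass(frozen=True)
class PowerInput:
    """Inputs of the binary-outcome power calculation; nothing is defaulted."""

    n_total: int
    case_fraction: float
    r2: float
    alpha: float
    or_alt: float

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ConfigurationError("n_total must be positive")
        if not (0 < self.case_fraction < 1):
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if not (0 < self.r2 < 1):
            raise ConfigurationError("r2 must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.or_alt <= 0:
            raise ConfigurationError("or_alt must be positive")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "case_fraction": self.case_fraction,
            "r2": self.r2,
            "alpha": self.alpha,
            "or_alt": self.or_alt,
        }


def f_overall(N: int, k: int, r2: float) -> float:
    """Overall F statistic (N - k - 1)/k * R^2/(1 - R^2)."""
    if not (0 < r2 < 1):
        raise ConfigurationError(f"r2 must lie in (0, 1), got {r2}")
    if k < 1 or N <= k + 1:
        raise ConfigurationError(f"need N > k + 1 >= 2, got N={N}, k={k}")
    return (N - k - 1) / k * r2 / (1.0 - r2)


def f_per_snp(inst: HarmonizedInstrument) -> float:
    """Approximate per-SNP F: the squared exposure z statistic (beta/se)^2."""
    return (inst.beta_exp / inst.se_exp) ** 2


def strength_summary(
    ds: HarmonizedDataset, N: int, r2: Optional[float] = None
) -> StrengthSummary:
    """Bundle overall and per-SNP strength for a harmonized dataset.

    ``r2`` is the externally estimated variance explained by the instrument
    set; when absent the overall F is reported as NaN rather than derived
    from printed betas (which cannot reproduce a joint R^2).
    """
    per_snp = {inst.rsid: f_per_snp(inst) for inst in ds.instruments}
    k = len(ds)
    f_all = f_overall(N, k, r2) if r2 is not None else math.nan
    return StrengthSummary(
        N=N, k=k, r2=math.nan if r2 is None else r2, f_overall=f_all, per_snp_f_approx=per_snp
    )


def power_binary(inp: PowerInput) -> float:
    """Power of the two-sided Wald test at level alpha for a binary outcome.

    Symmetric in or_alt <-> 1/or_alt; equals alpha/2 at or_alt = 1.
    """
    K = inp.case_fraction
    ncp = math.sqrt(inp.n_total * inp.r2 * K * (1.0 - K)) * abs(math.log(inp.or_alt))
    z = float(stats.norm.ppf(1.0 - inp.alpha / 2.0))
    return float(stats.norm.cdf(ncp - z))
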