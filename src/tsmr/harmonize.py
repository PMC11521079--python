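"""Allele harmonization and instrument screening.

Aligns exposure and outcome summary statistics to a common effect allele and
applies the screening filters of a two-sample MR workflow: exposure
significance threshold, confounder deny-list, and palindromic-variant
handling. Every removed variant lands in the exclusion log with a reason, so
|intersection| = |instruments| + |exclusions| always holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .datamodel import (
    HarmonizedDataset,
    HarmonizedInstrument,
    SnpAssociation,
    SummaryStatsTable,
)
from .errors import AnalysisError, ConfigurationError

__all__ = ["HarmonizationConfig", "is_palindromic", "harmonize", "apply_deny_list"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: rsids the published LST→DR screening removed as confounder-associated or
#: ambiguous-palindromic before arriving at its final instrument set.
PUBLISHED_DENY_LIST = frozenset(
    {"rs12992995", "rs13107325", "rs3791033", "rs6010651", "rs6857", "rs71658797"}
)


@dataclass(frozen=True)
class HarmonizationConfig:
    """Screening and alignment policy.

    Parameters
    ----------
    palindrome_policy
        ``"drop_all"`` removes every A/T and C/G variant; ``"drop_ambiguous"``
        (default) removes those whose effect-allele frequency lies inside
        ``ambiguous_eaf_window`` *or is unknown*; ``"keep"`` retains all
        palindromic variants and is intended for instrument sets that were
        already strand-checked upstream (such as the packaged LST→DR set).
    ambiguous_eaf_window
        Symmetric frequency interval around 0.5 within which a palindromic
        variant's strand cannot be resolved from frequency alone.
    pval_threshold
        Exposure-association significance required of an instrument
        (relevance criterion). Default 5e-9, the threshold the source
        exposure GWAS used.
    deny_list
        rsids excluded as confounder-associated (independence criterion).
    strand_complement
        When True, an outcome variant whose alleles match neither orientation
        is retried after A<->T / C<->G complementing before being excluded.
        Off by default: exclusion is the conservative choice.
    """

    palindrome_policy: str = "drop_ambiguous"
    ambiguous_eaf_window: tuple[float, float] = (0.42, 0.58)
    pval_threshold: float = 5e-9
    deny_list: frozenset[str] = frozenset()
    strand_complement: bool = False

    def __post_init__(self) -> None:
        if self.palindrome_policy not in ("drop_all", "drop_ambiguous", "keep"):
            raise ConfigurationError(
                f"unknown palindrome_policy {self.palindrome_policy!r}"
            )
        lo, hi = self.ambiguous_eaf_window
        if not (0 < lo < 0.5 < hi < 1):
            raise ConfigurationError(
                f"ambiguous_eaf_window must straddle 0.5 within (0,1), got {self.ambiguous_eaf_window}"
            )
        if not (0 < self.pval_threshold <= 1):
            raise ConfigurationError("pval_threshold must lie in (0, 1]")
        object.__setattr__(self, "deny_list", frozenset(self.deny_list))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}.

    Multi-base alleles (indels) are never palindromic: their strand is
    unambiguous in summary data.
    """
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def _align(exp: SnpAssociation, out: SnpAssociation, strand_complement: bool):
    """Return (beta_out, eaf_out, flipped) aligned to exp's effect allele, or None."""
    pairs = [(out.effect_allele, out.other_allele, out.beta, out.eaf)]
    if strand_complement:
        cea, coa = _complement(out.effect_allele), _complement(out.other_allele)
        if cea is not None and coa is not None and {cea, coa} != {out.effect_allele, out.other_allele}:
            pairs.append((cea, coa, out.beta, out.eaf))
    for ea, oa, beta, eaf in pairs:
        if (ea, oa) == (exp.effect_allele, exp.other_allele):
            return beta, eaf, False
        if (ea, oa) == (exp.other_allele, exp.effect_allele):
            return -beta, None if eaf is None else 1.0 - eaf, True
    return None


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    cfg: HarmonizationConfig = HarmonizationConfig(),
) -> HarmonizedDataset:
    """Intersect, align and screen an exposure/outcome table pair.

    Variants are processed in exposure order. Each shared rsid either becomes
    a :class:`~tsmr.datamodel.HarmonizedInstrument` or is logged with one of
    the exclusion reasons ``deny_list``, ``exposure_pvalue``,
    ``allele_mismatch``, ``palindromic`` or ``palindromic_ambiguous``.

    Raises
    ------
    AnalysisError
        The two tables share no rsids.
    """
    shared = [r for r in exposure.rsids if r in outcome]
    if not shared:
        raise AnalysisError(
            f"no shared rsids between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )
    ds = HarmonizedDataset()
    for rsid in shared:
        exp, out = exposure[rsid], outcome[rsid]
        if rsid in cfg.deny_list:
            ds.exclusions.append((rsid, "deny_list"))
            continue
        if exp.pval > cfg.pval_threshold:
            ds.exclusions.append((rsid, "exposure_pvalue"))
            continue
        aligned = _align(exp, out, cfg.strand_complement)
        if aligned is None:
            ds.exclusions.append((rsid, "allele_mismatch"))
            continue
        beta_out, eaf_out, flipped = aligned
        eaf = exp.eaf if exp.eaf is not None else eaf_out
        if is_palindromic(exp.effect_allele, exp.other_allele):
            if cfg.palindrome_policy == "drop_all":
                ds.exclusions.append((rsid, "palindromic"))
                continue
            if cfg.palindrome_policy == "drop_ambiguous":
                lo, hi = cfg.ambiguous_eaf_window
                if eaf is None or lo <= eaf <= hi:
                    ds.exclusions.append((rsid, "palindromic_ambiguous"))
                    continue
        ds.instruments.append(
            HarmonizedInstrument(
                rsid=rsid,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf=eaf,
                flipped=flipped,
            )
        )
    return ds


def apply_deny_list(dataset: HarmonizedDataset, rsids: Iterable[str]) -> HarmonizedDataset:
    """Move instruments whose rsid is listed into the exclusion log.

    Idempotent; the returned dataset shares no mutable state with the input.
    """
    listed = set(rsids)
    kept, dropped = [], []
    for inst in dataset.instruments:
        (dropped if inst.rsid in listed else kept).append(inst)
    exclusions = list(dataset.exclusions)
    exclusions.extend((inst.rsid, "confounder-associated") for inst in dropped)
    return HarmonizedDataset(instruments=kept, exclusions=exclusions)
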