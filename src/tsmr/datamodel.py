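"""Domain types for summary-statistics Mendelian randomization.

The package works entirely on GWAS summary associations: one (beta, SE) pair
per variant per trait. ``SnpAssociation`` holds a single variant-trait
association, ``SummaryStatsTable`` an ordered, rsid-keyed collection of them
for one trait, and ``HarmonizedInstrument``/``HarmonizedDataset`` the result
of aligning an exposure table and an outcome table to a common effect allele.

Notation used throughout the package: for instrument *j*, gamma_j (``beta_exp``)
is the SNP→exposure effect with standard error ``se_exp``, and Gamma_j
(``beta_out``) the SNP→outcome effect with standard error ``se_out``, both
expressed per copy of the same effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .errors import DataError

__all__ = [
    "SnpAssociation",
    "SummaryStatsTable",
    "HarmonizedInstrument",
    "HarmonizedDataset",
]


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary association with one trait.

    Parameters
    ----------
    rsid
        Variant identifier (e.g. ``"rs10189857"``).
    effect_allele, other_allele
        Allele strings, upper-case. Multi-base strings (indels) are allowed.
    beta
        Signed effect per effect-allele copy. Units depend on the trait:
        SD units for a continuous exposure, log-odds for a binary outcome.
    se
        Standard error of ``beta``; must be strictly positive.
    pval
        Association p-value in (0, 1].
    eaf
        Effect-allele frequency in (0, 1), or ``None`` when the source table
        does not report it. Absence is meaningful (palindrome screening must
        distinguish "unknown" from "balanced"), so it is never imputed.
    n
        Per-SNP sample size, or ``None``.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise DataError("empty rsid")
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if not a:
                raise DataError(f"{self.rsid}: empty {name}")
            if a != a.upper():
                object.__setattr__(self, name, a.upper())
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise DataError(f"{self.rsid}: non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            raise DataError(f"{self.rsid}: se must be > 0, got {self.se!r}")
        if not (0 < self.pval <= 1):
            raise DataError(f"{self.rsid}: p-value {self.pval!r} outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise DataError(f"{self.rsid}: eaf {self.eaf!r} outside (0, 1)")
        if self.n is not None and self.n <= 0:
            raise DataError(f"{self.rsid}: non-positive sample size")


class SummaryStatsTable:
    """Ordered collection of :class:`SnpAssociation` for one trait.

    Preserves insertion order (so read→write→read round-trips are the
    identity) and enforces rsid uniqueness.
    """

    def __init__(self, trait_label: str, records: Iterable[SnpAssociation] = ()):
        self.trait_label = trait_label
        self._records: dict[str, SnpAssociation] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SnpAssociation) -> None:
        if rec.rsid in self._records:
            raise DataError(f"duplicate rsid {rec.rsid!r} in table {self.trait_label!r}")
        self._records[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self._records.values())

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._records

    def __getitem__(self, rsid: str) -> SnpAssociation:
        return self._records[rsid]

    @property
    def rsids(self) -> list[str]:
        return list(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryStatsTable):
            return NotImplemented
        return (
            self.trait_label == other.trait_label
            and list(self._records.items()) == list(other._records.items())
        )

    def __repr__(self) -> str:
        return f"SummaryStatsTable({self.trait_label!r}, {len(self)} records)"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant with exposure and outcome effects aligned to one effect allele."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: Optional[float] = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise DataError(f"{self.rsid}: standard errors must be > 0")


@dataclass
class HarmonizedDataset:
    """Instruments surviving harmonization plus the exclusion log.

    Every rsid present in the exposure/outcome intersection appears in exactly
    one of ``instruments`` or ``exclusions``.
    """

    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [inst.rsid for inst in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (gamma, se_gamma, Gamma, se_Gamma) as float arrays."""
        g = np.array([i.beta_exp for i in self.instruments], dtype=float)
        sg = np.array([i.se_exp for i in self.instruments], dtype=float)
        G = np.array([i.beta_out for i in self.instruments], dtype=float)
        sG = np.array([i.se_out for i in self.instruments], dtype=float)
        return g, sg, G, sG

    def subset(self, rsids: Iterable[str]) -> "HarmonizedDataset":
        """Dataset restricted to ``rsids`` (exclusion log not carried over)."""
        keep = set(rsids)
        return HarmonizedDataset(
            instruments=[i for i in self.instruments if i.rsid in keep]
        )

    def drop(self, rsids: Iterable[str]) -> "HarmonizedDataset":
        omit = set(rsids)
        return HarmonizedDataset(
            instruments=[i for i in self.instruments if i.rsid not in omit]
        )
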