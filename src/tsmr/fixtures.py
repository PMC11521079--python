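"""Packaged instrument set: leisure screen time (LST) → diabetic retinopathy (DR).

The package ships the published 63-SNP instrument table for the LST→DR
analysis as plain TSV package data: for each variant, the effect/other
allele, the SNP→LST association (beta in SD units of screen time, SE,
p-value) from a 703,901-person GWAS meta-analysis, the SNP→DR association
(log-odds beta, SE, p-value) from a FinnGen case-control GWAS (10,413 cases,
308,633 controls), the per-SNP exposure sample size, and the published
per-SNP F statistic.

Digits are stored exactly as published (3-decimal betas/SEs). The published
per-SNP F column is carried verbatim but is *not* derivable from the printed
beta/SE pairs; use :func:`tsmr.strength.f_per_snp` for the usual (beta/se)^2
approximation and treat the two as different quantities.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .datamodel import SnpAssociation, SummaryStatsTable
from .errors import DataError

__all__ = ["load_lst_dr_instruments", "lst_dr_frame", "EXPOSURE_N", "OUTCOME_N_CASES", "OUTCOME_N_CONTROLS"]

#: Total exposure-GWAS sample size (meta-analysis of leisure screen time).
EXPOSURE_N = 703_901
#: Outcome (diabetic retinopathy) case/control counts.
OUTCOME_N_CASES = 10_413
OUTCOME_N_CONTROLS = 308_633

_FIXTURE = "lst_dr_instruments.tsv"
_SHA256 = "c8751beac041c12dc18890961696123e71f110cf73c731fe8dc23841a68281cc"


def _fixture_bytes() -> bytes:
    data = (resources.files("tsmr") / "data" / _FIXTURE).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _SHA256:
        raise DataError(
            f"packaged instrument table is corrupted (sha256 {digest}, expected {_SHA256})"
        )
    return data


def lst_dr_frame() -> pd.DataFrame:
    """The raw packaged table as a DataFrame (checksum-verified)."""
    import io as _io

    return pd.read_csv(_io.BytesIO(_fixture_bytes()), sep="\t", dtype=str)


def load_lst_dr_instruments() -> tuple[SummaryStatsTable, SummaryStatsTable]:
    """Load the packaged 63-SNP LST→DR instrument set.

    Returns
    -------
    (exposure, outcome)
        Two :class:`~tsmr.datamodel.SummaryStatsTable` with identical rsid
        sets and allele columns (the published table is already harmonized,
        so exposure and outcome share effect/other alleles). No effect-allele
        frequencies are published, so ``eaf`` is ``None`` throughout.
    """
    df = lst_dr_frame()
    exposure = SummaryStatsTable("leisure_screen_time")
    outcome = SummaryStatsTable("diabetic_retinopathy")
    for _, row in df.iterrows():
        common = dict(
            rsid=row["rsid"],
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
        )
        exposure.add(
            SnpAssociation(
                beta=float(row["beta_exp"]),
                se=float(row["se_exp"]),
                pval=float(row["pval_exp"]),
                n=int(row["n_exp"]),
                **common,
            )
        )
        outcome.add(
            SnpAssociation(
                beta=float(row["beta_out"]),
                se=float(row["se_out"]),
                pval=float(row["pval_out"]),
                **common,
            )
        )
    return exposure, outcome
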