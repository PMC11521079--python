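"""Readers and writers for delimited GWAS summary-statistic tables.

Column mapping is explicit configuration, never guessed from headers: GWAS
summary formats are dialect-rich and silently mis-mapping an allele or beta
column produces sign errors that propagate into the causal estimate. The
defaults accept the common ``SNP / effect_allele / other_allele / beta / se /
pval / eaf / N`` layout.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .datamodel import SnpAssociation, SummaryStatsTable
from .errors import ConfigurationError, DataError

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_summary_stats",
    "write_summary_stats",
    "read_deny_list",
]

#: file-header → field-name mapping used when the caller supplies none.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "SNP": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "eaf": "eaf",
    "N": "n",
}

_REQUIRED = {"rsid", "effect_allele", "other_allele", "beta", "se", "pval"}


def _sep_for(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return "," if name.endswith(".csv") else "\t"


def read_summary_stats(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
    trait_label: Optional[str] = None,
) -> SummaryStatsTable:
    """Read a tab- or comma-separated summary-statistics table.

    Parameters
    ----------
    path
        File path; ``.csv`` (or ``.csv.gz``) is parsed comma-separated,
        anything else tab-separated. gzip is handled transparently.
    column_map
        Mapping from file headers to the field names of
        :class:`~tsmr.datamodel.SnpAssociation`. Must cover rsid, alleles,
        beta, se and pval; eaf and n are optional.
    trait_label
        Label for the returned table; defaults to the file stem.

    Raises
    ------
    ConfigurationError
        A mapped column is absent from the file, or a required field is not
        mapped at all.
    DataError
        Duplicate rsid, unparseable or missing beta/se, non-positive se.
    """
    path = Path(path)
    cmap = dict(column_map) if column_map is not None else dict(DEFAULT_COLUMN_MAP)
    missing_fields = _REQUIRED - set(cmap.values())
    if missing_fields:
        raise ConfigurationError(
            f"column map does not cover required fields: {sorted(missing_fields)}"
        )
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    absent = [col for col in cmap if col not in df.columns]
    if absent:
        raise ConfigurationError(
            f"{path}: mapped columns missing from file: {absent}; found {list(df.columns)}"
        )

    table = SummaryStatsTable(trait_label or path.stem)
    for idx, row in df.iterrows():
        kwargs: dict[str, object] = {}
        for col, fieldname in cmap.items():
            raw = row[col]
            if fieldname in ("rsid", "effect_allele", "other_allele"):
                kwargs[fieldname] = "" if pd.isna(raw) else str(raw).strip()
                continue
            if pd.isna(raw) or str(raw).strip() == "":
                val = None
            else:
                try:
                    val = float(str(raw).replace(",", ""))
                except ValueError as exc:
                    raise DataError(
                        f"{path} row {idx}: cannot parse {fieldname} value {raw!r}"
                    ) from exc
            kwargs[fieldname] = val
        if kwargs.get("beta") is None or kwargs.get("se") is None:
            raise DataError(
                f"{path} row {idx} ({kwargs.get('rsid', '?')}): missing beta or se"
            )
        if kwargs.get("pval") is None:
            raise DataError(f"{path} row {idx}: missing p-value")
        if kwargs.get("n") is not None:
            kwargs["n"] = int(math.floor(float(kwargs["n"])))  # type: ignore[arg-type]
        table.add(SnpAssociation(**kwargs))  # type: ignore[arg-type]
    return table


def write_summary_stats(table: SummaryStatsTable, path: Union[str, Path]) -> None:
    """Write ``table`` in the default dialect ``read_summary_stats`` accepts."""
    path = Path(path)
    rows = [
        {
            "SNP": r.rsid,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "beta": repr(r.beta),
            "se": repr(r.se),
            "pval": repr(r.pval),
            "eaf": "" if r.eaf is None else repr(r.eaf),
            "N": "" if r.n is None else str(r.n),
        }
        for r in table
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_deny_list(path: Union[str, Path]) -> set[str]:
    """Read a deny-list file: one rsid per line, ``#`` starts a comment."""
    rsids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            rsids.add(entry)
    return rsids
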