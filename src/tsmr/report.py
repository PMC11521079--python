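"""Report serialization: full-precision JSON plus a human-readable forest table.

The JSON file is the machine-readable record of a run: every estimate,
diagnostic, per-SNP table, exclusion, seed and threshold. Floats are written
with ``repr`` precision so re-reading the file reproduces every number
bit-identically, and keys are sorted so identical runs produce
byte-identical files. The TSV summary mirrors the conventional forest-plot
layout (method, nSNP, OR, 95% CI, p).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from .errors import AnalysisError, TsmrError

__all__ = ["write_report", "read_report", "summary_lines"]


def summary_lines(report: dict) -> list[str]:
    """Forest-style summary rows for the estimates in ``report``."""
    lines = ["method\tnSNP\tOR\tCI_low\tCI_high\tp"]
    for est in report["estimates"]:
        lines.append(
            "{method}\t{n_snps}\t{or:.4f}\t{or_low:.4f}\t{or_high:.4f}\t{p:.3g}".format(**est)
        )
    return lines


def write_report(report: dict, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write ``report`` as ``report.json`` + ``summary.tsv`` under ``out_dir``.

    Raises
    ------
    AnalysisError
        The report holds no estimates.
    TsmrError
        The output location cannot be written.
    """
    if not report.get("estimates"):
        raise AnalysisError("refusing to write a report with no estimates")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        json_path = out_dir / "report.json"
        json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        tsv_path = out_dir / "summary.tsv"
        tsv_path.write_text("\n".join(summary_lines(report)) + "\n")
        excl_path = out_dir / "exclusions.tsv"
        excl_lines = ["rsid\treason"] + [
            f"{rsid}\t{reason}" for rsid, reason in report.get("exclusions", [])
        ]
        excl_path.write_text("\n".join(excl_lines) + "\n")
    except OSError as exc:
        raise TsmrError(f"cannot write report under {out_dir}: {exc}") from exc
    return {"json": json_path, "summary": tsv_path, "exclusions": excl_path}


def read_report(path: Union[str, Path]) -> dict:
    """Load a previously written ``report.json``."""
    return json.loads(Path(path).read_text())
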