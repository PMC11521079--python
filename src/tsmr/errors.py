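"""Exception hierarchy shared across the pipeline.

Each class carries the process exit code the command-line layer maps it to.
"""


class TsmrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(TsmrError):
    """A run was configured inconsistently (bad column map, thresholds, counts)."""

    exit_code = 2


class DataError(TsmrError):
    """An input table violates its contract (duplicate rsid, non-positive SE, ...)."""

    exit_code = 3


class AnalysisError(TsmrError):
    """A statistical stage cannot proceed (no overlapping SNPs, too few instruments)."""

    exit_code = 4
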