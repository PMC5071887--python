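"""Exception hierarchy for schpipe.

All package-raised errors derive from :class:`SchpipeError` so callers can
catch pipeline failures without masking programming errors.
"""


class SchpipeError(Exception):
    """Base class for all schpipe errors."""


class ConfigError(SchpipeError, ValueError):
    """Invalid configuration value or infeasible simulation request."""


class FormatError(SchpipeError, ValueError):
    """Malformed input file (missing column, bad index, asymmetry, ...)."""


class DimensionError(SchpipeError, ValueError):
    """Mismatched vector/matrix dimensions."""


class AnalysisError(SchpipeError, RuntimeError):
    """A statistical stage cannot run on the given data (empty populations,
    too few observations, undefined statistic)."""
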