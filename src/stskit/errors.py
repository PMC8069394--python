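"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: schema/contract problems exit with 2,
data-quality problems (e.g. excessive joint dropout) with 3.
"""


class StsKitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StsKitError):
    """A session log does not conform to the expected structure."""


class DataQualityError(StsKitError):
    """A session parses but is too degraded to analyze (e.g. joint dropout)."""


class ContractError(StsKitError):
    """An operation was called with inputs violating its preconditions."""


class UndefinedAngleError(ContractError):
    """An angle is requested for a degenerate joint configuration."""


class ConfigError(StsKitError):
    """Invalid configuration (generator parameters, dialects, report specs)."""
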