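"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigError(MRMediateError):
    """Invalid configuration: missing columns, out-of-range thresholds."""


class DataError(MRMediateError):
    """Invalid or insufficient input data."""


class EmptyIntersectionError(DataError):
    """Exposure and outcome datasets share no variants."""


class InsufficientInstrumentsError(DataError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(DataError):
    """Wald ratio requested for an instrument with zero exposure effect."""


class MissingLDError(DataError):
    """A within-window variant pair has no LD (r-squared) entry."""
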