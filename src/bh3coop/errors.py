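"""Exception hierarchy.

All package errors derive from :class:`BH3CoopError` so callers (and the CLI)
can distinguish user/configuration problems (exit 1) from internal bugs (exit 2).
"""


class BH3CoopError(Exception):
    """Base class for all bh3coop errors."""


class InvalidParameterError(BH3CoopError, ValueError):
    """A numeric argument is outside its domain (negative time, bad fraction...)."""


class ConfigurationError(BH3CoopError):
    """A scenario or run configuration is inconsistent (bad refs, duplicate ids...)."""


class InsufficientDataError(BH3CoopError):
    """Too few events or replicates to carry out the requested estimate."""


class UndefinedMeasurementError(BH3CoopError):
    """The requested quantity is undefined for this input (e.g. 0 events)."""


class UndefinedBaselineError(UndefinedMeasurementError):
    """Delta-priming baseline is 100% release: the normalisation is undefined."""


class UndefinedFEAError(UndefinedMeasurementError):
    """Bliss-expected effect is zero: fold excess additivism is not evaluable."""


class ChannelAbsentError(BH3CoopError):
    """A required cytometry channel is missing from the event table."""


class IncompleteProfileError(BH3CoopError):
    """An agent profile lacks a delta required for classification."""


class SchemaError(BH3CoopError):
    """An input file does not match the documented column schema."""


class PairingError(BH3CoopError):
    """Predictions and combination results cannot be matched pairwise."""
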