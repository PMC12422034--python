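"""Exception hierarchy shared across the costing pipeline."""


class IntecostError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IntecostError):
    """Invalid configuration value; message names the offending field."""


class ParameterError(IntecostError):
    """A required economic parameter is missing or out of range."""


class SequencingError(ParameterError):
    """An operation was called out of order (e.g. PPP conversion before inflation)."""


class CurrencyMismatchError(IntecostError):
    """Arithmetic attempted between amounts in different currencies or price years."""


class AllocationError(IntecostError):
    """Facility cost allocation is undefined (e.g. costs with zero patient volume)."""


class DataError(IntecostError):
    """A record carries an invalid value; message identifies the record."""


class ScenarioError(IntecostError):
    """A scale-up scenario is incomplete or inconsistent."""


class InsufficientDataError(IntecostError):
    """Too few observations for the requested statistic."""


class JoinError(IntecostError):
    """Record keys do not match when combining cost tables."""
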