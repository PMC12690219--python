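"""Exception hierarchy for osteocea."""


class OsteoceaError(Exception):
    """Base class for all package errors."""


class SchemaError(OsteoceaError):
    """A configuration file is missing a required field or has unknown keys."""


class ParameterValidationError(OsteoceaError):
    """A parameter value violates its domain (negative cost, probability > 1, ...)."""


class InputError(OsteoceaError):
    """Invalid input data (inconsistent risk table, empty fit list, ...)."""


class FittingError(OsteoceaError):
    """Survival fitting is impossible on the given data (e.g. no events)."""


class ConvergenceError(FittingError):
    """The likelihood optimiser failed to converge."""


class UndefinedIcer(OsteoceaError):
    """ICER requested between strategies with identical effectiveness."""


class RangeError(OsteoceaError):
    """An age-indexed lookup fell outside the covered range."""


class ConfigError(OsteoceaError):
    """A strategy or scenario references an unconfigured drug/value."""
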