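"""Exception hierarchy for the pipeline."""


class HaircellError(Exception):
    """Base class for all package errors."""


class InputError(HaircellError):
    """Malformed or unreadable user input (files, tables, parameters)."""


class UnsupportedFormatError(InputError):
    """Image format or layout the pipeline does not support."""


class ConfigurationError(HaircellError):
    """Invalid or incomplete configuration (thresholds, backends, presets)."""


class PathEstimationError(HaircellError):
    """Automated cochlear-path estimation failed; manual annotation advised."""


class GeneratorError(HaircellError):
    """Synthetic-cochlea generator parameters are geometrically infeasible."""
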