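"""Exception hierarchy used across the pipeline."""


class PaleodynError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PaleodynError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PaleodynError):
    """An input violates a documented precondition or invariant."""


class CoverageError(PaleodynError):
    """A date or window falls outside calibration-curve coverage."""


class CollinearityError(PaleodynError):
    """The regressor matrix of a model fit is rank deficient."""


class ComparisonError(PaleodynError):
    """Fits from incompatible tables were mixed in one comparison set."""


class DivergenceError(PaleodynError):
    """A simulated trajectory became non-finite; the message reports the step."""
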