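"""Exception types shared across the package."""


class SorboptError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SorboptError, ValueError):
    """An input violates a documented precondition."""


class UnsupportedDesignError(SorboptError, ValueError):
    """A design family or size the package does not generate."""


class SingularDesignError(SorboptError, ValueError):
    """The model matrix is rank deficient; names the collinear columns."""


class InsufficientDataError(SorboptError, ValueError):
    """Too few usable points remain for a fit."""


class InvalidFitError(SorboptError, ValueError):
    """A fitted model is outside its admissible parameter region."""


class PipelineError(SorboptError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
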