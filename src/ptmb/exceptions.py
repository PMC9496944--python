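"""Exception hierarchy shared across the package."""


class PtmbError(Exception):
    """Base class for all package errors."""


class FormatError(PtmbError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(PtmbError):
    """In-memory data violate a documented invariant."""


class ParameterError(PtmbError):
    """A function argument is outside its documented range."""


class ConfigurationError(PtmbError):
    """Inconsistent configuration, e.g. a gene set member without a length."""


class ConvergenceError(PtmbError):
    """An iterative fit failed to converge; carries the fitter's diagnostics."""
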