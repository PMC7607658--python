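"""Exception hierarchy shared across the package."""


class MethdriftError(Exception):
    """Base class for all package errors."""


class FormatError(MethdriftError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(MethdriftError):
    """Parsed data violates a domain invariant; message names the cell/row."""


class DomainError(MethdriftError):
    """An operation was called with arguments outside its domain."""


class DesignError(MethdriftError):
    """A design matrix cannot be built (missing cells, fatal collinearity)."""


class FitError(MethdriftError):
    """A model fit is impossible (e.g. non-positive residual df)."""
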