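"""Exception types shared across the package."""


class SpeckleError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SpeckleError, ValueError):
    """A physically invalid input (e.g. particle coincident with a pixel)."""


class ParameterError(SpeckleError, ValueError):
    """An operation parameter outside its valid range."""


class StateError(SpeckleError, RuntimeError):
    """An operation applied to data in the wrong unit/state."""


class FitError(SpeckleError, RuntimeError):
    """A model fit that cannot be performed (e.g. non-decaying g2 curve)."""
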