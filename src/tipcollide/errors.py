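"""Exception hierarchy shared across the package."""


class TipCollideError(Exception):
    """Base class for all package errors."""


class SchemaError(TipCollideError, ValueError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(TipCollideError, ValueError):
    """Data violate an invariant (non-monotone frames, non-finite positions...)."""


class EmptyInputError(TipCollideError, ValueError):
    """A file or collection that must contain data is empty."""


class InsufficientWindowError(TipCollideError, ValueError):
    """A near-collision window contains no usable steps."""


class DegenerateTrackError(TipCollideError, ValueError):
    """A track statistic is undefined (e.g. zero whole-track speed)."""


class BlankImageError(TipCollideError, ValueError):
    """An image carries no orientation signal (constant intensity)."""


class FitFailureError(TipCollideError, RuntimeError):
    """Gaussian peak fit did not converge.

    Carries a mode-based fallback result in ``.fallback`` (peak at the
    histogram mode, dispersion from the circular standard deviation).
    """

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class FormatError(TipCollideError, ValueError):
    """Unsupported output file format."""
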