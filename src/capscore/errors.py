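"""Exception hierarchy shared across the package."""


class CapsError(Exception):
    """Base class for all capscore errors."""


class ValidationError(CapsError, ValueError):
    """A clinical value is outside its instrument's defined range."""


class IndeterminateStatusError(CapsError):
    """No usable CSF analyte or ratio to decide amyloid status."""


class InsufficientVisitsError(CapsError):
    """Fewer than two dated cognitive scores; decline is undefined."""


class ZeroSpanError(CapsError):
    """All cognitive scores fall on the same date; rate is undefined."""


class IncompleteScoreError(CapsError):
    """A CAPS component is missing; carries the component name."""

    def __init__(self, component: str, message: str | None = None):
        self.component = component
        super().__init__(message or f"cannot score subject: missing component {component!r}")


class DegenerateDataError(CapsError):
    """Group comparison input has no variance on the parametric path."""
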