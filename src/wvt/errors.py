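"""Exception hierarchy shared by all pipeline stages."""


class WvtError(Exception):
    """Base class for all pipeline errors."""


class InputError(WvtError):
    """Malformed or inconsistent input data (e.g. shape mismatch in a phase triplet)."""


class MeasurementError(WvtError):
    """A resolution/FWHM measurement could not be made (flat profile, no beads, no fit)."""


class RegistrationError(WvtError):
    """Channel registration failed (no shared structure, correlation below floor)."""


class PlanningError(WvtError):
    """An imaging region cannot be planned (e.g. exceeds stage travel limits)."""


class FormatError(WvtError):
    """Unsupported file content (non-grayscale TIFF, bad bit depth)."""


class SwcParseError(FormatError):
    """Malformed SWC row; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ConfigError(WvtError):
    """Invalid pipeline configuration."""
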