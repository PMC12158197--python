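"""Exception hierarchy.

Configuration problems (bad option values, mismatched metadata) are kept
distinct from input problems (degenerate or malformed data) so that the CLI
can map them to different exit messages.
"""


class VegcoverError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VegcoverError):
    """An option, parameter or metadata combination is invalid."""


class InputError(VegcoverError):
    """Input data violate a precondition (empty, degenerate, out of range)."""


class FormatError(InputError):
    """A file is not in the expected raster/table format."""


class NoSeparabilityError(InputError):
    """The two class histograms are identical; no threshold can separate them."""


class DegenerateSeparationError(InputError):
    """The class histograms do not form two distinct modes.

    Carries the mode bin index found for each class so callers can report
    where the distributions collapsed.
    """

    def __init__(self, message: str, veg_mode_bin: int, soil_mode_bin: int):
        super().__init__(message)
        self.veg_mode_bin = veg_mode_bin
        self.soil_mode_bin = soil_mode_bin


class PipelineStageError(VegcoverError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
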