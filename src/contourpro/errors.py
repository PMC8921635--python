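"""Exception hierarchy shared across the package."""


class ContourError(Exception):
    """Base class for all package-specific errors."""


class ImageFormatError(ContourError):
    """Raised when a raster file cannot be decoded."""


class EmptyDatasetError(ContourError):
    """Raised when a dataset directory yields no readable images."""


class ConfigError(ContourError):
    """Raised on malformed configuration text.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class ShapeMismatchError(ContourError):
    """Raised when image shapes do not agree with an operation's contract."""


class PreprocessingMismatchError(ContourError):
    """Raised when inference preprocessing does not match classifier training."""


class TrainingDivergenceError(ContourError):
    """Raised when a training loss becomes non-finite."""

    def __init__(self, message: str, iteration: int | None = None):
        self.iteration = iteration
        if iteration is not None:
            message = f"iteration {iteration}: {message}"
        super().__init__(message)
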