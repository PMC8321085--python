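"""Exception hierarchy shared by all pipeline stages."""


class DbtvisError(Exception):
    """Base class for all package errors."""


class FormatError(DbtvisError):
    """A file could not be parsed or lacks required metadata (e.g. spacing)."""


class DimensionalityError(DbtvisError):
    """Input data is not a 3D scalar grid."""


class GeometryError(DbtvisError):
    """An object (disk, ROI, profile band) does not fit inside its container."""


class DomainError(DbtvisError):
    """A numeric argument lies outside the mathematically valid domain."""


class UsageError(DbtvisError):
    """Preconditions on how an operation is called were violated."""


class FitError(DbtvisError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientDataError(DbtvisError):
    """Too few samples inside the analysis window."""


class InfiniteSmoothnessError(DbtvisError):
    """Residuals of the regression line are exactly zero (collinear profile)."""


class UndefinedCNRError(DbtvisError):
    """Background standard deviation is zero; CNR is undefined."""
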