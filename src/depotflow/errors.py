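"""Exception hierarchy for depotflow.

Everything derives from :class:`DepotflowError` so callers can catch the
package's own failures separately from programming errors.  Argument
validation raises subclasses of :class:`InvalidArgumentError`, which is
itself a ``ValueError``.
"""


class DepotflowError(Exception):
    """Base class for all depotflow errors."""


class InvalidArgumentError(DepotflowError, ValueError):
    """An argument violates a documented precondition."""


class GridMismatchError(InvalidArgumentError):
    """Spectrum and basis are defined on different wavenumber grids."""


class IllConditionedBasisError(DepotflowError):
    """Reference spectra are (numerically) collinear; unmixing is undefined."""


class UndefinedFractionError(InvalidArgumentError):
    """Both component weights are zero; a relative fraction is undefined."""


class NumericalResolutionError(DepotflowError):
    """The PDE solve failed at the requested resolution; refine the grid."""


class NonIdentifiableError(DepotflowError):
    """The observed series carries no signal the fit could constrain."""


class FitFailureError(DepotflowError):
    """Every optimizer start failed; per-start diagnostics are attached."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class DiagnosticUnavailableError(DepotflowError):
    """A series-shape diagnostic is undefined for the given series."""


class NoRegionError(DepotflowError):
    """A segmentation mask is empty where a region is required."""


class InvalidProfileError(InvalidArgumentError):
    """A serial-section profile violates its spacing/ordering contract."""


class DegenerateTestError(DepotflowError):
    """A statistical test is degenerate for the given data."""
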