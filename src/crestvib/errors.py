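"""Exception hierarchy shared across the analysis stages."""


class CrestVibError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CrestVibError, ValueError):
    """A construction or analysis parameter is outside its valid domain."""


class OverdampedError(InvalidParameterError):
    """Oscillator is not underdamped (Q <= 1/2), so no oscillatory response exists."""


class ResolutionError(CrestVibError):
    """Sampling or integration resolution is too coarse for the requested dynamics."""


class OutOfBoundsError(CrestVibError):
    """A rendered trajectory leaves the frame."""


class TrackingError(CrestVibError):
    """Too many frames without a trackable object in one or more regions."""


class WeakDriveError(CrestVibError):
    """Drive spectrum peak indistinguishable from the noise floor in a spectrogram slice."""


class NoResonanceError(CrestVibError):
    """No spectral peak above the prominence floor."""


class FitFailureError(CrestVibError):
    """Nonlinear least squares did not converge or converged to a meaningless fit."""


class DegenerateFitError(FitFailureError):
    """Fitted peak width collapsed below the frequency-grid resolution."""


class InsufficientDataError(CrestVibError):
    """Fewer samples than the operation requires."""


class UndefinedRatioError(CrestVibError):
    """Reference band power is zero, leaving a power ratio undefined."""


class DesignError(CrestVibError):
    """Rank-deficient fixed-effect design matrix."""

    def __init__(self, message: str, collinear: list[str] | None = None):
        super().__init__(message)
        self.collinear = collinear or []


class ConvergenceError(CrestVibError):
    """Iterative model fit failed to converge."""
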