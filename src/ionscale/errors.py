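"""Exception types shared across the package."""


class IonscaleError(Exception):
    """Base class for all package-specific errors."""


class IncompleteStatisticsError(IonscaleError, ValueError):
    """A moment-statistics record is missing a field needed by the caller."""


class InvalidStatisticsError(IonscaleError, ValueError):
    """A statistics or parameter record violates its positivity invariants."""


class UnknownIonError(IonscaleError, KeyError):
    """An ion label is not in the built-in tables."""


class NumericalBlowupError(IonscaleError, RuntimeError):
    """A simulated state became non-finite.

    Attributes
    ----------
    step : int or None
        Index of the first step at which a non-finite value appeared.
    """

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step


class DegenerateSpectrumError(IonscaleError, RuntimeError):
    """A drift matrix has (numerically) repeated eigenvalues.

    The linear analysis assumes a distinct spectrum.
    """


class UnstableModelError(IonscaleError, RuntimeError):
    """A drift matrix has an eigenvalue with non-negative real part."""


class TrajectoryTooShortError(IonscaleError, ValueError):
    """A trajectory does not contain enough steps for the requested estimator."""
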