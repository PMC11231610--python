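"""Exceptions and warnings shared across the package."""


class SpinbindError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpinbindError, ValueError):
    """A physical parameter is outside its admissible domain."""


class SpectralWindowError(SpinbindError):
    """The field window truncates a non-negligible part of the spectrum."""


class FastRegimeError(SpinbindError):
    """Rotational correlation time is beyond the fast-motion validity range."""


class WeightSumError(SpinbindError, ValueError):
    """Mixture weights do not form a normalized probability vector."""


class EmptySpectrumError(SpinbindError):
    """Total double integral is zero; fractions are undefined."""


class NoBindingError(SpinbindError):
    """Bound fraction is zero; a dissociation constant is undefined."""


class StoichiometryError(SpinbindError, ValueError):
    """Bound ligand would exceed the available protein or ligand."""


class UndefinedTransitionError(SpinbindError):
    """An equilibrium constant cannot be formed from the given populations."""


class UnattainableLevelError(SpinbindError):
    """A binding curve never reaches the requested saturation level."""


class FitError(SpinbindError):
    """Nonlinear fit failed to converge; carries best-so-far state."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class InsufficientSeriesError(SpinbindError):
    """Too few usable points to assemble a series."""


class TraceFormatError(SpinbindError):
    """A time trace does not span the required analysis windows."""


class ParseError(SpinbindError):
    """A data file could not be parsed; message names the offending line."""


class SequenceError(SpinbindError, ValueError):
    """A residue string contains characters outside the 20 canonical letters."""


class ConfigError(SpinbindError):
    """Pipeline configuration is malformed or contains unknown keys."""


class DegeneracyWarning(UserWarning):
    """Two library components are nearly indistinguishable on this axis."""


class EdgeMaximumWarning(UserWarning):
    """A series maximum sits at the grid edge; no interpolation performed."""


class PlateauWarning(UserWarning):
    """The saturation plateau is not identifiable from the sampled range."""


class FieldOrderWarning(UserWarning):
    """Field axis was not strictly increasing and has been sorted."""
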