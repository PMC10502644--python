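"""Exception hierarchy shared across the package."""


class FluidMREError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FluidMREError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UndefinedPhaseError(DomainError):
    """Phase angle requested for a modulus with zero storage and loss parts."""


class InvalidWavenumberError(DomainError):
    """Complex wavenumber violates k' > 0 or k'' >= 0."""


class UnderdeterminedError(FluidMREError, ValueError):
    """Too few data points to constrain the requested fit."""


class FitFailureError(FluidMREError, RuntimeError):
    """An optimizer failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ResonanceError(FluidMREError, ValueError):
    """Cylinder forward model evaluated at (or fit pinned to) a J0 zero."""


class SolverError(FluidMREError, RuntimeError):
    """Field forward solver could not produce a valid solution."""


class InversionError(FluidMREError, RuntimeError):
    """Wave-field inversion produced no valid pixels."""


class EmptyROIError(FluidMREError, ValueError):
    """A region-of-interest mask selects no pixels."""


class UndefinedCriterionError(DomainError):
    """Boundary-stability criterion undefined (e.g. sin(phi_control) = 0)."""


class AmbiguousClassificationError(FluidMREError, ValueError):
    """Growth-pattern type depends on an unresolved redundant input.

    Carries the set of types compatible with the known inputs.
    """

    def __init__(self, message, possible_types):
        super().__init__(message)
        self.possible_types = tuple(sorted(possible_types))


class CannotTestError(FluidMREError, ValueError):
    """Summary statistics insufficient for the requested hypothesis test."""
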