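"""Exception types shared across the package."""


class CantibeatError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CantibeatError, ValueError):
    """An input parameter violates its physical or numerical precondition."""


class SingularModeError(CantibeatError, RuntimeError):
    """A harmonic sits on (or numerically too close to) a clamped-pinned
    resonance, where the prescribed-tip-displacement inversion is ill-posed."""


class ResonanceGuardError(CantibeatError, RuntimeError):
    """Retained harmonics violate the resonance guard band."""


class DegenerateBeatError(CantibeatError, RuntimeError):
    """A beat window never crosses the 20%-of-peak threshold on one side."""


class InstabilityError(CantibeatError, RuntimeError):
    """The forward beam simulation diverged."""


class TrackingError(CantibeatError, RuntimeError):
    """Tip tracking cannot proceed (featureless template, bad frames...)."""
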