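"""Analytic Euler–Bernoulli machinery for a clamped cantilever whose free
end is driven through a prescribed transverse displacement.

The probe is a thin elastic wire (default: a 0.2 mm silver wire) clamped at
``x = 0``; a contracting tissue gel hooked to the free end ``x = L`` drags
the tip through a measured displacement ``s(t)``.  Undamped transverse
motion obeys the Euler–Bernoulli beam equation

    rho * A * y_tt = -E * I * y_xxxx

with clamped-end conditions ``y(0, t) = y'(0, t) = 0`` and, at the free
end, a prescribed displacement ``y(L, t) = s(t)`` together with a vanishing
bending moment ``y''(L, t) = 0`` (the hook transmits force but no moment).

For a single harmonic ``S * cos(omega * t + phi)`` the spatial mode is

    y(x) = C1 * (cosh(k x) - cos(k x)) + C2 * (sinh(k x) - sin(k x))

with wavenumber ``k = (rho * A * omega^2 / (E * I))^(1/4)``.  The clamped-end
conditions are built into the basis; ``C1`` and ``C2`` follow from the two
tip conditions.  The internal shear at the tip, evaluated as
``EI * y'''(L)`` with the sign fixed so the quasi-static limit equals
``+3 EI S / L^3``, is the force the gel applies to the probe at that
harmonic.

Wherever the determinant of the 2x2 tip-condition system vanishes the
inversion is singular; those roots coincide with the clamped-pinned beam
eigenvalues (``tan(kappa) = tanh(kappa)``, ``kappa = k L``) and are guarded
against explicitly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError, SingularModeError

__all__ = [
    "CantileverSpec",
    "ModalCoefficients",
    "section_properties",
    "wavenumber",
    "modal_coefficients",
    "mode_shape",
    "tip_shear_amplitude",
    "resonance_wavenumbers",
    "resonance_frequencies",
    "determinant",
    "silver_wire",
    "SILVER_DENSITY",
    "SILVER_MODULUS",
    "CLAMPED_FREE_EIGENVALUE",
]

#: First eigenvalue of a clamped-free beam, root of cosh(x) cos(x) = -1.
CLAMPED_FREE_EIGENVALUE = 1.8751040687119611

#: Density of the silver probe wire, kg/m^3 (10.5 g/cm^3).
SILVER_DENSITY = 10500.0

#: Elastic modulus of the silver probe wire, Pa (83 GPa).
SILVER_MODULUS = 8.3e10

# Default singularity tolerance: |D| < tol * cosh(kappa) flags resonance.
DEFAULT_SINGULARITY_TOL = 1e-6


def section_properties(d: float) -> tuple[float, float]:
    """Area and second moment of area of a solid circular section.

    Parameters
    ----------
    d : float
        Wire diameter in metres.

    Returns
    -------
    (A, I_sec) : tuple of float
        Cross-sectional area ``pi d^2 / 4`` (m^2) and second moment
        ``pi d^4 / 64`` (m^4).
    """
    if not (d > 0):
        raise ParameterError(f"diameter must be positive, got {d!r}")
    area = math.pi * d * d / 4.0
    i_sec = math.pi * d**4 / 64.0
    return area, i_sec


@dataclass(frozen=True)
class CantileverSpec:
    """Geometry and material of the cantilever probe.

    Parameters
    ----------
    length : float
        Working length L from clamp to gel hook, metres.  This is a
        sample-specific quantity that must be supplied for real data.
    diameter : float
        Wire diameter, metres.
    density : float
        Wire density rho, kg/m^3.
    elastic_modulus : float
        Young's modulus E, Pa.
    """

    length: float
    diameter: float = 2.0e-4
    density: float = SILVER_DENSITY
    elastic_modulus: float = SILVER_MODULUS

    def __post_init__(self) -> None:
        for name in ("length", "diameter", "density", "elastic_modulus"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive and finite, got {v!r}")

    @property
    def area(self) -> float:
        """Cross-sectional area A (m^2)."""
        return section_properties(self.diameter)[0]

    @property
    def second_moment(self) -> float:
        """Second moment of area I (m^4)."""
        return section_properties(self.diameter)[1]

    @property
    def flexural_rigidity(self) -> float:
        """EI (N m^2)."""
        return self.elastic_modulus * self.second_moment

    @property
    def mass_per_length(self) -> float:
        """rho * A (kg/m)."""
        return self.density * self.area

    @property
    def static_stiffness(self) -> float:
        """Tip point-load stiffness 3 EI / L^3 (N/m)."""
        return 3.0 * self.flexural_rigidity / self.length**3

    def wave_speed_factor(self) -> float:
        """sqrt(EI / (rho A)) (m^2/s), the dispersion scale of the beam."""
        return math.sqrt(self.flexural_rigidity / self.mass_per_length)

    def clamped_free_frequency_hz(self) -> float:
        """First natural frequency of the free (unforced) cantilever, Hz."""
        lam = CLAMPED_FREE_EIGENVALUE
        return lam**2 / (2.0 * math.pi) * self.wave_speed_factor() / self.length**2

    def resonance_frequency_hz(self, n: int = 1) -> float:
        """n-th clamped-pinned resonance (inversion singularity), Hz."""
        kappa = resonance_wavenumbers(n)[n - 1]
        return kappa**2 / (2.0 * math.pi) * self.wave_speed_factor() / self.length**2

    # -- JSON interchange ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "length_m": self.length,
            "diameter_m": self.diameter,
            "density_kg_m3": self.density,
            "modulus_pa": self.elastic_modulus,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CantileverSpec":
        return cls(
            length=float(d["length_m"]),
            diameter=float(d.get("diameter_m", 2.0e-4)),
            density=float(d.get("density_kg_m3", SILVER_DENSITY)),
            elastic_modulus=float(d.get("modulus_pa", SILVER_MODULUS)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CantileverSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def silver_wire(length: float = 0.01, diameter: float = 2.0e-4) -> CantileverSpec:
    """A 0.2 mm silver-wire probe.  ``length`` defaults to a nominal 10 mm
    working length; real measurements must supply the actual value."""
    return CantileverSpec(length=length, diameter=diameter)


def wavenumber(omega: float, spec: CantileverSpec) -> float:
    """Flexural wavenumber k = (rho A omega^2 / EI)^(1/4), 1/m.

    Accepts scalars or arrays; ``k(0) = 0``.
    """
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0):
        raise ParameterError("omega must be non-negative")
    k = (spec.mass_per_length * om**2 / spec.flexural_rigidity) ** 0.25
    return float(k) if np.isscalar(omega) else k


def determinant(kappa):
    """Determinant D(kappa) of the two tip boundary conditions.

    D = (cosh k - cos k)(sinh k + sin k) - (cosh k + cos k)(sinh k - sin k),
    which simplifies to 2 (cosh k sin k - cos k sinh k).  Its positive roots
    are the clamped-pinned eigenvalues (tan k = tanh k) where the inversion
    is singular.
    """
    kp = np.asarray(kappa, dtype=float)
    return 2.0 * (np.cosh(kp) * np.sin(kp) - np.cos(kp) * np.sinh(kp))


def _determinant_scaled(kappa):
    """D(kappa) / (2 cosh kappa) — overflow-free for large kappa."""
    kp = np.asarray(kappa, dtype=float)
    return np.sin(kp) - np.cos(kp) * np.tanh(kp)


@dataclass(frozen=True)
class ModalCoefficients:
    """Spatial-mode coefficients for one displacement harmonic.

    The mode is ``y(x) = C1 (cosh kx - cos kx) + C2 (sinh kx - sin kx)``,
    oscillating as ``cos(omega t + phi)`` with tip amplitude S.
    """

    wavenumber: float  # k, 1/m
    amplitude: float  # S, m
    omega: float  # rad/s
    phi: float  # rad
    c1: float  # m
    c2: float  # m
    det: float  # determinant D(kappa), dimensionless
    singular: bool
    kappa: float  # k * L, dimensionless


def modal_coefficients(
    s_j: float,
    omega_j: float,
    phi_j: float,
    spec: CantileverSpec,
    tol: float = DEFAULT_SINGULARITY_TOL,
) -> ModalCoefficients:
    """Solve the two tip conditions for C1, C2 of one harmonic.

    With kappa = k L:

        C1 = S (sinh kappa + sin kappa) / D
        C2 = -S (cosh kappa + cos kappa) / D

    For kappa > 20 the ratios are evaluated with numerator and denominator
    rescaled by cosh(kappa) to avoid overflow.  ``singular`` is set when
    |D| < tol * cosh(kappa) (scale-aware threshold); the coefficients are
    still returned (possibly huge) but downstream force evaluation refuses
    singular modes.
    """
    if not np.isfinite(s_j):
        raise ParameterError("harmonic amplitude must be finite")
    k = wavenumber(omega_j, spec)
    kappa = k * spec.length

    if kappa == 0.0:
        # DC belongs to the static term; treat as the static limit shape.
        return ModalCoefficients(0.0, s_j, omega_j, phi_j, 0.0, 0.0, 0.0, False, 0.0)

    d_scaled = float(_determinant_scaled(kappa))  # D / (2 cosh kappa)
    # D -> 0 as kappa -> 0 is the benign quasi-static limit, not a
    # resonance: the first root of D sits at kappa ~ 3.9266, so the
    # scale-aware test only applies above that neighbourhood.
    singular = kappa > 3.5 and abs(2.0 * d_scaled) < tol

    if singular:
        warnings.warn(
            f"harmonic at omega={omega_j:.6g} rad/s sits near a clamped-pinned "
            f"resonance (kappa={kappa:.6g}); inversion is ill-posed there",
            RuntimeWarning,
            stacklevel=2,
        )
    if kappa <= 20.0:
        ch, sh = math.cosh(kappa), math.sinh(kappa)
        c, s = math.cos(kappa), math.sin(kappa)
        det = 2.0 * (ch * s - c * sh)
        if s_j == 0.0:
            return ModalCoefficients(k, s_j, omega_j, phi_j, 0.0, 0.0, det, singular, kappa)
        c1 = s_j * (sh + s) / det
        c2 = -s_j * (ch + c) / det
    else:
        # cosh-rescaled ratios: th = tanh(kappa), sech = 1/cosh(kappa)
        th = math.tanh(kappa)
        sech = 2.0 * math.exp(-kappa) / (1.0 + math.exp(-2.0 * kappa))
        c, s = math.cos(kappa), math.sin(kappa)
        den = 2.0 * (s - c * th)  # = D / cosh(kappa)
        det = math.inf if kappa > 700 else float(determinant(kappa))
        if s_j == 0.0:
            return ModalCoefficients(k, s_j, omega_j, phi_j, 0.0, 0.0, det, singular, kappa)
        c1 = s_j * (th + s * sech) / den
        c2 = -s_j * (1.0 + c * sech) / den

    if not (np.isfinite(c1) and np.isfinite(c2)):
        raise SingularModeError(
            f"modal coefficients non-finite at omega={omega_j:.6g} rad/s "
            f"(kappa={kappa:.6g}, D={det:.3g}): harmonic is on a resonance"
        )
    return ModalCoefficients(k, s_j, omega_j, phi_j, c1, c2, det, singular, kappa)


def mode_shape(mc: ModalCoefficients, x, deriv: int = 0):
    """Evaluate the spatial mode (or a derivative, up to third) at ``x``.

    deriv 0: C1 (cosh - cos) + C2 (sinh - sin)
    deriv 1: k   [C1 (sinh + sin) + C2 (cosh - cos)]
    deriv 2: k^2 [C1 (cosh + cos) + C2 (sinh + sin)]
    deriv 3: k^3 [C1 (sinh - sin) + C2 (cosh + cos)]
    """
    if deriv not in (0, 1, 2, 3):
        raise ParameterError("deriv must be 0..3")
    xv = np.asarray(x, dtype=float)
    kx = mc.wavenumber * xv
    ch, sh, c, s = np.cosh(kx), np.sinh(kx), np.cos(kx), np.sin(kx)
    if deriv == 0:
        val = mc.c1 * (ch - c) + mc.c2 * (sh - s)
    elif deriv == 1:
        val = mc.c1 * (sh + s) + mc.c2 * (ch - c)
    elif deriv == 2:
        val = mc.c1 * (ch + c) + mc.c2 * (sh + s)
    else:
        val = mc.c1 * (sh - s) + mc.c2 * (ch + c)
    out = val * mc.wavenumber**deriv
    return float(out) if np.isscalar(x) else out


def tip_shear_amplitude(mc: ModalCoefficients, spec: CantileverSpec) -> float:
    """Force amplitude (N) of one harmonic: the internal shear at the hook.

    Evaluates ``EI * d3y/dx3`` at ``x = L`` with the sign convention that a
    displacement toward the gel maps to positive (tensile) force, so the
    quasi-static limit is ``+3 EI S / L^3``.  In closed form,

        amplitude = 2 EI k^3 S (1 + cosh kappa cos kappa) / D(kappa),

    with a series fallback ``3 EI S / L^3 (1 - kappa^4 / 12)`` below
    kappa = 1e-3 where the direct form loses precision.
    """
    if mc.singular:
        raise SingularModeError(
            f"harmonic at omega={mc.omega:.6g} rad/s "
            f"({mc.omega / (2 * math.pi):.6g} Hz) lies on a clamped-pinned "
            f"resonance (kappa={mc.kappa:.6g}); force reconstruction is ill-posed"
        )
    ei = spec.flexural_rigidity
    if mc.amplitude == 0.0:
        return 0.0
    kappa = mc.kappa
    static = 3.0 * ei * mc.amplitude / spec.length**3
    if kappa < 1e-3:
        return static * (1.0 - kappa**4 / 12.0)
    k3 = mc.wavenumber**3
    if kappa <= 20.0:
        num = 2.0 * ei * k3 * mc.amplitude * (1.0 + math.cosh(kappa) * math.cos(kappa))
        return num / float(determinant(kappa))
    sech = 2.0 * math.exp(-kappa) / (1.0 + math.exp(-2.0 * kappa))
    num = 2.0 * ei * k3 * mc.amplitude * (sech + math.cos(kappa))
    den = 2.0 * float(_determinant_scaled(kappa))
    return num / den


def resonance_wavenumbers(n: int = 1) -> np.ndarray:
    """First ``n`` positive roots kappa of D(kappa) = 0, ascending.

    Equivalent to tan(kappa) = tanh(kappa); these are the clamped-pinned
    beam eigenvalues (3.9266, 7.0686, ...), dimensionless in kappa = k L.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    roots = []
    for i in range(1, n + 1):
        lo, hi = i * math.pi + 0.5, i * math.pi + 1.1
        f = _determinant_scaled
        # Safeguard: widen the bracket if the sign change drifted.
        if f(lo) * f(hi) > 0:  # pragma: no cover - analytic bracket holds
            lo, hi = i * math.pi + 1e-6, (i + 1) * math.pi - 1e-6
        roots.append(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))
    return np.asarray(roots)


def resonance_frequencies(spec: CantileverSpec, n: int = 1) -> np.ndarray:
    """First ``n`` clamped-pinned resonance frequencies of ``spec``, Hz."""
    kap = resonance_wavenumbers(n)
    return kap**2 / (2.0 * math.pi) * spec.wave_speed_factor() / spec.length**2
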