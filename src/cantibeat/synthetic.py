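"""Ground-truth generators for validating the force-reconstruction method.

This module provides, as first-class tested code:

* a parametric twitch-force generator with atrial-like and
  ventricular-like kinetic presets,
* an independent finite-difference forward simulator of the beam equation
  (force in, tip displacement out) that shares no modal code with
  :mod:`cantibeat.beam_core` — agreement between forward simulation and the
  analytic inversion is the method's primary verification,
* camera measurement-noise injection (pixel quantisation + Gaussian
  jitter),
* a synthetic video renderer for exercising the tip tracker, and
* the bioreactor stimulus scheduler (coordinated cyclic stretch and
  electrical pulse trains).

Preset twitch time constants are fabricated working values chosen only to
satisfy the atrial/ventricular ordering of the normalised kinetics
(atrial: faster rise and decay, hence larger F'_c and F'_r and smaller
FI'); they are not measured values.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .beam_core import CantileverSpec, silver_wire
from .errors import InstabilityError, ParameterError
from .reconstruction import ForceTrace
from .spectral import DisplacementTrace

__all__ = [
    "TwitchParams",
    "BeamSimConfig",
    "StimulusSchedule",
    "RenderConfig",
    "atrial_preset",
    "ventricular_preset",
    "compliant_wire",
    "twitch_force",
    "twitch_truth_metrics",
    "simulate_cantilever_fd",
    "static_shape",
    "add_measurement_noise",
    "render_frames",
    "stimulus_timeline",
    "describe_timeline",
    "DEFAULT_PIXEL_SCALE",
]

log = logging.getLogger(__name__)

#: Default camera scale, m/px (100x objective, 6.5 um sensor pixels).
DEFAULT_PIXEL_SCALE = 6.5e-8


# -- twitch forces -----------------------------------------------------------


@dataclass(frozen=True)
class TwitchParams:
    """Parametric periodic twitch-force train.

    One pulse per period is the product of a saturating rise and an
    exponential decay (alpha-function family),

        g(u) = (1 - exp(-u / rise_tau))**shape * exp(-u / decay_tau),

    rescaled so the peak equals ``amplitude``.  The two time constants
    control contraction and relaxation kinetics independently, mirroring
    the T_1/T_m/T_2 structure of measured beats.
    """

    amplitude: float = 1.0e-5  # N
    beat_rate: float = 1.0  # Hz
    rise_tau: float = 0.10  # s
    decay_tau: float = 0.18  # s
    shape: float = 2.0  # dimensionless rise exponent
    preset: str = "custom"

    def __post_init__(self) -> None:
        if not (self.amplitude > 0):
            raise ParameterError("amplitude must be positive")
        if not (self.beat_rate > 0):
            raise ParameterError("beat_rate must be positive")
        period = 1.0 / self.beat_rate
        if not (0 < self.rise_tau < period):
            raise ParameterError("rise_tau must lie in (0, 1/beat_rate)")
        if not (self.decay_tau > 0):
            raise ParameterError("decay_tau must be positive")
        if self.peak_time + 4.0 * self.decay_tau > period:
            raise ParameterError(
                "pulse does not relax within the beat period "
                f"(peak at {self.peak_time:.4g} s + 4*decay_tau exceeds {period:.4g} s)"
            )

    @property
    def period(self) -> float:
        return 1.0 / self.beat_rate

    @property
    def peak_time(self) -> float:
        """Time of the pulse maximum within a period (closed form)."""
        return self.rise_tau * math.log(1.0 + self.shape * self.decay_tau / self.rise_tau)

    def _g(self, u) -> np.ndarray:
        """Raw un-normalised pulse kernel, zero for u < 0."""
        u = np.asarray(u, dtype=float)
        with np.errstate(over="ignore"):
            g = (1.0 - np.exp(-u / self.rise_tau)) ** self.shape * np.exp(
                -u / self.decay_tau
            )
        return np.where(u >= 0, g, 0.0)

    def periodic_shape(self, u) -> np.ndarray:
        """Periodic steady-state waveform (peak normalised to 1) at phase
        ``u`` in [0, period).

        The tails of preceding pulses are superposed so the waveform is
        smooth across period boundaries; the diastolic floor is therefore
        slightly positive when relaxation is incomplete within one period.
        """
        u = np.asarray(u, dtype=float)
        total = np.zeros_like(u)
        for k in range(4):  # tails beyond 4 periods are < 1e-6 by validity
            total = total + self._g(u + k * self.period)
        return total / self._periodic_peak

    @functools.cached_property
    def _periodic_peak(self) -> float:
        dense = np.linspace(0.0, self.period, 20_001)
        return float(np.max(sum(self._g(dense + k * self.period) for k in range(4))))


def atrial_preset(amplitude: float = 1.0e-5, beat_rate: float = 1.0) -> TwitchParams:
    """Atrial-like kinetics: fast rise and decay (fabricated working values)."""
    return TwitchParams(
        amplitude=amplitude,
        beat_rate=beat_rate,
        rise_tau=0.04,
        decay_tau=0.06,
        preset="atrial",
    )


def ventricular_preset(amplitude: float = 1.0e-5, beat_rate: float = 1.0) -> TwitchParams:
    """Ventricular-like kinetics: slower rise and decay (fabricated values)."""
    return TwitchParams(
        amplitude=amplitude,
        beat_rate=beat_rate,
        rise_tau=0.10,
        decay_tau=0.18,
        preset="ventricular",
    )


def compliant_wire(length: float = 0.1) -> CantileverSpec:
    """A deliberately long (default 100 mm) silver wire whose first natural
    frequency (~7.9 Hz) sits inside the beating band, for exercising the
    dynamic, non-quasi-static regime of the inversion."""
    return silver_wire(length=length)


def twitch_force(
    params: TwitchParams,
    times,
    ramp_beats: float = 0.0,
) -> ForceTrace:
    """Evaluate the periodic twitch train on a time grid.

    ``ramp_beats > 0`` multiplies the train by a raised-cosine amplitude
    envelope over the first ``ramp_beats`` periods — a soft start that
    avoids exciting the free-vibration transient in forward simulations.
    """
    t = np.asarray(times, dtype=float)
    u = np.mod(t, params.period)
    v = params.amplitude * params.periodic_shape(u)
    if ramp_beats > 0:
        t_ramp = ramp_beats * params.period
        env = np.where(
            t < t_ramp, 0.5 * (1.0 - np.cos(np.pi * np.clip(t, 0, t_ramp) / t_ramp)), 1.0
        )
        v = v * env
    return ForceTrace(
        t,
        v,
        {
            "generator": "twitch",
            "params": {
                "amplitude_N": params.amplitude,
                "beat_rate_hz": params.beat_rate,
                "rise_tau_s": params.rise_tau,
                "decay_tau_s": params.decay_tau,
                "shape": params.shape,
                "preset": params.preset,
            },
            "ramp_beats": ramp_beats,
        },
    )


def twitch_truth_metrics(
    params: TwitchParams, n_dense: int = 200_001, baseline: str = "diastolic"
) -> dict:
    """Generator-truth beat metrics of the noiseless periodic waveform.

    Evaluates one steady-state period on ``n_dense`` points and applies
    the metric definitions directly (same baseline convention as the
    analysis default, so recovery tests compare like with like; the grid
    is fine enough that discretisation is negligible)."""
    from .beat_metrics import beat_parameters

    t = np.linspace(0.0, params.period, n_dense)
    force = ForceTrace(t, params.amplitude * params.periodic_shape(t))
    m = beat_parameters(force, (0, n_dense - 1), baseline=baseline)
    return m.to_dict()


# -- finite-difference forward oracle ---------------------------------------


@dataclass(frozen=True)
class BeamSimConfig:
    """Settings of the finite-difference forward beam simulation.

    The beam equation is discretised in space with second-order central
    differences and ghost nodes enforcing the clamped-end conditions and,
    at the tip, zero moment plus an end shear equal to the applied force.
    Time integration is a Newmark scheme; with ``newmark_gamma`` slightly
    above 1/2 the unconditionally stable average-acceleration method gains
    algorithmic damping of spatial modes the time step cannot resolve, so
    ``dt`` is chosen for accuracy of the forcing band (default: half the
    applied-force grid spacing), not for an explicit stability bound.
    """

    n_elements: int = 50
    dt: float | None = None
    output_fs: float = 60.0
    mass_damping: float = 0.0  # 1/s, velocity-proportional
    stiffness_damping: float = 0.0  # s, damps high modes ~ omega^2
    newmark_gamma: float = 0.55
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_elements < 8:
            raise ParameterError("n_elements must be >= 8")
        if self.dt is not None and not (self.dt > 0):
            raise ParameterError("dt must be positive")


def _beam_matrices(spec: CantileverSpec, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Stiffness matrix K (N/m per unit mass scaling below), tip-force load
    pattern, and grid spacing for DOFs y_1..y_n (y_0 clamped).

    Ghost nodes: y_{-1} = y_1 (clamp slope), y_{n+1} = 2 y_n - y_{n-1}
    (zero tip moment), and the tip third-derivative condition carries the
    applied point force into the last row.
    """
    h = spec.length / n
    s = np.zeros((n, n))
    for i in range(1, n + 1):  # node index; DOF j = i - 1
        r = i - 1
        if i == 1:
            s[r, r] += 7.0
            s[r, r + 1] += -4.0
            s[r, r + 2] += 1.0
        elif i == 2:
            s[r, r - 1] += -4.0
            s[r, r] += 6.0
            s[r, r + 1] += -4.0
            s[r, r + 2] += 1.0
        elif i <= n - 2:
            s[r, r - 2] += 1.0
            s[r, r - 1] += -4.0
            s[r, r] += 6.0
            s[r, r + 1] += -4.0
            s[r, r + 2] += 1.0
        elif i == n - 1:
            s[r, r - 2] += 1.0
            s[r, r - 1] += -4.0
            s[r, r] += 5.0
            s[r, r + 1] += -2.0
        else:  # i == n, tip row after ghost elimination
            s[r, r - 2] += 2.0
            s[r, r - 1] += -4.0
            s[r, r] += 2.0
    k = spec.flexural_rigidity / h**4 * s
    load = np.zeros(n)
    load[-1] = 2.0 / h  # tip point force enters through the shear ghost
    return k, load, h


def static_shape(spec: CantileverSpec, tip_force: float, n_elements: int = 50) -> np.ndarray:
    """Static deflection of all free nodes under a tip point load (m),
    computed from the same discretisation as the forward simulator."""
    k, load, _ = _beam_matrices(spec, n_elements)
    return np.linalg.solve(k, load * tip_force)


def simulate_cantilever_fd(
    applied_force: ForceTrace,
    spec: CantileverSpec,
    cfg: BeamSimConfig | None = None,
    initial_displacement: np.ndarray | None = None,
) -> DisplacementTrace:
    """Forward-simulate the beam driven by a tip force; return the tip
    displacement sampled at ``cfg.output_fs``.

    ``initial_displacement`` optionally sets the starting nodal deflection
    (free DOFs, length ``n_elements``), e.g. a bent shape for free-vibration
    studies.  Energy-balance diagnostics are attached to the returned
    trace's ``meta``.
    """
    cfg = cfg or BeamSimConfig()
    n = cfg.n_elements
    k_mat, load, h = _beam_matrices(spec, n)
    rho_a = spec.mass_per_length
    m_diag = np.full(n, rho_a)  # per-unit-length mass; equations are in
    # PDE form rho*A*y_tt = -(EI) y_xxxx + q, so "mass" is rho*A per node

    force_dt = applied_force.dt if len(applied_force) >= 2 else 1.0 / cfg.output_fs
    dt = cfg.dt if cfg.dt is not None else force_dt / 2.0
    duration = float(applied_force.times[-1] - applied_force.times[0])
    n_steps = int(round(duration / dt))
    t0 = float(applied_force.times[0])

    gam = cfg.newmark_gamma
    beta = 0.25 * (gam + 0.5) ** 2

    c_mat = cfg.mass_damping * np.diag(m_diag) + cfg.stiffness_damping * k_mat

    a_eff = np.diag(m_diag) + gam * dt * c_mat + beta * dt * dt * k_mat
    lu = lu_factor(a_eff)

    sim_t = t0 + dt * np.arange(n_steps + 1)
    f_tip = np.interp(sim_t, applied_force.times, applied_force.values)

    y = np.zeros(n) if initial_displacement is None else np.array(initial_displacement, dtype=float)
    if y.shape != (n,):
        raise ParameterError(f"initial_displacement must have shape ({n},)")
    v = np.zeros(n)
    rhs0 = load * f_tip[0] - c_mat @ v - k_mat @ y
    a = rhs0 / m_diag

    scale = (
        np.max(np.abs(f_tip)) / spec.static_stiffness
        + np.max(np.abs(y))
        + 1e-30
    )
    tip_series = np.empty(n_steps + 1)
    tip_series[0] = y[-1]
    work = 0.0
    check_every = max(1, n_steps // 50)
    for step in range(1, n_steps + 1):
        y_pred = y + dt * v + dt * dt * (0.5 - beta) * a
        v_pred = v + dt * (1.0 - gam) * a
        rhs = load * f_tip[step] - c_mat @ v_pred - k_mat @ y_pred
        a = lu_solve(lu, rhs)
        y = y_pred + beta * dt * dt * a
        v = v_pred + gam * dt * a
        tip_series[step] = y[-1]
        work += f_tip[step] * v[-1] * dt  # point-force work at the tip
        if step % check_every == 0 and np.max(np.abs(y)) > 1e4 * scale:
            raise InstabilityError(
                f"simulated displacement exceeded {1e4:.0e} x the static scale "
                f"at t={sim_t[step]:.4g} s; reduce dt or check the forcing"
            )

    kinetic = 0.5 * rho_a * h * float(v @ v)
    strain = 0.5 * h * float(y @ (k_mat @ y))
    diagnostics = {
        "dt": dt,
        "n_elements": n,
        "newmark_gamma": gam,
        "mass_damping": cfg.mass_damping,
        "stiffness_damping": cfg.stiffness_damping,
        "seed": cfg.seed,
        "energy": {
            "work_in_J": work,
            "kinetic_J": kinetic,
            "strain_J": strain,
        },
    }

    out_dt = 1.0 / cfg.output_fs
    n_out = int(math.floor(duration / out_dt)) + 1
    out_t = t0 + out_dt * np.arange(n_out)
    out_v = np.interp(out_t, sim_t, tip_series)
    return DisplacementTrace(out_t, out_v, meta=diagnostics)


# -- measurement noise -------------------------------------------------------


def add_measurement_noise(
    trace: DisplacementTrace,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    sigma_px: float = 0.5,
    seed: int | None = None,
) -> DisplacementTrace:
    """Camera measurement model: zero-mean Gaussian jitter of ``sigma_px``
    pixels followed by quantisation to the pixel grid.

    The jitter (sensor/shot noise reaching the tracker) acts *before* the
    grid rounds the reading: with dither at or above half a pixel the
    quantisation error is whitened.  Rounding a noise-free periodic signal
    first would instead imprint the deterministic pixel staircase — and
    its strong in-band harmonics — onto every beat."""
    if not (pixel_scale > 0):
        raise ParameterError("pixel_scale must be positive")
    rng = np.random.default_rng(seed)
    jittered = trace.values + rng.normal(
        0.0, sigma_px * pixel_scale, size=trace.values.shape
    )
    noisy = np.round(jittered / pixel_scale) * pixel_scale
    meta = dict(trace.meta)
    meta["measurement_noise"] = {
        "pixel_scale_m_per_px": pixel_scale,
        "sigma_px": sigma_px,
        "seed": seed,
    }
    return DisplacementTrace(trace.times, noisy, pixel_scale, meta)


# -- synthetic video ---------------------------------------------------------


@dataclass(frozen=True)
class RenderConfig:
    """Synthetic microscope-frame rendering settings (8-bit grayscale)."""

    height: int = 120
    width: int = 160
    pixel_scale: float = DEFAULT_PIXEL_SCALE  # m/px
    background: int = 200
    foreground: int = 40
    wire_sigma_px: float = 1.8
    tip_radius_px: float = 3.0
    tip_x_frac: float = 0.7  # horizontal position of the hook
    y0_frac: float = 0.5  # resting vertical position of the hook


def render_frames(
    trace: DisplacementTrace, cfg: RenderConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render a dark wire-plus-hook whose tip follows the trace vertically.

    Returns ``(frames, truth)``: a ``(T, H, W)`` uint8 stack and the
    ground-truth sub-pixel tip row coordinate per frame.
    """
    cfg = cfg or RenderConfig()
    h, w = cfg.height, cfg.width
    tip_x = cfg.tip_x_frac * (w - 1)
    y0 = cfg.y0_frac * (h - 1)
    disp_px = trace.values / cfg.pixel_scale
    truth = y0 + disp_px

    if np.any(truth < 4) or np.any(truth > h - 5):
        raise ParameterError("tip leaves the rendered frame; enlarge it or rescale")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    depth = cfg.background - cfg.foreground
    frames = np.empty((len(trace), h, w), dtype=np.uint8)
    wire_end = tip_x - 3.0 * cfg.tip_radius_px  # hook protrudes past the wire
    for i, y_tip in enumerate(truth):
        # wire: straight segment pivoting about the clamp-side edge
        y_line = y0 + (y_tip - y0) * np.clip(xx / max(tip_x, 1.0), 0.0, 1.0)
        d_wire = np.where(xx <= wire_end, np.abs(yy - y_line), np.inf)
        img = cfg.background - 0.6 * depth * np.exp(
            -(d_wire**2) / (2 * cfg.wire_sigma_px**2)
        )
        # hook: round blob at the tip, the darkest feature in the frame
        d2 = (yy - y_tip) ** 2 + (xx - tip_x) ** 2
        img -= depth * np.exp(-d2 / (2 * cfg.tip_radius_px**2))
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames, truth


# -- bioreactor stimulus timelines -------------------------------------------


@dataclass(frozen=True)
class StimulusSchedule:
    """Coordinated cyclic-stretch / electrical-pulse schedule.

    One motor rotation drives one stretch cycle and triggers one electrical
    pulse, so stretch frequency, pulse frequency and their periods are all
    locked to the motor rate ``gamma`` (rotations/s): ``f_m = f_e = gamma``
    and ``P_s = P_e = 1/gamma``.
    """

    motor_rate: float = 1.0  # gamma, rotations/s
    stretch_width: float | None = None  # tau, s (default 0.5 * P_s)
    max_strain: float = 0.05  # epsilon_m, dimensionless
    pulse_amplitude_mv: float = 100.0  # E_m
    pulse_width_ms: float = 1.0  # upsilon
    phase_ms: float = 0.0  # delta, pulse delay after stretch onset

    def __post_init__(self) -> None:
        if not (self.motor_rate > 0):
            raise ParameterError("motor_rate must be positive")
        tau = self.stretch_width if self.stretch_width is not None else 0.5 * self.period_s
        if not (0 < tau <= self.period_s):
            raise ParameterError("stretch_width must lie in (0, P_s]")
        object.__setattr__(self, "stretch_width", tau)
        if not (0 <= self.phase_ms < self.period_s * 1e3):
            raise ParameterError("phase must satisfy 0 <= delta < P_s")
        if not (0 < self.pulse_width_ms <= self.period_s * 1e3):
            raise ParameterError("pulse width must satisfy 0 < upsilon <= P_e")

    @property
    def stretch_frequency_hz(self) -> float:
        return self.motor_rate

    @property
    def period_s(self) -> float:
        return 1.0 / self.motor_rate

    @property
    def pulse_period_s(self) -> float:
        return self.period_s

    @property
    def pulse_frequency_hz(self) -> float:
        return self.motor_rate


def stimulus_timeline(
    sched: StimulusSchedule, duration: float, sample_rate: float = 10_000.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled stretch-strain and electrical-pulse waveforms.

    Strain is a half-sine pulse of width ``tau`` and peak ``epsilon_m``
    once per cycle; the electrical waveform is a rectangular pulse of
    amplitude ``E_m`` (mV) and width ``upsilon`` (ms), delayed ``delta``
    (ms) from each stretch onset.  Returns ``(times, strain, pulse_mV)``.
    """
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    phase = np.mod(t, sched.period_s)
    tau = sched.stretch_width
    strain = np.where(
        phase < tau, sched.max_strain * np.sin(np.pi * phase / tau), 0.0
    )
    on = sched.phase_ms * 1e-3
    off = on + sched.pulse_width_ms * 1e-3
    pulse = np.where((phase >= on) & (phase < off), sched.pulse_amplitude_mv, 0.0)
    return t, strain, pulse


def describe_timeline(
    times: np.ndarray, strain: np.ndarray, pulse: np.ndarray
) -> dict:
    """Waveform inspection: event counts, peaks and measured widths."""
    dt = float(times[1] - times[0])
    strain_on = strain > 0
    pulse_on = pulse > 0
    n_strain = int(np.count_nonzero(np.diff(strain_on.astype(int)) == 1) + strain_on[0])
    n_pulse = int(np.count_nonzero(np.diff(pulse_on.astype(int)) == 1) + pulse_on[0])
    return {
        "duration_s": dt * len(times),
        "n_stretch_events": n_strain,
        "n_pulse_events": n_pulse,
        "strain_peak": float(np.max(strain)) if len(strain) else 0.0,
        "pulse_amplitude_mV": float(np.max(pulse)) if len(pulse) else 0.0,
        "pulse_width_ms": float(np.count_nonzero(pulse_on) * dt * 1e3 / max(n_pulse, 1)),
        "stretch_width_s": float(np.count_nonzero(strain_on) * dt / max(n_strain, 1)),
    }
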