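"""Real Fourier-series decomposition of a sampled tip-displacement record.

A near-periodic beating record ``s(t)`` sampled on a uniform grid is
represented as the truncated real series

    s(t) = S0/2 + sum_j S_j cos(omega_j t + phi_j),

with ``omega_j = 2 pi j / T_rec`` harmonics of the analysed record length.
The DC term ``S0/2`` carries the static pre-stretch offset of the probe and
is deliberately *not* detrended: displacement must be supplied relative to
the unloaded cantilever position.

To suppress spectral leakage the record is, by default, truncated to an
integer number of beat periods before the DFT (the beat period is estimated
from the autocorrelation of the record); the beating signals this package
targets are near-periodic, so a whole-record Fourier series over an integer
number of beats is the natural representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "DisplacementTrace",
    "SpectralDecomposition",
    "decompose",
    "reconstruct",
    "read_trace_csv",
    "write_trace_csv",
]

log = logging.getLogger(__name__)

#: Default camera frame rate, Hz.
DEFAULT_FPS = 60.0


def _check_uniform(times: np.ndarray) -> float:
    if times.ndim != 1 or times.size < 2:
        raise ParameterError("times must be a 1-D array with >= 2 samples")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ParameterError("times must be strictly increasing")
    step = float(np.mean(dt))
    if np.max(np.abs(dt - step)) > 1e-9 * max(step, 1.0) + 1e-12:
        raise ParameterError("times must be uniformly spaced (1e-9 relative)")
    return step


@dataclass(frozen=True)
class DisplacementTrace:
    """Uniformly sampled tip displacement, SI metres.

    ``pixel_scale`` (m/px) is optional provenance recording how pixel
    measurements were converted; ``meta`` carries generator/simulator
    provenance for synthetic traces.
    """

    times: np.ndarray
    values: np.ndarray
    pixel_scale: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if values.shape != times.shape:
            raise ParameterError("times and values must have the same shape")
        _check_uniform(times)
        if not np.all(np.isfinite(values)):
            raise ParameterError("displacement values must be finite")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def fs(self) -> float:
        """Sample rate, Hz (1/dt by construction)."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Record length counted in sample intervals, seconds."""
        return self.dt * len(self.times)

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_samples(
        cls,
        values,
        fs: float = DEFAULT_FPS,
        t0: float = 0.0,
        pixel_scale: float | None = None,
        meta: dict | None = None,
    ) -> "DisplacementTrace":
        values = np.asarray(values, dtype=float)
        times = t0 + np.arange(values.size) / float(fs)
        return cls(times, values, pixel_scale, meta or {})


@dataclass(frozen=True)
class SpectralDecomposition:
    """Truncated real Fourier series of a displacement record.

    The constant offset of the series is ``S0/2``; each harmonic ``j`` has
    amplitude ``S_j >= 0`` (m), angular frequency ``omega_j`` (rad/s) and
    phase ``phi_j`` (rad), referenced to absolute time ``t = 0``.
    """

    s0: float
    amplitudes: np.ndarray
    omegas: np.ndarray
    phases: np.ndarray
    record_duration: float
    dropped_energy_fraction: float = 0.0
    n_samples: int = 0

    def __post_init__(self) -> None:
        for name in ("amplitudes", "omegas", "phases"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.amplitudes < 0):
            raise ParameterError("harmonic amplitudes must be non-negative")
        if np.any(np.diff(self.omegas) <= 0):
            raise ParameterError("harmonic frequencies must be strictly increasing")

    @property
    def n_harmonics(self) -> int:
        return int(self.amplitudes.size)

    def harmonics(self):
        """Iterate (S_j, omega_j, phi_j) triples."""
        yield from zip(self.amplitudes, self.omegas, self.phases)


def _estimate_period_samples(values: np.ndarray) -> float | None:
    """Dominant period of a near-periodic record, in (fractional) samples.

    The fundamental is located as the dominant non-DC DFT bin and refined
    to sub-bin accuracy with Jacobsen's three-bin estimator, which is exact
    when the record already spans an integer number of periods."""
    x = values - values.mean()
    n = x.size
    scale = float(np.max(np.abs(x))) if n else 0.0
    if scale == 0.0:
        return None
    spec = np.fft.rfft(x)
    mag = np.abs(spec)
    if mag.size < 3:
        return None
    k = int(np.argmax(mag[1:])) + 1
    if mag[k] <= 1e-12 * n * scale:
        return None
    delta = 0.0
    if 1 <= k < mag.size - 1:
        denom = 2.0 * spec[k] - spec[k - 1] - spec[k + 1]
        if abs(denom) > 0:
            delta = float(-np.real((spec[k + 1] - spec[k - 1]) / denom))
            delta = min(0.5, max(-0.5, delta))
    freq_bins = k + delta  # cycles per record
    if freq_bins <= 0:
        return None
    return n / freq_bins


def decompose(
    trace: DisplacementTrace,
    max_harmonics: int | None = 25,
    amp_floor: float = 1e-3,
    window: str | None = "integer_period",
    max_freq_hz: float | None = None,
    denoise: bool = True,
) -> SpectralDecomposition:
    """Discrete real-Fourier decomposition of a displacement record.

    Parameters
    ----------
    trace : DisplacementTrace
        At least 4 samples.
    max_harmonics : int or None
        Keep harmonics up to this multiple of the *beat* fundamental
        (None: everything below the Nyquist bin).  When no beat period can
        be detected the record fundamental is the unit instead.
    amp_floor : float
        Harmonics with ``S_j < amp_floor * max_j S_j`` are dropped; the
        dropped-energy fraction is reported on the result.
    window : "integer_period" or None
        Truncate the record to an integer number of estimated beat periods
        before the DFT, to suppress leakage.
    max_freq_hz : float or None
        Additionally drop all harmonics at or above this frequency with a
        logged warning (resonance guard hook for the reconstruction layer).
    denoise : bool
        In integer-period (comb) mode, estimate the white measurement-noise
        power per bin from the off-comb bins — which carry no periodic
        signal — and subtract it from the comb amplitudes in the power
        domain (spectral subtraction).  Exact no-op on noiseless records.
    """
    if len(trace) < 4:
        raise ParameterError("record must contain at least 4 samples")
    values = trace.values
    n = values.size
    p = _estimate_period_samples(values)
    beats_in_record = 1
    if window == "integer_period":
        if p is not None and p < n:
            n_beats = int(n // p)
            n_keep = int(round(n_beats * p))
            if 4 <= n_keep <= n:
                values = values[:n_keep]
                n = n_keep
                beats_in_record = n_beats
    elif window is None:
        if p is not None and p < n:
            beats_in_record = max(1, int(round(n / p)))
    else:
        raise ParameterError(f"unknown window mode {window!r}")

    dt = trace.dt
    t_rec = n * dt
    nyq_index = (n - 1) // 2  # exclude the ambiguous Nyquist bin for even n
    if max_harmonics is None:
        max_bin = nyq_index
    else:
        # the cap counts harmonics of the beat: an m-beat record carries
        # beat harmonic q at DFT bin q*m
        max_bin = min(nyq_index, max_harmonics * beats_in_record)

    spec = np.fft.rfft(values)
    s0 = 2.0 * float(spec[0].real) / n
    j = np.arange(1, nyq_index + 1)
    coef = 2.0 * spec[1 : nyq_index + 1] / n
    amps_all = np.abs(coef)
    total_var = float(np.var(values))
    # phase referenced to absolute t: fold the start time into phi
    omegas_all = 2.0 * np.pi * j / t_rec
    phases_all = np.angle(coef) - omegas_all * trace.times[0]

    if denoise and window == "integer_period" and beats_in_record > 1:
        offcomb = j % beats_in_record != 0
        if np.count_nonzero(offcomb) >= 16:
            # off-comb amplitudes of white noise are Rayleigh; the median
            # of their power estimates the mean bin noise power robustly
            nf2 = float(np.median(amps_all[offcomb] ** 2)) / math.log(2.0)
            amps_all = np.sqrt(np.maximum(amps_all**2 - nf2, 0.0))

    # absolute floor: harmonics at double-precision rounding level relative
    # to the record scale are artefacts of the DFT, not signal
    scale = float(np.max(np.abs(values))) if n else 0.0
    keep = (j <= max_bin) & (amps_all > 1e-12 * scale)
    if window == "integer_period" and beats_in_record > 1:
        # the series models the *periodic* beat, whose harmonics sit at
        # multiples of the beat fundamental (bin = n_beats); off-comb bins
        # carry noise and beat-to-beat variability and are excluded here
        # (synchronous averaging over the analysed beats) — use window=None
        # to keep the full spectrum
        keep &= j % beats_in_record == 0
    if amps_all.size and amps_all.max() > 0:
        keep &= amps_all >= amp_floor * amps_all.max()
    if max_freq_hz is not None:
        guard = omegas_all / (2.0 * np.pi) < max_freq_hz
        n_guarded = int(np.count_nonzero(keep & ~guard))
        if n_guarded:
            log.warning(
                "dropping %d harmonic(s) at or above %.6g Hz (resonance guard)",
                n_guarded,
                max_freq_hz,
            )
        keep &= guard

    retained_power = float(np.sum(amps_all[keep] ** 2) / 2.0)
    dropped = 0.0 if total_var == 0 else max(0.0, 1.0 - retained_power / total_var)

    return SpectralDecomposition(
        s0=s0,
        amplitudes=amps_all[keep],
        omegas=omegas_all[keep],
        phases=phases_all[keep],
        record_duration=t_rec,
        dropped_energy_fraction=dropped,
        n_samples=n,
    )


def reconstruct(decomp: SpectralDecomposition, times) -> np.ndarray:
    """Evaluate ``S0/2 + sum_j S_j cos(omega_j t + phi_j)`` at ``times``."""
    t = np.asarray(times, dtype=float)
    out = np.full(t.shape, decomp.s0 / 2.0)
    for s_j, om_j, ph_j in decomp.harmonics():
        out += s_j * np.cos(om_j * t + ph_j)
    return out


# -- CSV interchange ---------------------------------------------------------


def read_trace_csv(path: str | Path, pixel_scale: float | None = None) -> DisplacementTrace:
    """Read a trace CSV with columns ``time_s`` and either ``displacement_m``
    or ``displacement_px`` (the latter requires ``pixel_scale`` in m/px)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ParameterError(f"{path}: missing required column 'time_s'")
    if "displacement_m" in df.columns:
        values = df["displacement_m"].to_numpy(dtype=float)
        scale = pixel_scale
    elif "displacement_px" in df.columns:
        if pixel_scale is None:
            raise ParameterError(
                f"{path}: column 'displacement_px' requires a pixel scale (m/px)"
            )
        values = df["displacement_px"].to_numpy(dtype=float) * pixel_scale
        scale = pixel_scale
    else:
        raise ParameterError(
            f"{path}: need a 'displacement_m' or 'displacement_px' column"
        )
    return DisplacementTrace(df["time_s"].to_numpy(dtype=float), values, scale)


def write_trace_csv(trace: DisplacementTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "displacement_m": trace.values}).to_csv(
        path, index=False, float_format="%.12e"
    )
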