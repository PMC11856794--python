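"""Sub-pixel tip tracking from microscope (or synthetic) frame stacks.

The gel drags the probe hook along one axis, so tracking is 1-D: a
reference patch around the tip is taken from frame 0 (a fixed reference
avoids drift accumulation on periodic motion) and matched in every frame
by normalised cross-correlation over integer shifts along the motion axis,
followed by parabolic interpolation of the correlation peak for sub-pixel
resolution.  The peak correlation value doubles as a per-frame confidence
score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, TrackingError
from .spectral import DisplacementTrace

__all__ = ["TemplateConfig", "TrackingResult", "track_tip", "read_stack", "write_stack"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemplateConfig:
    """Template-matching settings.

    half_size : patch half-width in px; search_radius : max shift in px;
    min_confidence : frames whose peak normalised correlation falls below
    this are flagged (and interpolated over when converting to a trace);
    variance_floor : minimum template variance (featureless guard).
    """

    half_size: int = 10
    search_radius: int = 20
    min_confidence: float = 0.5
    variance_floor: float = 1.0


@dataclass(frozen=True)
class TrackingResult:
    """Per-frame tip position along the tracked axis (px, sub-pixel)."""

    positions_px: np.ndarray
    confidence: np.ndarray
    axis: str
    reference_center: tuple[int, int]  # (row, col) of the template centre

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions_px", np.asarray(self.positions_px, dtype=float))
        object.__setattr__(self, "confidence", np.asarray(self.confidence, dtype=float))
        if self.positions_px.shape != self.confidence.shape:
            raise ParameterError("positions and confidence must align")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ParameterError("confidence must lie in [0, 1]")

    def to_trace(
        self,
        fs: float,
        pixel_scale: float,
        min_confidence: float = 0.5,
        origin_px: float | None = None,
    ) -> DisplacementTrace:
        """Convert to a displacement trace (m, relative to ``origin_px``;
        default: the first confident frame).  Low-confidence frames are
        linearly interpolated from confident neighbours with a warning."""
        pos = self.positions_px.copy()
        good = self.confidence >= min_confidence
        if not np.any(good):
            raise TrackingError("no frame reaches the confidence threshold")
        if not np.all(good):
            warnings.warn(
                f"interpolating over {int(np.count_nonzero(~good))} "
                "low-confidence frame(s)",
                stacklevel=2,
            )
            idx = np.arange(pos.size)
            pos[~good] = np.interp(idx[~good], idx[good], pos[good])
        if origin_px is None:
            origin_px = pos[int(np.argmax(good))]
        values = (pos - origin_px) * pixel_scale
        return DisplacementTrace.from_samples(values, fs=fs, pixel_scale=pixel_scale)


def _locate_tip(frame0: np.ndarray) -> tuple[int, int]:
    """Darkest feature after light smoothing = the hook blob."""
    sm = gaussian_filter(frame0.astype(float), 1.0)
    r, c = np.unravel_index(np.argmin(sm), sm.shape)
    return int(r), int(c)


def track_tip(
    frames,
    axis: str = "y",
    cfg: TemplateConfig | None = None,
) -> TrackingResult:
    """Track the tip through an image stack along one axis.

    Parameters
    ----------
    frames : (T, H, W) array-like
        At least 2 frames of identical size.
    axis : "y" or "x"
        Image axis of the motion (rows or columns).
    """
    cfg = cfg or TemplateConfig()
    stack = np.asarray(frames)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise TrackingError("need a (T, H, W) stack with at least 2 frames")
    if axis not in ("y", "x"):
        raise ParameterError("axis must be 'y' or 'x'")
    if axis == "x":
        stack = np.swapaxes(stack, 1, 2)
    t_n, h, w = stack.shape

    r0, c0 = _locate_tip(stack[0])
    hs = cfg.half_size
    # clamp the template inside the frame, leaving room for the search
    r0 = int(np.clip(r0, hs + cfg.search_radius, h - 1 - hs - cfg.search_radius))
    c0 = int(np.clip(c0, hs, w - 1 - hs))
    template = stack[0, r0 - hs : r0 + hs + 1, c0 - hs : c0 + hs + 1].astype(float)
    template = template - template.mean()
    t_norm = float(np.sqrt(np.sum(template**2)))
    if template.var() < cfg.variance_floor:
        raise TrackingError(
            "reference patch is featureless (variance below floor); "
            "check illumination or template placement"
        )

    shifts = np.arange(-cfg.search_radius, cfg.search_radius + 1)
    positions = np.empty(t_n)
    confidence = np.empty(t_n)
    for i in range(t_n):
        frame = stack[i].astype(float)
        if frame.shape != (h, w):
            raise TrackingError(f"frame {i} size differs from frame 0")
        ncc = np.empty(shifts.size)
        for si, s in enumerate(shifts):
            win = frame[r0 - hs + s : r0 + hs + 1 + s, c0 - hs : c0 + hs + 1]
            win = win - win.mean()
            denom = t_norm * float(np.sqrt(np.sum(win**2)))
            ncc[si] = float(np.sum(template * win)) / denom if denom > 0 else 0.0
        best = int(np.argmax(ncc))
        frac = 0.0
        if 0 < best < ncc.size - 1:
            denom = ncc[best - 1] - 2.0 * ncc[best] + ncc[best + 1]
            if denom < 0:
                frac = 0.5 * (ncc[best - 1] - ncc[best + 1]) / denom
        positions[i] = r0 + shifts[best] + frac
        confidence[i] = float(np.clip(ncc[best], 0.0, 1.0))
        if confidence[i] < cfg.min_confidence:
            log.warning("frame %d: low tracking confidence %.3f", i, confidence[i])

    return TrackingResult(positions, confidence, axis, (r0, c0))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a TIFF (multi-page) or PNG stack as a (T, H, W) array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        stack = tifffile.imread(path)
    else:
        from PIL import Image

        stack = np.asarray(Image.open(path))
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(frames: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(frames))
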