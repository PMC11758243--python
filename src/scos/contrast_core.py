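"""Noise-corrected speckle contrast and the cerebral blood flow index.

The processing chain converts each camera frame of a speckle recording into a
single squared spatial contrast value

    K_raw^2 = sigma^2(I) / mu^2(I)

(population variance over the analyzed pixels), subtracts the sensor-noise
contributions

    K_adj^2 = K_raw^2 - K_shot^2 - K_quant^2 - K_cam^2

and reports the blood flow index CBFI = 1 / K_adj^2, optionally normalized to
its mean over a baseline window.  The noise terms use the standard
camera-calibration forms, all expressed in digital numbers (DN):

    K_shot^2  = 1 / (g * mu)      shot noise, g = conversion gain [e-/DN]
    K_quant^2 = (1/12) / mu^2     uniform quantization, 1-DN step
    K_cam^2   = sigma_r^2 / mu^2  read + dark noise, sigma_r in DN

Frames whose corrected contrast is non-positive (noise subtraction exceeding
the measured variance) are flagged invalid and excluded downstream rather than
clamped: 1/K^2 would otherwise blow up on what is pure noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import BaselineError, DegenerateInputError

log = logging.getLogger(__name__)

__all__ = [
    "CameraModel",
    "FrameStack",
    "ContrastTrace",
    "FlowTrace",
    "compute_raw_contrast",
    "compute_noise_contrasts",
    "adjust_contrast",
    "compute_cbfi",
    "process_stack",
    "DEFAULT_BASELINE_WINDOW",
]

#: Baseline window (seconds) used for CBFI normalization and the blood-volume
#: baseline intensity I0 when the caller does not specify one.
DEFAULT_BASELINE_WINDOW: Tuple[float, float] = (0.0, 5.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Sensor parameters that determine the three noise-contrast terms.

    Parameters
    ----------
    gain_e_per_dn
        Conversion gain in electrons per digital number (DN).
    read_noise_dn
        Combined read + dark noise standard deviation, in DN.
    bit_depth
        Bits per pixel; the saturation level is ``2**bit_depth - 1`` DN.
    """

    gain_e_per_dn: float
    read_noise_dn: float = 0.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not self.gain_e_per_dn > 0:
            raise ValueError(f"gain_e_per_dn must be > 0, got {self.gain_e_per_dn}")
        if self.read_noise_dn < 0:
            raise ValueError(f"read_noise_dn must be >= 0, got {self.read_noise_dn}")
        if not (1 <= int(self.bit_depth) <= 32):
            raise ValueError(f"bit_depth must be in [1, 32], got {self.bit_depth}")

    @property
    def max_dn(self) -> int:
        """Saturation level in DN (``2**bit_depth - 1``)."""
        return 2 ** int(self.bit_depth) - 1

    def to_dict(self) -> dict:
        return {
            "gain_e_per_dn": self.gain_e_per_dn,
            "read_noise_dn": self.read_noise_dn,
            "bit_depth": int(self.bit_depth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            gain_e_per_dn=float(d["gain_e_per_dn"]),
            read_noise_dn=float(d.get("read_noise_dn", 0.0)),
            bit_depth=int(d.get("bit_depth", 8)),
        )


@dataclass
class FrameStack:
    """A time-ordered sequence of 2-D intensity frames from one channel.

    ``frames`` has shape ``(n_frames, rows, cols)`` in DN.  Timestamps are
    derived from the frame index and the (fixed) frame rate.
    """

    frames: np.ndarray
    frame_rate: float
    exposure_T: float
    channel_id: str = "ch0"
    camera: Optional[CameraModel] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(
                f"frames must be a (n, rows, cols) array with n >= 1, got shape {self.frames.shape}"
            )
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not self.exposure_T > 0:
            raise ValueError(f"exposure_T must be > 0, got {self.exposure_T}")
        if self.exposure_T > 1.0 / self.frame_rate + 1e-12:
            raise ValueError("exposure_T cannot exceed the frame period 1/frame_rate")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ValueError("mask shape must match the frame shape")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds (frame_index / frame_rate)."""
        return np.arange(self.n_frames, dtype=float) / self.frame_rate

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate


@dataclass
class ContrastTrace:
    """Per-frame squared contrasts: raw, the three noise terms, and corrected."""

    time_s: np.ndarray
    k_raw_sq: np.ndarray
    k_shot_sq: np.ndarray
    k_quant_sq: np.ndarray
    k_cam_sq: np.ndarray
    k_adj_sq: np.ndarray
    valid: np.ndarray
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("k_raw_sq", "k_shot_sq", "k_quant_sq", "k_cam_sq", "k_adj_sq", "valid"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have the same length as time_s")
            setattr(self, name, arr)
        self.valid = self.valid.astype(bool)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class FlowTrace:
    """Blood flow index trace: CBFI = 1/K_adj^2 and its baseline-normalized form."""

    time_s: np.ndarray
    cbfi: np.ndarray
    cbfi_normalized: np.ndarray
    valid: np.ndarray
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE_WINDOW
    channel_id: str = "ch0"

    def __len__(self) -> int:
        return len(self.time_s)


# ---------------------------------------------------------------------------
# Per-frame operations
# ---------------------------------------------------------------------------

def _masked_pixels(frame: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.size == 0:
        raise DegenerateInputError("empty frame")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != frame.shape:
            raise ValueError("mask shape must match frame shape")
        px = frame[mask]
    else:
        px = frame.ravel()
    if px.size == 0:
        raise DegenerateInputError("mask excludes every pixel")
    return px.astype(np.float64, copy=False)


def compute_raw_contrast(frame: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Squared spatial speckle contrast sigma^2(I)/mu^2(I) of one frame.

    Uses the population variance (divide by N) over the masked pixels; with
    whole-frame statistics (>=10^4 pixels) the sample/population distinction is
    negligible and the population form matches the moment definition.
    """
    px = _masked_pixels(frame, mask)
    mu = px.mean()
    if not mu > 0:
        raise DegenerateInputError(f"mean intensity must be > 0, got {mu}")
    return float(px.var() / mu ** 2)


def compute_noise_contrasts(
    frame: np.ndarray, camera: CameraModel, mask: Optional[np.ndarray] = None
) -> Tuple[float, float, float]:
    """Shot, quantization and read/dark noise contrast contributions of one frame.

    Returns ``(k_shot_sq, k_quant_sq, k_cam_sq)`` evaluated at the frame's mean
    intensity over the mask.
    """
    px = _masked_pixels(frame, mask)
    mu = px.mean()
    if not mu > 0:
        raise DegenerateInputError(f"mean intensity must be > 0, got {mu}")
    k_shot = 1.0 / (camera.gain_e_per_dn * mu)
    k_quant = (1.0 / 12.0) / mu ** 2
    k_cam = camera.read_noise_dn ** 2 / mu ** 2
    return float(k_shot), float(k_quant), float(k_cam)


def adjust_contrast(k_raw_sq, k_shot_sq, k_quant_sq, k_cam_sq):
    """Noise-corrected contrast ``K_adj^2 = K_raw^2 - K_shot^2 - K_quant^2 - K_cam^2``.

    Works on scalars or arrays.  Returns ``(k_adj_sq, valid)`` where ``valid``
    is False wherever the subtraction is non-positive; such samples must be
    excluded downstream (never clamped).
    """
    parts = [np.asarray(a, dtype=float) for a in (k_raw_sq, k_shot_sq, k_quant_sq, k_cam_sq)]
    for name, a in zip(("k_raw_sq", "k_shot_sq", "k_quant_sq", "k_cam_sq"), parts):
        if np.any(a < 0):
            raise ValueError(f"{name} must be non-negative")
    k_adj = parts[0] - parts[1] - parts[2] - parts[3]
    valid = k_adj > 0
    if k_adj.ndim == 0:
        return float(k_adj), bool(valid)
    return k_adj, valid


# ---------------------------------------------------------------------------
# Trace-level operations
# ---------------------------------------------------------------------------

def baseline_indices(
    time_s: np.ndarray, window: Tuple[float, float], *, clip: bool = False
) -> np.ndarray:
    """Boolean index of samples whose timestamp lies in the closed ``window``.

    With ``clip=True`` a window extending past the recording is truncated to
    it; otherwise an empty selection raises :class:`BaselineError`.
    """
    start, end = float(window[0]), float(window[1])
    if end < start:
        raise BaselineError(f"baseline window {window} has end < start")
    time_s = np.asarray(time_s, dtype=float)
    tol = 1e-9
    sel = (time_s >= start - tol) & (time_s <= end + tol)
    if not sel.any():
        if clip:
            raise BaselineError(
                f"baseline window {window} does not overlap the recording "
                f"[{time_s[0]:g}, {time_s[-1]:g}] s"
            )
        raise BaselineError(f"baseline window {window} contains no samples")
    if not clip and end > time_s[-1] + (time_s[1] - time_s[0] if len(time_s) > 1 else 0.0) + tol:
        raise BaselineError(
            f"baseline window {window} extends past the end of the recording ({time_s[-1]:g} s)"
        )
    return sel


def compute_cbfi(
    trace: ContrastTrace,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> FlowTrace:
    """Blood flow index CBFI = 1/K_adj^2, normalized to its baseline mean.

    Invalid contrast samples propagate as NaN in both ``cbfi`` and
    ``cbfi_normalized``.  The normalization divides by the mean CBFI over the
    valid samples inside ``baseline_window`` (window clipped to the recording).
    """
    cbfi = np.full(len(trace), np.nan)
    v = trace.valid
    cbfi[v] = 1.0 / trace.k_adj_sq[v]
    sel = baseline_indices(trace.time_s, baseline_window, clip=True)
    base = sel & v
    if not base.any():
        raise BaselineError(
            f"no valid samples in baseline window {baseline_window} for channel {trace.channel_id}"
        )
    norm = cbfi[base].mean()
    return FlowTrace(
        time_s=trace.time_s,
        cbfi=cbfi,
        cbfi_normalized=cbfi / norm,
        valid=v.copy(),
        baseline_window=(float(baseline_window[0]), float(baseline_window[1])),
        channel_id=trace.channel_id,
    )


def process_stack(
    stack: FrameStack,
    camera: Optional[CameraModel] = None,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    mask: Optional[np.ndarray] = None,
) -> Tuple[ContrastTrace, FlowTrace]:
    """Run the full per-frame contrast chain on a recording.

    For each frame: build the analysis mask (user mask intersected with the
    stack mask, saturated pixels ``DN == max_dn`` excluded when a camera model
    is available), compute the raw contrast, the three noise terms, the
    corrected contrast, and finally the (normalized) CBFI trace.

    ``camera=None`` (and no camera on the stack) treats the recording as
    noise-free: all three noise terms are zero and ``K_adj^2 = K_raw^2``.
    """
    camera = camera if camera is not None else stack.camera
    n = stack.n_frames
    base_mask = np.ones(stack.frame_shape, dtype=bool)
    if stack.mask is not None:
        base_mask &= stack.mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.frame_shape:
            raise ValueError("mask shape must match frame shape")
        base_mask &= mask

    k_raw = np.empty(n)
    k_shot = np.zeros(n)
    k_quant = np.zeros(n)
    k_cam = np.zeros(n)
    n_sat = 0
    for i in range(n):
        frame = stack.frames[i]
        m = base_mask
        if camera is not None:
            sat = frame >= camera.max_dn
            if sat.any():
                m = base_mask & ~sat
                n_sat += int((sat & base_mask).sum())
        k_raw[i] = compute_raw_contrast(frame, m)
        if camera is not None:
            k_shot[i], k_quant[i], k_cam[i] = compute_noise_contrasts(frame, camera, m)
    if n_sat:
        frac = n_sat / (n * base_mask.sum())
        log.info(
            "channel %s: excluded %d saturated pixel samples (%.3g%% of analyzed)",
            stack.channel_id, n_sat, 100 * frac,
        )

    k_adj, valid = adjust_contrast(k_raw, k_shot, k_quant, k_cam)
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.info(
            "channel %s: %d/%d frames flagged invalid (noise terms exceed raw contrast)",
            stack.channel_id, n_invalid, n,
        )
    trace = ContrastTrace(
        time_s=stack.times,
        k_raw_sq=k_raw,
        k_shot_sq=k_shot,
        k_quant_sq=k_quant,
        k_cam_sq=k_cam,
        k_adj_sq=k_adj,
        valid=valid,
        channel_id=stack.channel_id,
    )
    flow = compute_cbfi(trace, baseline_window)
    return trace, flow
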