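"""Blood-volume indices from transmitted-intensity traces.

More blood in the interrogated tissue volume absorbs more light, so the
spatially averaged transmitted intensity mu(I(t)) (in camera grayscale units,
DN) falls as blood volume rises.  Relative to the baseline intensity I0 (mean
intensity over a baseline window) two cerebral blood volume indices are
defined:

    CBVI_linear(t) = 2 - mu(I(t)) / I0          (baseline value 1)
    CBVI_log(t)    = log10(I0 / mu(I(t)))       (baseline value 0)

The linear form is the first-order expansion of the logarithmic one:
for small excursions, CBVI_linear - 1 = ln(10) * CBVI_log + O(delta^2).
Both are strictly decreasing in mu; the logarithmic form is preferable for
large intensity excursions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .contrast_core import DEFAULT_BASELINE_WINDOW, FrameStack, baseline_indices
from .exceptions import DegenerateInputError

__all__ = [
    "VolumeTrace",
    "channel_mean_intensity",
    "compute_baseline_intensity",
    "compute_cbvi_linear",
    "compute_cbvi_log",
    "process_volume",
]


@dataclass
class VolumeTrace:
    """Per-frame mean intensity (DN) and the two blood-volume indices."""

    time_s: np.ndarray
    mean_intensity: np.ndarray
    i0: float
    cbvi_linear: np.ndarray
    cbvi_log: np.ndarray
    valid: np.ndarray
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE_WINDOW
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        if not self.i0 > 0:
            raise ValueError(f"i0 must be > 0, got {self.i0}")

    def __len__(self) -> int:
        return len(self.time_s)


def channel_mean_intensity(stack: FrameStack, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame spatial mean intensity over the mask, in DN."""
    sel = None
    if stack.mask is not None:
        sel = stack.mask.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.frame_shape:
            raise ValueError("mask shape must match frame shape")
        sel = mask if sel is None else (sel & mask)
    if sel is None:
        return stack.frames.reshape(stack.n_frames, -1).mean(axis=1).astype(float)
    if not sel.any():
        raise DegenerateInputError("mask excludes every pixel")
    return stack.frames[:, sel].mean(axis=1).astype(float)


def compute_baseline_intensity(
    mean_intensity: np.ndarray,
    time_s: np.ndarray,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> float:
    """Baseline intensity I0: mean of the mean-intensity trace over the window.

    The window must be non-empty and lie within the recording; a window
    extending past the recording raises :class:`BaselineError`.
    """
    mean_intensity = np.asarray(mean_intensity, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if mean_intensity.shape != time_s.shape:
        raise ValueError("mean_intensity and time_s must have equal length")
    sel = baseline_indices(time_s, baseline_window, clip=False)
    return float(mean_intensity[sel].mean())


def compute_cbvi_linear(mean_intensity: np.ndarray, i0: float) -> np.ndarray:
    """Linear blood-volume index ``2 - mu/I0`` (pointwise)."""
    if not i0 > 0:
        raise ValueError(f"i0 must be > 0, got {i0}")
    return 2.0 - np.asarray(mean_intensity, dtype=float) / i0


def compute_cbvi_log(mean_intensity: np.ndarray, i0: float) -> Tuple[np.ndarray, np.ndarray]:
    """Logarithmic blood-volume index ``log10(I0/mu)`` (pointwise).

    Samples with non-positive mean intensity are flagged invalid (NaN in the
    returned trace) rather than raising.  Returns ``(cbvi_log, valid)``.
    """
    if not i0 > 0:
        raise ValueError(f"i0 must be > 0, got {i0}")
    mu = np.asarray(mean_intensity, dtype=float)
    valid = mu > 0
    out = np.full(mu.shape, np.nan)
    out[valid] = np.log10(i0 / mu[valid])
    return out, valid


def process_volume(
    stack: FrameStack,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    mask: Optional[np.ndarray] = None,
) -> VolumeTrace:
    """Full blood-volume chain for one channel.

    The baseline window is clipped to the recording (a recording shorter than
    the default 5 s window uses all of it); the strict window check of
    :func:`compute_baseline_intensity` applies to direct calls only.
    """
    mi = channel_mean_intensity(stack, mask)
    t = stack.times
    sel = baseline_indices(t, baseline_window, clip=True)
    i0 = float(mi[sel].mean())
    cbvi_lin = compute_cbvi_linear(mi, i0)
    cbvi_log, valid = compute_cbvi_log(mi, i0)
    return VolumeTrace(
        time_s=t,
        mean_intensity=mi,
        i0=i0,
        cbvi_linear=cbvi_lin,
        cbvi_log=cbvi_log,
        valid=valid,
        baseline_window=(float(baseline_window[0]), float(baseline_window[1])),
        channel_id=stack.channel_id,
    )
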