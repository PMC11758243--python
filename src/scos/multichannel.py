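"""Cross-channel correlation analysis of blood-flow/volume traces.

Healthy perfusion drives near-identical cardiac dynamics everywhere on the
head, so the CBFI traces of all channel pairs correlate strongly; a region
whose dynamics have decoupled (e.g. over a structural injury) shows up as a
block of channels that correlate with each other but not with the rest.

The pairwise statistic is the plain Pearson correlation coefficient

    rho(i,j) = sum_t (x_i(t) - xbar_i)(x_j(t) - xbar_j)
               / sqrt(sum_t (x_i(t) - xbar_i)^2 * sum_t (x_j(t) - xbar_j)^2)

computed on the normalized CBFI traces over the full recording with no
detrending or band-pass filtering (none is applied by default; callers may
pre-filter traces themselves).  Samples flagged invalid in either channel of
a pair are dropped pairwise (complete-case).  "Distinct groups" of channels
are operationalized as connected components of the graph whose edges join
pairs with rho >= threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .contrast_core import FlowTrace
from .exceptions import UndefinedCorrelationError
from .hemodynamics import VolumeTrace

log = logging.getLogger(__name__)

__all__ = [
    "ChannelSet",
    "CorrelationResult",
    "pearson_correlation",
    "correlation_matrix",
    "two_channel_summary",
    "group_channels",
]


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class ChannelSet:
    """Labeled collection of per-channel flow (and optionally volume) traces.

    All traces must share the sample count and timestamps (one shared frame
    grid).  ``sd_distance_mm`` optionally records source-detector separations
    for reporting.
    """

    flow: Dict[str, FlowTrace]
    volume: Optional[Dict[str, VolumeTrace]] = None
    frame_rate: Optional[float] = None
    sd_distance_mm: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if len(self.flow) < 1:
            raise ValueError("ChannelSet needs at least one channel")
        lengths = {lab: len(tr) for lab, tr in self.flow.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"all traces must share one sample count, got {lengths}")
        ref = next(iter(self.flow.values())).time_s
        for lab, tr in self.flow.items():
            if not np.allclose(tr.time_s, ref):
                raise ValueError(f"channel {lab} timestamps differ from the shared grid")
        if self.volume is not None:
            for lab, tr in self.volume.items():
                if lab not in self.flow:
                    raise ValueError(f"volume trace {lab} has no matching flow trace")
                if len(tr) != len(ref):
                    raise ValueError(f"volume trace {lab} length differs from the shared grid")

    @property
    def labels(self) -> List[str]:
        return list(self.flow.keys())

    @property
    def n_channels(self) -> int:
        return len(self.flow)

    def mean_intensity(self, label: str) -> float:
        """Time-averaged mean intensity of one channel, DN (NaN if no volume trace)."""
        if self.volume is None or label not in self.volume:
            return float("nan")
        return float(np.nanmean(self.volume[label].mean_intensity))

    def signal(self, label: str, which: str = "cbfi") -> Tuple[np.ndarray, np.ndarray]:
        """(trace, valid) arrays for one channel: normalized CBFI or linear CBVI."""
        if which == "cbfi":
            tr = self.flow[label]
            return tr.cbfi_normalized, tr.valid
        if which == "cbvi":
            if self.volume is None or label not in self.volume:
                raise ValueError(f"no volume trace for channel {label}")
            tv = self.volume[label]
            return tv.cbvi_linear, tv.valid
        raise ValueError(f"signal must be 'cbfi' or 'cbvi', got {which!r}")

    @classmethod
    def from_stacks(
        cls,
        stacks: Dict[str, "FrameStack"],
        camera=None,
        baseline_window=(0.0, 5.0),
    ) -> "ChannelSet":
        """Run the contrast and volume chains on a dict of frame stacks."""
        from .contrast_core import process_stack
        from .hemodynamics import process_volume

        flow, volume = {}, {}
        rate = None
        for lab, stack in stacks.items():
            _, flow[lab] = process_stack(stack, camera=camera, baseline_window=baseline_window)
            volume[lab] = process_volume(stack, baseline_window=baseline_window)
            rate = stack.frame_rate
        return cls(flow=flow, volume=volume, frame_rate=rate)


@dataclass
class CorrelationResult:
    """Pairwise Pearson factors with the symmetric matrix and pair summaries."""

    labels: List[str]
    matrix: pd.DataFrame  # symmetric, unit diagonal, NaN for failed pairs
    pairs: pd.DataFrame  # columns: chan_i, chan_j, pair_mean_intensity_dn, rho
    n_pairs: int
    failed_pairs: List[Tuple[str, str]] = field(default_factory=list)
    signal: str = "cbfi"

    def rho(self, i: str, j: str) -> float:
        return float(self.matrix.loc[i, j])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pearson_correlation(trace_i: np.ndarray, trace_j: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length traces.

    Non-finite samples in either trace are dropped pairwise.  Raises
    :class:`UndefinedCorrelationError` if either trace is constant after
    masking, ``ValueError`` on length mismatch or fewer than two joint
    samples.
    """
    x = np.asarray(trace_i, dtype=np.float64)
    y = np.asarray(trace_j, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(f"traces must be equal-length 1-D arrays, got {x.shape} and {y.shape}")
    joint = np.isfinite(x) & np.isfinite(y)
    x, y = x[joint], y[joint]
    if x.size < 2:
        raise ValueError(f"need at least 2 jointly valid samples, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.dot(xc, xc)
    sy = np.dot(yc, yc)
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant trace")
    r = np.dot(xc, yc) / np.sqrt(sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def correlation_matrix(channel_set: ChannelSet, signal: str = "cbfi") -> CorrelationResult:
    """All unordered pairwise correlations of a channel set.

    For n channels there are n(n-1)/2 pairs.  Pairs for which the correlation
    is undefined are flagged (NaN in the matrix) rather than fatal.  Each pair
    also carries the two-channel mean intensity: the average of the two
    channels' time-averaged mean intensities, in DN.
    """
    labels = channel_set.labels
    if len(labels) < 2:
        raise ValueError("correlation analysis needs at least 2 channels")
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    rows = []
    failed: List[Tuple[str, str]] = []
    traces = {lab: channel_set.signal(lab, signal) for lab in labels}
    for li, lj in itertools.combinations(labels, 2):
        (xi, vi), (xj, vj) = traces[li], traces[lj]
        joint = vi & vj
        n_dropped = int(len(xi) - joint.sum())
        if n_dropped:
            log.info("pair (%s, %s): dropped %d invalid samples (complete-case)", li, lj, n_dropped)
        try:
            rho = pearson_correlation(
                np.where(joint, xi, np.nan), np.where(joint, xj, np.nan)
            )
        except (UndefinedCorrelationError, ValueError) as exc:
            log.warning("pair (%s, %s): correlation failed: %s", li, lj, exc)
            rho = np.nan
            failed.append((li, lj))
        mat.loc[li, lj] = mat.loc[lj, li] = rho
        pair_mi = 0.5 * (channel_set.mean_intensity(li) + channel_set.mean_intensity(lj))
        rows.append({"chan_i": li, "chan_j": lj, "pair_mean_intensity_dn": pair_mi, "rho": rho})
    pairs = pd.DataFrame(rows, columns=["chan_i", "chan_j", "pair_mean_intensity_dn", "rho"])
    return CorrelationResult(
        labels=labels,
        matrix=mat,
        pairs=pairs,
        n_pairs=len(rows),
        failed_pairs=failed,
        signal=signal,
    )


def two_channel_summary(channel_set: ChannelSet, signal: str = "cbfi") -> pd.DataFrame:
    """One (two-channel mean intensity, rho) point per unordered channel pair.

    The scatter of these points separates noise effects from physiology: pure
    noise would make low-intensity pairs systematically low-correlation,
    whereas two dim channels sharing the same dynamics keep a high rho.
    """
    return correlation_matrix(channel_set, signal=signal).pairs


def group_channels(result: CorrelationResult, threshold: float = 0.6) -> List[List[str]]:
    """Partition channels into connected components of the rho >= threshold graph.

    Returns the components as label lists, each sorted in channel order, the
    components ordered by their first channel.  A threshold above the largest
    rho yields all-singleton groups.
    """
    g = nx.Graph()
    g.add_nodes_from(result.labels)
    order = {lab: k for k, lab in enumerate(result.labels)}
    for li, lj in itertools.combinations(result.labels, 2):
        rho = result.matrix.loc[li, lj]
        if np.isfinite(rho) and rho >= threshold:
            g.add_edge(li, lj)
    comps = [sorted(c, key=order.get) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: order[c[0]])
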