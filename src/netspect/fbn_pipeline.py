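"""Functional-network state-transition detection from multichannel signals.

Pipeline: slice a channels × samples recording into windows, build one
functional network per window (vertices = channels, edge iff the
within-window Pearson correlation exceeds a cutoff, default 0.5),
cluster the resulting graph sequence with the spectral-density k-means
(K = 2), map the cluster indices onto binary states (1 = the state the
recording starts in, e.g. awake), and locate state transitions as the
first center of a 50-point centered moving average of the labels that
crosses 0.5 — downward for loss of the initial state, upward for
recovery.

A synthetic two-state generator (shared latent signal whose coupling to
the channels switches at known change points) makes the whole path
testable without any recording downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .clustering import kmeans_graphs
from .graph_models import Graph

__all__ = [
    "SignalWindow",
    "StateSeries",
    "window_stream",
    "correlation_graph",
    "detect_transition",
    "synthetic_two_state_signals",
    "cluster_windows",
    "run_transition_pipeline",
    "TransitionResult",
]


@dataclass(frozen=True)
class SignalWindow:
    """One channels × samples slice of a recording."""

    data: np.ndarray
    start: int

    def __post_init__(self):
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 2 or d.shape[0] < 2 or d.shape[1] < 3:
            raise ValueError("window needs >= 2 channels and >= 3 samples")
        object.__setattr__(self, "data", d)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class StateSeries:
    """Binary state labels over time (1 = initial/awake-like state)."""

    labels: np.ndarray
    interval: float = 1.0

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1 or not np.all(np.isin(lab, (0, 1))):
            raise ValueError("state labels must be a 1-D 0/1 series")
        object.__setattr__(self, "labels", lab)


def window_stream(
    signals: np.ndarray, window_len: int, stride: Optional[int] = None
) -> List[SignalWindow]:
    """Slice a channels × samples table into strided windows.

    ``stride`` defaults to ``window_len`` (non-overlapping windows);
    window start indices are multiples of the stride.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2:
        raise ValueError("signals must be a 2-D channels x samples array")
    n_samples = signals.shape[1]
    if window_len > n_samples:
        raise ValueError(f"window_len {window_len} exceeds {n_samples} samples")
    stride = window_len if stride is None else int(stride)
    if stride < 1:
        raise ValueError("stride must be positive")
    return [
        SignalWindow(signals[:, s:s + window_len], s)
        for s in range(0, n_samples - window_len + 1, stride)
    ]


def correlation_graph(window, cutoff: float = 0.5) -> Graph:
    """Threshold the window's Pearson correlation matrix into a graph.

    One vertex per channel; edge {i, j} iff r(i, j) strictly exceeds
    ``cutoff``.  The diagonal is ignored (no self-loops).
    """
    data = window.data if isinstance(window, SignalWindow) else np.asarray(window)
    dead = np.flatnonzero(np.ptp(data, axis=1) == 0)
    if dead.size:
        raise ValueError(f"zero-variance channel(s): {dead.tolist()}")
    r = np.corrcoef(data)
    ii, jj = np.nonzero(np.triu(r > cutoff, k=1))
    return Graph.from_edges(data.shape[0], zip(ii.tolist(), jj.tolist()))


def detect_transition(
    states, window: int = 50, direction: str = "falling"
) -> Optional[int]:
    """First centered moving-average crossing of 0.5.

    Returns the center index (window start + window // 2) of the first
    length-``window`` window whose label mean drops below 0.5
    (``direction="falling"``) or rises above 0.5 (``"rising"``), or
    ``None`` when no window crosses.  Edge positions where the full
    window does not fit are not evaluated (no padding).
    """
    if direction not in ("falling", "rising"):
        raise ValueError("direction must be 'falling' or 'rising'")
    labels = states.labels if isinstance(states, StateSeries) else np.asarray(states)
    if labels.size < window:
        raise ValueError(f"series of {labels.size} labels shorter than window {window}")
    means = np.convolve(labels.astype(float), np.ones(window) / window, "valid")
    hits = np.flatnonzero(means < 0.5 if direction == "falling" else means > 0.5)
    if hits.size == 0:
        return None
    return int(hits[0]) + window // 2


def synthetic_two_state_signals(
    n_channels: int,
    n_samples: int,
    change_points: Sequence[int],
    coupling_high: float = 0.9,
    coupling_low: float = 0.1,
    noise_sd: float = 0.5,
    seed=None,
) -> np.ndarray:
    """Synthetic multichannel recording with switching channel coupling.

    Every channel is ``coupling * z(t) + noise_sd * eps`` with one shared
    latent standard-normal signal ``z``; the coupling alternates between
    ``coupling_high`` (segments starting at sample 0) and
    ``coupling_low`` at the sorted ``change_points``.  Expected pairwise
    correlation is ``c² / (c² + noise_sd²)``, so high-coupling segments
    produce dense correlation graphs and low-coupling segments sparse
    ones — a deliberately idealized stand-in for awake/anesthetized
    recordings.
    """
    for c in (coupling_high, coupling_low):
        if not (0.0 <= c <= 1.0):
            raise ValueError("coupling values must lie in [0, 1]")
    change_points = sorted(int(c) for c in change_points)
    if any(not (0 < c < n_samples) for c in change_points):
        raise ValueError("change points must fall inside (0, n_samples)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    coupling = np.full(n_samples, coupling_high)
    bounds = change_points + [n_samples]
    for seg, start in enumerate(change_points):
        value = coupling_low if seg % 2 == 0 else coupling_high
        coupling[start:bounds[seg + 1]] = value
    noise = rng.standard_normal((n_channels, n_samples)) * noise_sd
    return coupling[None, :] * z[None, :] + noise


def cluster_windows(
    graphs: Sequence[Graph],
    ref_len: int = 50,
    n_restarts: int = 10,
    seed=None,
) -> StateSeries:
    """Cluster a window-graph sequence (K=2) into a binary state series.

    The cluster holding the majority of the first ``ref_len`` windows is
    mapped to state 1 (the recording is assumed to start in that state).
    """
    result = kmeans_graphs(graphs, 2, n_restarts=n_restarts, seed=seed)
    head = result.labels[: max(1, min(ref_len, len(graphs)))]
    initial = 1 if head.mean() > 0.5 else 0
    return StateSeries((result.labels == initial).astype(np.int64))


@dataclass
class TransitionResult:
    states: StateSeries
    falling: Optional[int]
    rising: Optional[int]


def run_transition_pipeline(
    signals: np.ndarray,
    window_len: int,
    stride: Optional[int] = None,
    cutoff: float = 0.5,
    ma_window: int = 50,
    n_restarts: int = 10,
    seed=None,
) -> TransitionResult:
    """End-to-end: windows → correlation graphs → k-means → transitions."""
    windows = window_stream(signals, window_len, stride)
    graphs = [correlation_graph(w, cutoff) for w in windows]
    states = cluster_windows(graphs, ref_len=ma_window,
                             n_restarts=n_restarts, seed=seed)
    return TransitionResult(
        states=states,
        falling=detect_transition(states, ma_window, "falling"),
        rising=detect_transition(states, ma_window, "rising"),
    )
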