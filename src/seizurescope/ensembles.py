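"""Neuronal ensemble detection by surrogate shuffling.

A sliding 0.5-s (10-frame) window converts a binary event raster into a
coactivity series — the number of neurons with at least one event in each
window.  The null distribution is built by shuffling each neuron's binary
event vector (a full random permutation, preserving its event count while
destroying all timing), recomputing the coactivity series, and pooling the
counts over all shuffles (default 2000).  Window positions whose observed
count strictly exceeds the empirical (1 - alpha) quantile of the pooled null
(default alpha = 0.001, i.e. the 99.9th percentile as an order statistic) are
flagged; runs of consecutive flagged positions merge into one ensemble
event whose members are the neurons active within the merged span.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError


@dataclass
class CoactivitySeries:
    """Sliding-window coactive-neuron counts."""

    counts: np.ndarray
    window: int
    fps: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any() or (self.counts > self.n_neurons).any():
            raise InputError("coactivity counts outside [0, n_neurons]")


def _window_counts(raster: np.ndarray, window: int) -> np.ndarray:
    """Coactive-neuron count for every window start position."""
    cs = np.zeros((raster.shape[0] + 1, raster.shape[1]), dtype=np.int32)
    np.cumsum(raster, axis=0, out=cs[1:])
    active = (cs[window:] - cs[:-window]) > 0     # neuron has >=1 event in window
    return active.sum(axis=1)


def coactivity_series(raster: np.ndarray, window: int = 10,
                      fps: float = 20.0) -> CoactivitySeries:
    """Count coactive neurons in every sliding window of a binary raster.

    ``counts[t]`` = number of neurons with at least one event in frames
    ``[t, t + window)``; a neuron with several events in a window counts once.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise InputError("raster must be 2-D (frames, neurons)")
    raster = raster.astype(bool)
    if window < 1:
        raise ParameterError("window must be >= 1 frame")
    if window > raster.shape[0]:
        raise InputError("window longer than the epoch")
    return CoactivitySeries(
        _window_counts(raster, window), window=window, fps=fps,
        n_neurons=raster.shape[1],
    )


def surrogate_null(
    raster: np.ndarray, window: int = 10, n_shuffles: int = 2000, seed=0
) -> np.ndarray:
    """Pooled null coactivity counts from within-neuron shuffles.

    Each shuffle independently permutes every neuron's binary event vector in
    time (event counts preserved), recomputes the sliding-window coactivity
    series, and pools all counts into one empirical null distribution.
    """
    if n_shuffles < 1:
        raise ParameterError("need at least one shuffle")
    raster = np.asarray(raster).astype(bool)
    if window < 1 or window > raster.shape[0]:
        raise InputError("invalid window for this raster")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_windows = raster.shape[0] - window + 1
    pooled = np.empty(n_shuffles * n_windows, dtype=np.int32)
    for s in range(n_shuffles):
        perm = rng.permuted(raster, axis=0)
        pooled[s * n_windows : (s + 1) * n_windows] = _window_counts(perm, window)
    return pooled


def null_threshold(null: np.ndarray, alpha: float = 0.001) -> int:
    """(1 - alpha) empirical quantile of the pooled null, as an order statistic."""
    if len(null) == 0:
        raise InputError("null distribution is empty")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    return int(np.quantile(null, 1.0 - alpha, method="inverted_cdf"))


@dataclass
class EnsembleEvent:
    """One merged run of significant coactivation windows."""

    frame_start: int          # first flagged window position
    frame_stop: int           # exclusive end of the covered frame span
    members: np.ndarray       # neuron indices with >=1 event in the span
    peak_count: int
    centroid: np.ndarray | None = None
    member_distances: np.ndarray | None = None


@dataclass
class EnsembleSet:
    """All detected ensemble events plus the null-model bookkeeping."""

    events: list[EnsembleEvent]
    threshold: int
    alpha: float
    n_shuffles: int
    window: int
    seed: int | None = None
    flagged_positions: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __len__(self) -> int:
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.events):
            for k, m in enumerate(e.members):
                d = (
                    float(e.member_distances[k])
                    if e.member_distances is not None
                    else np.nan
                )
                rows.append((i, e.frame_start, e.frame_stop, int(m), d))
        return pd.DataFrame(
            rows, columns=["ensemble", "frame_start", "frame_stop", "member", "distance"]
        )


def detect_ensembles(
    observed: CoactivitySeries,
    null: np.ndarray,
    raster: np.ndarray,
    alpha: float = 0.001,
    n_shuffles: int | None = None,
    seed: int | None = None,
) -> EnsembleSet:
    """Flag windows beating the null and merge them into ensemble events.

    A window position is significant iff its observed count strictly exceeds
    the (1 - alpha) order-statistic quantile of the pooled null.  Consecutive
    significant positions merge into one event; the event's members are the
    neurons with at least one raster event within the merged frame span
    (first position through last position + window).
    """
    thr = null_threshold(null, alpha)
    flagged = np.flatnonzero(observed.counts > thr)
    raster = np.asarray(raster).astype(bool)
    events = []
    if len(flagged):
        breaks = np.flatnonzero(np.diff(flagged) > 1)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks, [len(flagged) - 1]])
        for a, b in zip(starts, stops):
            lo = int(flagged[a])
            hi = int(flagged[b]) + observed.window   # exclusive frame span end
            members = np.flatnonzero(raster[lo:hi].any(axis=0))
            peak = int(observed.counts[flagged[a] : flagged[b] + 1].max())
            events.append(
                EnsembleEvent(frame_start=lo, frame_stop=hi, members=members,
                              peak_count=peak)
            )
    return EnsembleSet(
        events=events,
        threshold=thr,
        alpha=alpha,
        n_shuffles=n_shuffles if n_shuffles is not None else 0,
        window=observed.window,
        seed=seed,
        flagged_positions=flagged,
    )


def find_ensembles(
    raster: np.ndarray,
    window: int = 10,
    n_shuffles: int = 2000,
    alpha: float = 0.001,
    seed: int = 0,
    fps: float = 20.0,
) -> EnsembleSet:
    """Convenience wrapper: coactivity series + surrogate null + detection."""
    obs = coactivity_series(raster, window=window, fps=fps)
    null = surrogate_null(raster, window=window, n_shuffles=n_shuffles, seed=seed)
    return detect_ensembles(obs, null, raster, alpha=alpha,
                            n_shuffles=n_shuffles, seed=seed)


def ensemble_spatial_stats(ens: EnsembleSet, centroids: np.ndarray) -> EnsembleSet:
    """Attach centroid and per-member Euclidean distances to every ensemble.

    ``centroids`` is an (n_neurons, 2) coordinate array (pixels or microns).
    The ensemble centroid is the mean of its members' coordinates.
    """
    centroids = np.asarray(centroids, dtype=float)
    for e in ens.events:
        if len(e.members) and e.members.max() >= len(centroids):
            raise InputError("ensemble member lacks a centroid coordinate")
        pts = centroids[e.members]
        c = pts.mean(axis=0)
        e.centroid = c
        e.member_distances = np.linalg.norm(pts - c, axis=1)
    return ens


def mask_ictal_frames(
    raster: np.ndarray,
    ictal_windows_s: list[tuple[float, float]],
    fps: float,
    pad_s: float = 2.0,
) -> np.ndarray:
    """Zero out raster events inside (padded) ictal windows.

    Ensemble analysis targets interictal activity; brain-wide ictal events
    would otherwise trivially dominate the coactivity series.
    """
    out = np.asarray(raster).astype(bool).copy()
    n = out.shape[0]
    for t0, t1 in ictal_windows_s:
        a = max(0, int(np.floor((t0 - pad_s) * fps)))
        b = min(n, int(np.ceil((t1 + pad_s) * fps)) + 1)
        out[a:b] = False
    return out
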