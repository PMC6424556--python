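"""LFP / calcium ictal-event feature extraction and pairing.

For each ictal event (in either modality) the amplitude is the absolute
maximum deflection from baseline within the event span, and the duration is
the interval between the first departure from and last return to baseline.
"Baseline" is made operational for noisy traces as the median of a pre-event
window, with departure/return defined as crossings of baseline +/- k robust
standard deviations (MAD-based, default k = 3).

Paired features across modalities are summarized by the squared Pearson
correlation: in the seizure preparation this pipeline models, durations are
tightly coupled across modalities while amplitudes are not.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import InputError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class EventFeatures:
    """Amplitude/duration features for one modality's events."""

    table: pd.DataFrame        # columns: event, amplitude, duration_s
    source: str                # "lfp" | "calcium"


def robust_sd(x: np.ndarray) -> float:
    """Median absolute deviation scaled to the Gaussian standard deviation."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def filter_lfp(x: np.ndarray, fps: float, hp_hz: float = 0.1,
               lp_hz: float | None = 1000.0) -> np.ndarray:
    """Band-limit an LFP trace (zero-phase Butterworth).

    Defaults mirror a typical acquisition chain (0.1 Hz high-pass, 1 kHz
    low-pass); the low-pass is skipped when it exceeds the Nyquist rate, as
    for down-sampled synthetic traces.
    """
    x = np.asarray(x, dtype=float)
    nyq = fps / 2.0
    if hp_hz and hp_hz > 0:
        sos = signal.butter(2, hp_hz, btype="highpass", fs=fps, output="sos")
        x = signal.sosfiltfilt(sos, x)
    if lp_hz and lp_hz < 0.95 * nyq:
        sos = signal.butter(4, lp_hz, btype="lowpass", fs=fps, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return x


def _clean_mask(above: np.ndarray, close_gap: int, min_run: int) -> np.ndarray:
    """Close short sub-threshold gaps, then drop short supra-threshold runs.

    Gap closing bridges the zero crossings of an oscillatory burst; run
    pruning rejects isolated noise excursions that would otherwise define
    spurious first/last crossings over a long event span.
    """
    mask = above.copy()
    n = len(mask)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    starts, stops = edges[::2], edges[1::2]
    # close gaps between consecutive runs
    for s, e in zip(stops[:-1], starts[1:]):
        if e - s <= close_gap:
            mask[s:e] = True
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    starts, stops = edges[::2], edges[1::2]
    for s, e in zip(starts, stops):
        if e - s < min_run:
            mask[s:e] = False
    assert len(mask) == n
    return mask


def event_features(
    trace: np.ndarray,
    fps: float,
    spans_s: list[tuple[float, float]],
    baseline_window_s: float = 5.0,
    k: float = 3.0,
    close_gap_s: float = 0.15,
    min_run_s: float = 0.5,
    source: str = "calcium",
) -> EventFeatures:
    """Amplitude and duration of each event span in a single trace.

    For each span, the baseline is the median of the ``baseline_window_s``
    seconds preceding the span (clipped to the trace start); the noise scale
    is the robust SD of the same window.  The supra-threshold mask
    (|trace - baseline| > k*SD) is cleaned morphologically: sub-threshold
    gaps shorter than ``close_gap_s`` are closed (bridging the zero crossings
    of oscillatory bursts) and supra-threshold runs shorter than
    ``min_run_s`` are discarded (isolated noise excursions).  Duration is the
    interval from the first to the last surviving supra-threshold sample.
    Events with no surviving crossing are flagged unresolvable and excluded
    with a log entry.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if not fps > 0:
        raise ParameterError("fps must be positive")
    close_gap = int(round(close_gap_s * fps))
    min_run = max(1, int(round(min_run_s * fps)))
    rows = []
    for e, (t0, t1) in enumerate(spans_s):
        a = int(round(t0 * fps))
        b = int(round(t1 * fps))
        if not (0 <= a < b <= n):
            raise InputError(f"event {e} span [{t0}, {t1}] s outside the trace")
        pre_a = max(0, a - int(round(baseline_window_s * fps)))
        if pre_a == a:
            raise InputError(f"event {e}: no pre-event data for a baseline")
        pre = trace[pre_a:a]
        base = float(np.median(pre))
        sd = max(robust_sd(pre), 1e-12)
        dev = trace[a:b] - base
        above = _clean_mask(np.abs(dev) > k * sd, close_gap, min_run)
        if not above.any():
            log.warning("event %d: no baseline crossing; unresolvable, excluded", e)
            continue
        first = int(np.argmax(above))
        last = int(len(above) - 1 - np.argmax(above[::-1]))
        rows.append(
            (e, float(np.abs(dev).max()), (last - first + 1) / fps)
        )
    return EventFeatures(
        table=pd.DataFrame(rows, columns=["event", "amplitude", "duration_s"]),
        source=source,
    )


def paired_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of paired per-event features."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("paired features must have equal length")
    if len(x) < 3:
        raise InputError("need at least 3 paired events")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in a paired feature; R^2 defined as 0",
                      stacklevel=2)
        return 0.0
    r = stats.pearsonr(x, y).statistic
    return float(r ** 2)


def lfp_calcium_correlation(
    calcium: EventFeatures, lfp: EventFeatures
) -> dict[str, float]:
    """Pair events by shared id and report amplitude and duration R^2."""
    merged = calcium.table.merge(lfp.table, on="event", suffixes=("_ca", "_lfp"))
    if len(merged) < 3:
        raise InputError("fewer than 3 events resolvable in both modalities")
    return {
        "n_events": int(len(merged)),
        "r2_amplitude": paired_r2(
            merged["amplitude_ca"].to_numpy(), merged["amplitude_lfp"].to_numpy()
        ),
        "r2_duration": paired_r2(
            merged["duration_s_ca"].to_numpy(), merged["duration_s_lfp"].to_numpy()
        ),
    }
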