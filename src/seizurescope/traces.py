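"""ROI trace extraction and dF/F normalization.

dF/F uses a causal sliding-window lower-half baseline: at each sample t the
baseline B[t] is the mean of the lowest ``ceil(fraction * n)`` values among
the n samples in the previous ``window_s`` seconds (the window ending at and
including t), and dF/F[t] = (F[t] - B[t]) / B[t].  During the warm-up (the
first window) the partial causal window is used, so the first sample has
B[0] = F[0] and dF/F[0] = 0.  The baseline tracks slow drift while ignoring
transients, which occupy the upper half of the window's values.
"""
from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import RoiSet, TraceMatrix
from .exceptions import InputError, NumericalError, ParameterError


def extract_roi_traces(stack: np.ndarray, rois: RoiSet, fps: float = 1.0) -> TraceMatrix:
    """Average the pixels of each ROI in every frame of an image stack.

    Returns a raw-kind :class:`TraceMatrix` whose channel order follows the
    RoiSet order.  ``fps`` is acquisition metadata, not stored in the TIFF.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InputError("stack must be 3-D (frames, rows, cols)")
    if stack.shape[1:] != rois.frame_shape:
        raise InputError(
            f"stack frames {stack.shape[1:]} do not match ROI masks {rois.frame_shape}"
        )
    values = np.column_stack(
        [stack[:, roi.mask].mean(axis=1, dtype=np.float64) for roi in rois]
    )
    return TraceMatrix(values, fps=fps, labels=rois.channel_labels, kind="raw")


def _lower_half_baseline(x: np.ndarray, window: int, fraction: float) -> np.ndarray:
    """Causal lower-fraction mean baseline for one channel."""
    n = len(x)
    baseline = np.empty(n)
    # warm-up: partial causal windows [0, t]
    head = min(window - 1, n)
    for t in range(head):
        win = np.sort(x[: t + 1])
        k = math.ceil(fraction * (t + 1))
        baseline[t] = np.mean(win[:k])
    if n >= window:
        k = math.ceil(fraction * window)
        windows = sliding_window_view(x, window)       # rows end at t = window-1 .. n-1
        # partition pulls the k smallest per row; sorting that slice makes the
        # summation order identical to a full per-window sort
        low = np.sort(np.partition(windows, k - 1, axis=1)[:, :k], axis=1)
        baseline[window - 1 :] = low.mean(axis=1)
    return baseline


def compute_dff(
    raw: TraceMatrix, window_s: float = 10.0, fraction: float = 0.5
) -> TraceMatrix:
    """Baseline-normalize raw fluorescence to dF/F.

    ``window_s`` is the causal sliding-window length in seconds (default the
    10-s convention); ``fraction`` the lower fraction of window samples
    averaged into the baseline (default the lower 50%).
    """
    if raw.kind != "raw":
        raise InputError("compute_dff expects a raw-kind TraceMatrix")
    window = int(round(window_s * raw.fps))
    if window < 2:
        raise ParameterError("window_s * fps must be at least 2 samples")
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must lie in (0, 1]")
    if (raw.values <= 0).any():
        t, c = np.argwhere(raw.values <= 0)[0]
        raise NumericalError(
            f"nonpositive raw fluorescence at frame {t}, channel {raw.labels[c]!r}"
        )
    window = min(window, raw.n_frames)
    out = np.empty_like(raw.values)
    for j in range(raw.n_channels):
        b = _lower_half_baseline(raw.values[:, j], window, fraction)
        if (b <= 0).any():
            t = int(np.argmax(b <= 0))
            raise NumericalError(
                f"nonpositive baseline at frame {t}, channel {raw.labels[j]!r}"
            )
        out[:, j] = (raw.values[:, j] - b) / b
    return TraceMatrix(out, fps=raw.fps, labels=list(raw.labels), kind="dff")


def normalized_auc(dff: TraceMatrix, channel: str | None = None):
    """Rectified, duration-normalized area under the dF/F curve.

    The trapezoidal integral of ``max(dF/F, 0)`` over time divided by the
    epoch length in seconds — a per-channel scalar summary of total
    paroxysmal activity.  Returns a scalar for one ``channel`` or a dict over
    all channels.
    """
    if dff.kind != "dff":
        raise InputError("normalized_auc expects a dff-kind TraceMatrix")
    if dff.n_frames == 0:
        raise InputError("empty trace")

    def one(x: np.ndarray) -> float:
        return float(
            np.trapezoid(np.clip(x, 0.0, None), dx=1.0 / dff.fps) / dff.duration_s
        )

    if channel is not None:
        return one(dff.channel(channel))
    return {lab: one(dff.values[:, j]) for j, lab in enumerate(dff.labels)}
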