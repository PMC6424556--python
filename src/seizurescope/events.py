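"""Template-matching calcium event detection and event-train management.

A time-varying Pearson correlation is computed between each dF/F trace and a
library of unit-peak transient templates.  Candidate timestamps are the
strict local maxima of the per-time maximum correlation across templates; a
candidate becomes an event iff its correlation exceeds ``corr_thresh`` and
the peak dF/F within the matched template's span exceeds ``amp_thresh``
(defaults 0.85 and 0.1).  Surviving candidates undergo greedy non-maximum
suppression: an accepted event suppresses lower-correlation candidates that
are closer than ``min_sep_s`` or fall inside its matched template span, so a
single long transient yields a single event.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core import TraceMatrix
from .exceptions import EditError, InputError, ParameterError
from .synthetic import generate_calcium_kernel

#: Default template grids; template span is 5x the decay constant, capped at
#: MAX_TEMPLATE_SPAN_S, so the library covers transient durations from 1.5 s
#: (short interictal transients) to ~16 s (long ictal events).  Shorter
#: templates are available via a custom grid, but at 20 Hz a sub-second
#: correlation window has too few samples for a 0.85 Pearson threshold to be
#: selective.
DEFAULT_DECAYS_S = (0.3, 0.6, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0)
DEFAULT_RISES_S = (0.05, 0.25)
MAX_TEMPLATE_SPAN_S = 16.0


@dataclass
class TemplateLibrary:
    """A list of unit-peak transient waveforms at a common sampling rate."""

    templates: list[np.ndarray]
    fps: float

    def __post_init__(self) -> None:
        if not self.templates:
            raise ParameterError("template library is empty")
        for i, t in enumerate(self.templates):
            t = np.asarray(t, dtype=float)
            if len(t) < 4:
                raise ParameterError(f"template {i} has fewer than 4 samples")
            if not np.isclose(t.max(), 1.0):
                raise ParameterError(f"template {i} does not peak at 1")
            self.templates[i] = t

    @property
    def durations_s(self) -> list[float]:
        return [len(t) / self.fps for t in self.templates]

    @property
    def min_len(self) -> int:
        return min(len(t) for t in self.templates)


def build_template_library(
    rises_s=DEFAULT_RISES_S, decays_s=DEFAULT_DECAYS_S, fps: float = 20.0
) -> TemplateLibrary:
    """One difference-of-exponentials template per (rise, decay) pair.

    Each template spans 5 decay constants, long enough to capture ~99% of the
    waveform's area.
    """
    if not len(rises_s) or not len(decays_s):
        raise ParameterError("rise/decay grids must be nonempty")
    templates = [
        generate_calcium_kernel(r, d, fps, min(5.0 * d, MAX_TEMPLATE_SPAN_S))
        for r in rises_s
        for d in decays_s
    ]
    return TemplateLibrary(templates, fps=fps)


def sliding_pearson(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of every length-L window of ``x`` with ``template``.

    Returns an array of length ``len(x) - L + 1``; windows with zero variance
    get correlation 0 (a flat segment cannot be an event).
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(template, dtype=float)
    L = len(g)
    if len(x) < L:
        raise InputError(f"trace of {len(x)} samples shorter than template ({L})")
    g0 = g - g.mean()
    sg = np.sqrt(np.sum(g0 ** 2))
    if sg == 0:
        return np.zeros(len(x) - L + 1)
    w = sliding_window_view(x, L)
    dots = w @ g0
    s1 = w.sum(axis=1)
    s2 = (w ** 2).sum(axis=1)
    var = s2 - s1 ** 2 / L
    var = np.clip(var, 0.0, None)
    sx = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = dots / (sg * sx)
    r[sx <= 1e-12 * max(np.abs(x).max(), 1.0)] = 0.0
    return np.clip(r, -1.0, 1.0)


def _local_maxima_first_frame(c: np.ndarray) -> np.ndarray:
    """Strict local maxima; plateaus report their first frame."""
    peaks = []
    n = len(c)
    t = 1
    while t < n - 1:
        if c[t] > c[t - 1]:
            u = t
            while u + 1 < n and c[u + 1] == c[t]:
                u += 1
            if u + 1 < n and c[u + 1] < c[t]:
                peaks.append(t)
            t = u + 1
        else:
            t += 1
    return np.asarray(peaks, dtype=int)


@dataclass
class EventTrain:
    """Per-channel calcium event timestamps (frames) and amplitudes (dF/F)."""

    frames: dict[str, np.ndarray]
    amplitudes: dict[str, np.ndarray]
    fps: float
    n_frames: int
    audit_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.frames) != set(self.amplitudes):
            raise InputError("frames and amplitudes must cover the same channels")
        for ch in self.frames:
            f = np.asarray(self.frames[ch], dtype=int)
            a = np.asarray(self.amplitudes[ch], dtype=float)
            if len(f) != len(a):
                raise InputError(f"channel {ch!r}: frame/amplitude length mismatch")
            if len(f) and (np.diff(f) <= 0).any():
                raise InputError(f"channel {ch!r}: timestamps not strictly increasing")
            if len(f) and (f.min() < 0 or f.max() >= self.n_frames):
                raise InputError(f"channel {ch!r}: timestamps outside the epoch")
            if (a <= 0).any():
                raise InputError(f"channel {ch!r}: amplitudes must be positive")
            self.frames[ch] = f
            self.amplitudes[ch] = a

    @property
    def channels(self) -> list[str]:
        return list(self.frames)

    def counts(self) -> dict[str, int]:
        return {ch: len(f) for ch, f in self.frames.items()}

    def raster(self, channel_order: list[str] | None = None) -> np.ndarray:
        """Binary (n_frames, n_channels) event raster."""
        order = channel_order or self.channels
        out = np.zeros((self.n_frames, len(order)), dtype=bool)
        for j, ch in enumerate(order):
            out[self.frames[ch], j] = True
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ch in self.channels:
            for f, a in zip(self.frames[ch], self.amplitudes[ch]):
                rows.append((ch, int(f), f / self.fps, float(a)))
        return pd.DataFrame(rows, columns=["channel", "frame", "time_s", "amplitude"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, fps: float, n_frames: int) -> "EventTrain":
        df = pd.read_csv(path)
        frames = {}
        amps = {}
        for ch, grp in df.groupby("channel", sort=False):
            order = np.argsort(grp["frame"].to_numpy())
            frames[str(ch)] = grp["frame"].to_numpy(dtype=int)[order]
            amps[str(ch)] = grp["amplitude"].to_numpy(dtype=float)[order]
        return cls(frames, amps, fps=fps, n_frames=n_frames)


def _detect_channel(x, templates: TemplateLibrary, fps, amp_thresh, corr_thresh,
                    min_sep_s):
    n = len(x)
    if n < templates.min_len:
        raise InputError("trace shorter than the shortest template")
    corr = np.full(n, -np.inf)
    best_len = np.zeros(n, dtype=int)
    trunc_min = max(4, int(round(fps)))   # truncated templates keep >= ~1 s
    for g in templates.templates:
        L = min(len(g), n)
        r = sliding_pearson(x, g[:L])
        better = r > corr[: len(r)]
        corr[: len(r)][better] = r[better]
        best_len[: len(r)][better] = L
        # near the trace end, slide the template off the edge so long
        # transients close to the epoch boundary still get a matched span
        for t in range(n - L + 1, n - trunc_min + 1):
            k = n - t
            if k >= L:
                continue
            rt = sliding_pearson(x[t:], g[:k])[0]
            if rt > corr[t]:
                corr[t] = rt
                best_len[t] = k
    corr[np.isneginf(corr)] = 0.0

    cands = _local_maxima_first_frame(corr)
    keep = []
    for t in cands:
        if corr[t] <= corr_thresh:
            continue
        span = min(t + best_len[t], n)
        # transient amplitude = local rise from the candidate frame to the
        # peak within the matched template span; a window sliding down a
        # decay tail has high correlation but no rise and is rejected here
        if np.max(x[t:span]) - x[t] > amp_thresh:
            keep.append(t)

    # greedy non-maximum suppression, highest correlation first
    keep = sorted(keep, key=lambda t: (-corr[t], t))
    min_sep = int(round(min_sep_s * fps))
    accepted: list[int] = []
    spans: list[tuple[int, int]] = []
    for t in keep:
        ok = True
        for (a, b), ta in zip(spans, accepted):
            if abs(t - ta) < min_sep or a <= t < b:
                ok = False
                break
        if ok:
            accepted.append(t)
            spans.append((t, min(t + best_len[t], n)))
    accepted = np.array(sorted(accepted), dtype=int)
    amps = np.array(
        [np.max(x[t : min(t + best_len[t], n)]) - x[t] for t in accepted],
        dtype=float,
    )
    return accepted, amps


def detect_events(
    dff: TraceMatrix,
    templates: TemplateLibrary | None = None,
    amp_thresh: float = 0.1,
    corr_thresh: float = 0.85,
    min_sep_s: float = 1.0,
) -> EventTrain:
    """Detect calcium events in every channel of a dF/F trace matrix."""
    if dff.kind != "dff":
        raise InputError("detect_events expects a dff-kind TraceMatrix")
    if not 0 < corr_thresh <= 1:
        raise ParameterError("corr_thresh must lie in (0, 1]")
    if templates is None:
        templates = build_template_library(fps=dff.fps)
    frames, amps = {}, {}
    for j, ch in enumerate(dff.labels):
        f, a = _detect_channel(
            dff.values[:, j], templates, dff.fps, amp_thresh, corr_thresh, min_sep_s
        )
        frames[ch], amps[ch] = f, a
    return EventTrain(frames, amps, fps=dff.fps, n_frames=dff.n_frames)


def apply_manual_corrections(train: EventTrain, edits: list[dict]) -> EventTrain:
    """Apply reviewed add/delete edits to an event train.

    Each edit is ``{"action": "add"|"delete", "channel": str, "frame": int,
    "amplitude": float (adds only)}``.  Deleting a timestamp that does not
    exist raises :class:`EditError`.  The returned train carries an audit log
    of every edit applied.
    """
    frames = {ch: list(f) for ch, f in train.frames.items()}
    amps = {ch: list(a) for ch, a in train.amplitudes.items()}
    audit = list(train.audit_log)
    for e in edits:
        action = e["action"]
        ch = e["channel"]
        frame = int(e["frame"])
        if ch not in frames:
            raise EditError(f"unknown channel {ch!r}")
        if action == "delete":
            if frame not in frames[ch]:
                raise EditError(f"no event at frame {frame} in channel {ch!r}")
            i = frames[ch].index(frame)
            del frames[ch][i]
            del amps[ch][i]
        elif action == "add":
            if frame in frames[ch]:
                raise EditError(f"event already exists at frame {frame} in {ch!r}")
            frames[ch].append(frame)
            amps[ch].append(float(e["amplitude"]))
            order = np.argsort(frames[ch])
            frames[ch] = [frames[ch][k] for k in order]
            amps[ch] = [amps[ch][k] for k in order]
        else:
            raise EditError(f"unknown action {action!r}")
        audit.append(dict(e))
    return EventTrain(
        {ch: np.array(f, dtype=int) for ch, f in frames.items()},
        {ch: np.array(a, dtype=float) for ch, a in amps.items()},
        fps=train.fps,
        n_frames=train.n_frames,
        audit_log=audit,
    )


def firing_rate(train: EventTrain, per_s: float = 300.0) -> dict[str, float]:
    """Event count per channel scaled to a ``per_s``-second epoch (default 5 min)."""
    if not per_s > 0:
        raise ParameterError("per_s must be positive")
    epoch = train.n_frames / train.fps
    return {ch: len(f) * per_s / epoch for ch, f in train.frames.items()}
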