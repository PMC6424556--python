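"""Seizure propagation: onset timing, normalized lags, tercile statistics.

Within each ictal event window, a region's onset is the time of the maximum
of the first difference of the 50-point centered moving average of its dF/F
trace (the point of fastest fluorescence rise).  Onsets are converted to
relative lags (vs the earliest region in that event), normalized to [0, 1]
over the earliest-to-latest interval, rank-assigned to terciles (ranks 1-4
early, 5-8 middle, 9-12 late for 12 bilateral channels), and the resulting
6-region x 3-tercile contingency table is tested for independence with a
Pearson chi-square test (df = 10).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import REGIONS, TraceMatrix, region_of
from .events import EventTrain
from .exceptions import InputError, ParameterError

log = logging.getLogger(__name__)

TERCILES = ("early", "middle", "late")


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with the window truncated at the edges."""
    x = np.asarray(x, dtype=float)
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def ictal_windows_from_events(
    train: EventTrain,
    reference: str = "cerebellum_left",
    pre_s: float = 5.0,
    post_s: float = 15.0,
) -> list[tuple[float, float]]:
    """Ictal search windows around each reference-channel event.

    The cerebellum channel is the conventional brain-wide event indicator;
    each window spans event start minus ``pre_s`` to event start plus
    ``post_s`` seconds, clipped to the epoch.
    """
    if reference not in train.frames:
        raise InputError(f"reference channel {reference!r} not in event train")
    epoch = train.n_frames / train.fps
    wins = []
    for f in train.frames[reference]:
        t = f / train.fps
        wins.append((max(0.0, t - pre_s), min(epoch, t + post_s)))
    return wins


def detect_onsets(
    dff: TraceMatrix,
    ictal_windows: list[tuple[float, float]],
    smooth_n: int = 50,
    edge_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-event, per-channel onset times from the smoothed-derivative maximum.

    With ``smooth_n`` points of smoothing, a fast fluorescence rise flattens
    the slope maximum into a plateau whose exact argmax is set by noise; the
    onset is therefore taken as the first frame at which the smoothed slope
    reaches ``edge_fraction`` of its window maximum (default the half-maximum
    leading edge).  ``edge_fraction=0`` recovers the strict argmax.

    Returns a DataFrame with columns ``event``, ``roi``, ``onset_s``.  Events
    whose window spans fewer than ``smooth_n`` samples are skipped with a log
    entry.
    """
    if not 0 <= edge_fraction < 1:
        raise ParameterError("edge_fraction must lie in [0, 1)")
    if dff.kind != "dff":
        raise InputError("detect_onsets expects a dff-kind TraceMatrix")
    if smooth_n < 2:
        raise ParameterError("smooth_n must be at least 2")
    smoothed = np.column_stack(
        [moving_average(dff.values[:, j], smooth_n) for j in range(dff.n_channels)]
    )
    slope = np.diff(smoothed, axis=0)
    rows = []
    for e, (t0, t1) in enumerate(ictal_windows):
        a = max(0, int(round(t0 * dff.fps)))
        b = min(dff.n_frames - 1, int(round(t1 * dff.fps)))
        if b - a < smooth_n:
            log.warning("event %d window [%.2f, %.2f] s too short; skipped", e, t0, t1)
            continue
        for j, ch in enumerate(dff.labels):
            s = slope[a:b, j]
            if edge_fraction > 0 and s.max() > 0:
                thr = edge_fraction * s.max()
                i = int(np.argmax(s >= thr))
                # sub-frame interpolation of the crossing avoids frame-grid
                # ties, which would otherwise all break anterior-first
                if i > 0 and s[i] > s[i - 1]:
                    i = i - 1 + (thr - s[i - 1]) / (s[i] - s[i - 1])
            else:
                i = int(np.argmax(s))
            rows.append((e, ch, (a + i + 0.5) / dff.fps))
    return pd.DataFrame(rows, columns=["event", "roi", "onset_s"])


def normalized_lags(onsets: pd.DataFrame) -> pd.DataFrame:
    """Relative and normalized lags per event.

    Adds ``rel_lag_s`` (onset minus the event's earliest onset), ``norm_lag``
    (rescaled to [0, 1] over the earliest-to-latest interval) and a
    ``degenerate`` flag for events where all onsets coincide (excluded from
    tercile analysis downstream).  Single-channel events are dropped.
    """
    out = []
    for e, grp in onsets.groupby("event", sort=True):
        if len(grp) < 2:
            log.warning("event %s has a single ROI onset; skipped", e)
            continue
        g = grp.copy()
        lo, hi = g["onset_s"].min(), g["onset_s"].max()
        g["rel_lag_s"] = g["onset_s"] - lo
        span = hi - lo
        if span == 0:
            g["norm_lag"] = 0.0
            g["degenerate"] = True
        else:
            g["norm_lag"] = g["rel_lag_s"] / span
            g["degenerate"] = False
        out.append(g)
    if not out:
        return pd.DataFrame(
            columns=["event", "roi", "onset_s", "rel_lag_s", "norm_lag", "degenerate"]
        )
    return pd.concat(out, ignore_index=True)


def tercile_groups(
    lags: pd.DataFrame, channel_order: list[str] | None = None
) -> pd.DataFrame:
    """Rank-based tercile labels per event.

    Within each (non-degenerate) event the normalized lags are rank-ordered
    — ties broken by anterior-first channel order — and split into thirds:
    the earliest third "early", then "middle", then "late".
    """
    rows = []
    for e, grp in lags.groupby("event", sort=True):
        if grp["degenerate"].any():
            continue
        g = grp.reset_index(drop=True)
        if channel_order is not None:
            pos = np.array([channel_order.index(r) for r in g["roi"]])
        else:
            pos = np.arange(len(g))
        order = np.lexsort((pos, g["norm_lag"].to_numpy()))
        n = len(g)
        third = n // 3
        labels = np.empty(n, dtype=object)
        labels[order[:third]] = "early"
        labels[order[third : 2 * third]] = "middle"
        labels[order[2 * third :]] = "late"
        g["tercile"] = labels
        rows.append(g)
    if not rows:
        return pd.DataFrame(columns=list(lags.columns) + ["tercile"])
    return pd.concat(rows, ignore_index=True)


def region_tercile_probabilities(labeled: pd.DataFrame) -> pd.DataFrame:
    """P(region in tercile) over all events; rows sum to 1."""
    counts = region_tercile_counts(labeled)
    return counts.div(counts.sum(axis=1), axis=0)


def region_tercile_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """6-region x 3-tercile contingency counts (2 data points per region/event)."""
    df = labeled.copy()
    df["region"] = [region_of(r) for r in df["roi"]]
    counts = pd.crosstab(df["region"], df["tercile"])
    counts = counts.reindex(
        index=[r for r in REGIONS if r in counts.index],
        columns=[t for t in TERCILES if t in counts.columns],
        fill_value=0,
    )
    return counts


def onset_chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table."""
    table = np.asarray(counts, dtype=float)
    if (table < 0).any():
        raise InputError("contingency counts must be nonnegative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise InputError(
            "contingency table has an all-zero row or column; pool sparse "
            "categories before testing"
        )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        raise InputError("zero expected cell; pool sparse categories")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class OnsetTable:
    """Full propagation result: per-ROI onset/lag table plus the group test."""

    table: pd.DataFrame
    contingency: pd.DataFrame
    chi2: float
    dof: int
    pvalue: float

    def region_probabilities(self) -> pd.DataFrame:
        return self.contingency.div(self.contingency.sum(axis=1), axis=0)


def propagation_analysis(
    dff: TraceMatrix,
    ictal_windows: list[tuple[float, float]],
    smooth_n: int = 50,
    edge_fraction: float = 0.5,
) -> OnsetTable:
    """Onsets -> lags -> terciles -> chi-square, end to end."""
    onsets = detect_onsets(dff, ictal_windows, smooth_n=smooth_n,
                           edge_fraction=edge_fraction)
    lags = normalized_lags(onsets)
    labeled = tercile_groups(lags, channel_order=list(dff.labels))
    counts = region_tercile_counts(labeled)
    chi2, dof, p = onset_chi_square(counts)
    return OnsetTable(table=labeled, contingency=counts, chi2=chi2, dof=dof, pvalue=p)
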