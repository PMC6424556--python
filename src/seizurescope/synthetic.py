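"""Synthetic data generator for the whole pipeline.

Emulates the three experimental conditions of an acute zebrafish seizure
preparation imaged at 20 Hz:

* ``control`` — noise-only regional traces (no paroxysmal transients);
* ``ptz`` — recurrent high-amplitude (dF/F 1-3), long-duration (5-15 s)
  ictal-like transients at ~1-2 events/min, present in all twelve bilateral
  region channels with a planted anterior-to-posterior onset-lag profile;
* ``4ap`` — frequent small (dF/F 0.1-0.3), short (0.5-2 s) transients
  restricted to the cerebellum and hindbrain channels.

It also builds single-neuron event rasters with planted coactive ensembles,
LFP traces whose burst durations are coupled to the planted calcium event
durations (amplitudes independent), and small rendered image stacks so ROI
extraction can be tested end to end.  Every generator records its ground
truth, and a given (config, seed) pair is bit-reproducible.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import REGION_CHANNELS, REGIONS, RoiSet, TraceMatrix
from .exceptions import ParameterError

#: Default anterior-to-posterior onset-lag profile (seconds per region).
#: Ordering matters scientifically; magnitudes are free generator parameters.
DEFAULT_LAG_PROFILE = {
    "pallium": 0.0,
    "habenula": 0.1,
    "neuropil": 0.25,
    "spv": 0.35,
    "cerebellum": 0.5,
    "hindbrain": 0.7,
}

#: Channels carrying 4-AP transients (posterior hindbrain/cerebellum only).
FOURAP_CHANNELS = tuple(
    c for c in REGION_CHANNELS if c.startswith(("cerebellum", "hindbrain"))
)


@dataclass
class SimConfig:
    """Generator configuration.

    Defaults mirror the experimental recording conditions the pipeline is
    designed for: 5-min epochs at 20 Hz, 12 bilateral region channels,
    ~75 tectal neurons, GCaMP6f-like kernel (0.1 s rise, 1 s decay).
    """

    fps: float = 20.0
    duration_s: float = 300.0
    n_regions: int = 12
    n_neurons: int = 75
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.0
    noise_sd: float = 0.05          # dF/F units
    baseline_f: float = 100.0       # camera units
    ictal_rate_per_min: float = 1.5
    ictal_amp_range: tuple[float, float] = (1.0, 3.0)
    ictal_dur_range_s: tuple[float, float] = (5.0, 15.0)
    fourap_rate_per_min: float = 8.0
    fourap_amp_range: tuple[float, float] = (0.1, 0.3)
    fourap_dur_range_s: tuple[float, float] = (0.5, 2.0)
    lag_profile_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAG_PROFILE)
    )
    lag_jitter_sd_s: float = 0.1
    background_rate: float = 0.001  # events per frame per neuron

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ParameterError("fps must be positive")
        if not self.duration_s > 0:
            raise ParameterError("duration must be positive")
        if not (self.kernel_decay_s > self.kernel_rise_s > 0):
            raise ParameterError("kernel requires decay > rise > 0")
        for name in ("noise_sd", "ictal_rate_per_min", "fourap_rate_per_min",
                     "background_rate", "lag_jitter_sd_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if set(self.lag_profile_s) != set(REGIONS):
            raise ParameterError("lag profile must name exactly the six regions")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """Planted truth accompanying every simulated dataset."""

    condition: str
    seed: int
    fps: float
    duration_s: float
    channels: list[str]
    event_times_s: np.ndarray                    # (n_events,) global onsets
    event_durations_s: np.ndarray                # (n_events,)
    event_amplitudes: np.ndarray                 # (n_events,) peak dF/F
    onset_lags_s: np.ndarray                     # (n_events, n_channels)
    per_channel_event_times: dict[str, np.ndarray]
    event_frames: dict[str, np.ndarray] = field(default_factory=dict)
    ensembles: list[tuple[int, np.ndarray]] = field(default_factory=list)
    lfp_durations_s: np.ndarray | None = None

    @property
    def n_events(self) -> int:
        return len(self.event_times_s)

    def to_dict(self) -> dict:
        """JSON-serializable representation."""
        d = dataclasses.asdict(self)
        for k in ("event_times_s", "event_durations_s", "event_amplitudes",
                  "onset_lags_s"):
            d[k] = np.asarray(d[k]).tolist()
        d["per_channel_event_times"] = {
            k: np.asarray(v).tolist() for k, v in self.per_channel_event_times.items()
        }
        d["event_frames"] = {
            k: np.asarray(v).tolist() for k, v in self.event_frames.items()
        }
        d["ensembles"] = [[int(f), np.asarray(m).tolist()] for f, m in self.ensembles]
        if self.lfp_durations_s is not None:
            d["lfp_durations_s"] = np.asarray(self.lfp_durations_s).tolist()
        return d


def generate_calcium_kernel(
    rise_s: float, decay_s: float, fps: float, duration_s: float
) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient kernel.

    k(t) = exp(-t/decay) - exp(-t/rise), normalized so max(k) == 1.  The
    closed-form peak sits at t* = ln(decay/rise) * rise*decay / (decay-rise).

    Parameters are in seconds; the returned waveform has
    ``round(duration_s * fps)`` samples.
    """
    if not (decay_s > rise_s > 0):
        raise ParameterError(
            f"kernel requires decay > rise > 0, got rise={rise_s}, decay={decay_s}"
        )
    if not fps > 0 or not duration_s > 0:
        raise ParameterError("fps and duration must be positive")
    n = int(round(duration_s * fps))
    if n < 1:
        raise ParameterError("kernel would have zero samples")
    t = np.arange(n) / fps
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:  # pragma: no cover - excluded by decay > rise
        raise ParameterError("degenerate kernel")
    return k / peak


def ictal_waveform(duration_s: float, fps: float, rise_s: float = 0.3,
                   taper_s: float = 0.8) -> np.ndarray:
    """Unit-peak ictal-like transient of (approximately) known duration.

    Fast rise, exponential decay reaching 25% of peak at ``duration_s``, then
    a half-cosine taper to zero over ``taper_s``.  The compact support makes
    the baseline-crossing duration measured downstream nearly independent of
    the event amplitude, which is what couples calcium and LFP durations in
    the simulation.
    """
    if duration_s <= 2 * rise_s:
        raise ParameterError("ictal duration too short for its rise time")
    decay = duration_s / np.log(4.0)
    n = int(round((duration_s + taper_s) * fps))
    t = np.arange(n) / fps
    w = np.exp(-t / decay) - np.exp(-t / rise_s)
    w /= w.max()
    in_taper = t > duration_s
    w[in_taper] *= 0.5 * (1.0 + np.cos(np.pi * (t[in_taper] - duration_s) / taper_s))
    w[t > duration_s + taper_s] = 0.0
    return np.clip(w, 0.0, None)


def _renewal_event_schedule(rng, rate_per_min, duration_s, dur_range):
    """Jittered-renewal ictal schedule: gaps = (60/rate)*U(0.85,1.15).

    Events are kept only if the full transient (plus a 2-s guard) fits in the
    epoch. At 1.5/min over 300 s this yields 6-9 events for every seed.
    """
    base = 60.0 / rate_per_min
    times, durs = [], []
    t = rng.uniform(2.0, 20.0)
    while True:
        dur = rng.uniform(*dur_range)
        if t + dur + 2.0 > duration_s:
            break
        times.append(t)
        durs.append(dur)
        t += base * rng.uniform(0.85, 1.15)
    return np.array(times), np.array(durs)


def simulate_region_traces(
    cfg: SimConfig, condition: str, seed: int
) -> tuple[TraceMatrix, GroundTruth]:
    """Simulate the 12 bilateral region channels for one condition.

    Raw fluorescence is ``baseline * (1 + dF/F signal) + Gaussian noise``.
    PTZ transients carry the anterior-to-posterior lag profile (with per-event
    Gaussian jitter); 4-AP transients are restricted to cerebellum/hindbrain
    channels; control is noise only.
    """
    if condition not in ("control", "ptz", "4ap"):
        raise ParameterError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    labels = list(REGION_CHANNELS)
    n = cfg.n_frames
    sig = np.zeros((n, len(labels)))

    if condition == "control":
        times = np.array([])
        durs = np.array([])
        amps = np.array([])
        lags = np.zeros((0, len(labels)))
        active = labels
    elif condition == "ptz":
        times, durs = _renewal_event_schedule(
            rng, cfg.ictal_rate_per_min, cfg.duration_s, cfg.ictal_dur_range_s
        )
        amps = rng.uniform(*cfg.ictal_amp_range, size=len(times))
        base_lag = np.array([cfg.lag_profile_s[c.rsplit("_", 1)[0]] for c in labels])
        lags = base_lag[None, :] + rng.normal(
            0.0, cfg.lag_jitter_sd_s, size=(len(times), len(labels))
        )
        active = labels
    else:  # 4ap
        times, durs = _renewal_event_schedule(
            rng, cfg.fourap_rate_per_min, cfg.duration_s, cfg.fourap_dur_range_s
        )
        amps = rng.uniform(*cfg.fourap_amp_range, size=len(times))
        active = list(FOURAP_CHANNELS)
        lags = np.zeros((len(times), len(labels)))
        cols = [labels.index(c) for c in active]
        lags[:, cols] = rng.normal(0.0, 0.02, size=(len(times), len(cols)))

    taper = 0.8 if condition == "ptz" else 0.2
    rise = 0.3 if condition == "ptz" else 0.1
    for i, (t0, dur, amp) in enumerate(zip(times, durs, amps)):
        w = amp * ictal_waveform(dur, cfg.fps, rise_s=rise, taper_s=taper)
        for c in active:
            j = labels.index(c)
            start = int(round((t0 + lags[i, j]) * cfg.fps))
            stop = min(start + len(w), n)
            if start < 0 or start >= n:
                continue
            sig[start:stop, j] += w[: stop - start]

    raw = cfg.baseline_f * (1.0 + sig) + rng.normal(
        0.0, cfg.noise_sd * cfg.baseline_f, size=sig.shape
    )
    traces = TraceMatrix(raw, fps=cfg.fps, labels=labels, kind="raw")
    per_channel = {}
    for j, c in enumerate(labels):
        if c in active and len(times):
            per_channel[c] = times + lags[:, j]
        else:
            per_channel[c] = np.array([])
    gt = GroundTruth(
        condition=condition,
        seed=int(seed),
        fps=cfg.fps,
        duration_s=cfg.duration_s,
        channels=labels,
        event_times_s=times,
        event_durations_s=durs,
        event_amplitudes=amps,
        onset_lags_s=lags,
        per_channel_event_times=per_channel,
    )
    return traces, gt


def simulate_neuron_raster(
    cfg: SimConfig,
    planted_ensembles: list[tuple[int, np.ndarray]] | None = None,
    seed: int = 0,
    ensemble_window: int = 10,
) -> tuple[TraceMatrix, GroundTruth]:
    """Simulate single-neuron traces with sparse background + planted ensembles.

    Background events are independent Bernoulli draws per neuron per frame at
    ``cfg.background_rate``.  Each planted ensemble ``(frame, member_ids)``
    gives every member exactly one event at a uniformly random offset within
    ``[frame, frame + ensemble_window)``.  Traces are the kernel-convolved
    event trains mapped onto raw fluorescence plus noise.

    The binary raster is recoverable via :func:`event_raster`.
    """
    planted_ensembles = planted_ensembles or []
    rng = np.random.default_rng(seed)
    n, n_neu = cfg.n_frames, cfg.n_neurons
    for f, members in planted_ensembles:
        if not (0 <= f <= n - ensemble_window):
            raise ParameterError(f"ensemble frame {f} outside the epoch")
        members = np.asarray(members)
        if members.size and (members.min() < 0 or members.max() >= n_neu):
            raise ParameterError("ensemble member ids out of range")
        if members.size > n_neu:
            raise ParameterError("more members than neurons")

    raster = rng.random((n, n_neu)) < cfg.background_rate
    planted = []
    for f, members in planted_ensembles:
        members = np.asarray(members, dtype=int)
        offs = rng.integers(0, ensemble_window, size=len(members))
        raster[f + offs, members] = True
        planted.append((int(f), members))

    kernel = generate_calcium_kernel(
        cfg.kernel_rise_s, cfg.kernel_decay_s, cfg.fps, 5 * cfg.kernel_decay_s
    )
    amps = rng.uniform(0.3, 0.8, size=raster.shape) * raster
    sig = np.empty_like(amps)
    for j in range(n_neu):
        sig[:, j] = np.convolve(amps[:, j], kernel)[:n]
    raw = cfg.baseline_f * (1.0 + sig) + rng.normal(
        0.0, cfg.noise_sd * cfg.baseline_f, size=sig.shape
    )
    labels = [f"neuron_{j}" for j in range(n_neu)]
    traces = TraceMatrix(raw, fps=cfg.fps, labels=labels, kind="raw")

    frames = {lab: np.flatnonzero(raster[:, j]) for j, lab in enumerate(labels)}
    gt = GroundTruth(
        condition="raster",
        seed=int(seed),
        fps=cfg.fps,
        duration_s=cfg.duration_s,
        channels=labels,
        event_times_s=np.array([]),
        event_durations_s=np.array([]),
        event_amplitudes=np.array([]),
        onset_lags_s=np.zeros((0, n_neu)),
        per_channel_event_times={k: v / cfg.fps for k, v in frames.items()},
        event_frames=frames,
        ensembles=planted,
    )
    return traces, gt


def event_raster(gt: GroundTruth, n_frames: int | None = None) -> np.ndarray:
    """Binary (n_frames, n_channels) raster rebuilt from planted event frames."""
    n = n_frames or int(round(gt.duration_s * gt.fps))
    raster = np.zeros((n, len(gt.channels)), dtype=bool)
    for j, lab in enumerate(gt.channels):
        fr = gt.event_frames.get(lab)
        if fr is None:
            fr = np.round(gt.per_channel_event_times[lab] * gt.fps).astype(int)
        fr = np.asarray(fr, dtype=int)
        raster[fr[(fr >= 0) & (fr < n)], j] = True
    return raster


@dataclass
class LfpSim:
    """A simulated single-channel LFP recording with its planted burst truth."""

    values: np.ndarray
    fps: float
    burst_starts_s: np.ndarray
    burst_durations_s: np.ndarray
    burst_amplitudes: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps


def simulate_lfp(
    gt: GroundTruth,
    duration_jitter_sd_s: float = 0.0,
    fps_lfp: float = 200.0,
    seed: int = 0,
    noise_sd: float = 0.02,
    carrier_hz: tuple[float, float] = (4.0, 10.0),
    amp_range: tuple[float, float] = (0.5, 2.0),
) -> LfpSim:
    """Simulate an LFP trace whose bursts shadow the planted calcium events.

    Each ictal event contributes an oscillatory burst starting at the planted
    event time, of duration = planted duration + Gaussian jitter, and of an
    amplitude drawn *independently* of the calcium amplitude (the experimental
    dissociation this pipeline quantifies).  The baseline is 40-Hz low-passed
    Gaussian noise.  Burst envelopes are narrow-tapered (Tukey, alpha=0.06) so
    the realized burst duration is sharply defined.
    """
    rng = np.random.default_rng(seed)
    n = int(round(gt.duration_s * fps_lfp))
    x = signal.sosfiltfilt(
        signal.butter(4, min(40.0, 0.45 * fps_lfp), fs=fps_lfp, output="sos"),
        rng.normal(0.0, 1.0, size=n),
    )
    x = noise_sd * x / max(x.std(), 1e-12)

    starts, durs, amps = [], [], []
    for t0, d0 in zip(gt.event_times_s, gt.event_durations_s):
        d = d0 + rng.normal(0.0, duration_jitter_sd_s)
        d = max(d, 0.5)
        amp = rng.uniform(*amp_range)
        f = rng.uniform(*carrier_hz)
        phase = rng.uniform(0.0, 2 * np.pi)
        m = int(round(d * fps_lfp))
        i0 = int(round(t0 * fps_lfp))
        if i0 >= n:
            continue
        m = min(m, n - i0)
        tau = np.arange(m) / fps_lfp
        burst = amp * np.sin(2 * np.pi * f * tau + phase)
        burst *= signal.windows.tukey(m, alpha=0.06)
        x[i0 : i0 + m] += burst
        starts.append(t0)
        durs.append(m / fps_lfp)
        amps.append(amp)
    return LfpSim(
        values=x,
        fps=fps_lfp,
        burst_starts_s=np.array(starts),
        burst_durations_s=np.array(durs),
        burst_amplitudes=np.array(amps),
    )


def render_movie(
    traces: TraceMatrix,
    rois: RoiSet,
    frame_shape: tuple[int, int] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dtype=np.uint16,
) -> np.ndarray:
    """Render traces into a multi-page grayscale image stack.

    Every pixel inside ROI r at frame t takes that channel's fluorescence
    value plus i.i.d. Gaussian noise; pixels outside all ROIs are noise around
    zero.  One ROI per trace channel, in order.  RoiSet construction already
    rejects overlapping masks; a ``frame_shape`` differing from the mask
    geometry means the masks do not fit the requested frame.
    """
    if len(rois) != traces.n_channels:
        raise ParameterError(
            f"{len(rois)} ROIs for {traces.n_channels} trace channels"
        )
    if frame_shape is not None and tuple(frame_shape) != rois.frame_shape:
        raise ParameterError(
            f"ROI masks of shape {rois.frame_shape} do not fit frame {frame_shape}"
        )
    rng = np.random.default_rng(seed)
    h, w = rois.frame_shape
    stack = np.zeros((traces.n_frames, h, w), dtype=np.float64)
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    for j, roi in enumerate(rois):
        stack[:, roi.mask] += traces.values[:, j][:, None]
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        stack = np.clip(np.rint(stack), info.min, info.max)
    return stack.astype(dtype)
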