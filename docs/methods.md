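# Methods

This note documents the models, parameter choices and numerical conventions
behind each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## ΔF/F normalization

The baseline at sample t is the mean of the lowest ⌈f·n⌉ values among the n
samples in the causal window (t − W, t], with W = 10 s and f = 0.5 by
default. During the warm-up (t < W) the partial window (0, t] is used, so
the first sample's baseline is F[0] and ΔF/F[0] = 0; this keeps the
transform causal without discarding the first ten seconds. ΔF/F may be
negative (no rectification at this stage); the AUC summary rectifies before
integrating (trapezoidal) and divides by the epoch length, so a unit-height
10-s plateau in a 300-s epoch scores 1/30.

The fast path partitions each window and sorts only the lower slice, which
is arithmetically identical (same summands, same order) to a full
per-window sort — the property tests assert bit-exact agreement with a
brute-force oracle. Gain invariance (ΔF/F(cF) = ΔF/F(F)) and causality are
tested directly.

Caveat: during transients longer than the window the baseline starts
climbing into the event itself, compressing measured ΔF/F late in long
events and producing a small post-event undershoot. This is inherent to a
causal percentile-style baseline and is shared by the analyses downstream.

## Event detection

Detection correlates the trace with a library of unit-peak
difference-of-exponential templates, k(t) ∝ e^{−t/τ_d} − e^{−t/τ_r}. The
default grid is τ_r ∈ {0.05, 0.25} s and τ_d ∈ {0.3, 0.6, 1, 2, 3, 5, 7,
10} s with template span min(5 τ_d, 16 s); spans therefore run from 1.5 s
(short interictal transients) to 16 s (ictal events). Sub-second templates
are deliberately not in the default grid: at 20 Hz a 0.5-s window has 10
samples, and a 10-sample Pearson correlation exceeds 0.85 by chance far too
often (null sd ≈ 1/3) for the standard threshold to be selective. Custom
grids can restore them for higher-rate data. Near the end of the trace,
templates are end-truncated (to ≥ ~1 s) so late events keep a matched span.

Candidate timestamps are strict local maxima of the per-time maximum
correlation over templates (plateaus take their first frame; zero-variance
windows score 0, not NaN). A candidate becomes an event iff its correlation
exceeds 0.85 and its *amplitude* — the peak ΔF/F within the matched
template span minus the value at the candidate frame — exceeds 0.1. The
amplitude is defined as a local rise deliberately: a window sliding down
the decay tail of a large transient correlates > 0.85 with decay-dominated
templates at every alignment but shows no rise, so the rise criterion is
what makes one transient produce one event. Surviving candidates then pass
greedy non-maximum suppression (highest correlation first): an accepted
event suppresses candidates within min_sep (1 s default) or inside its
matched template span. Because a suppressed candidate always has lower
correlation than its suppressor, raising either threshold can only shrink
the event set — the monotonicity property test checks this.

On the default synthetic PTZ condition (SNR ≥ 20), detection recovers
planted events with recall and precision 1.0 at a ±10-frame matching
tolerance (the acceptance tests require ≥ 0.9).

## Synchronization

Instantaneous phase is the angle of the Hilbert analytic signal of the
mean-removed ΔF/F trace. No band-pass is applied by default — ΔF/F traces
are already slow — but the phase input is a plain array, so any filtering
can be composed upstream. A constant trace has no defined phase and raises.

The pairwise matrix holds phase-locking values; the global index maps the
largest eigenvalue of the symmetric matrix onto [0, 1] as
(λ_max − 1)/(N − 1), clipped. This is the simplest normalization satisfying
both limit cases: an all-ones matrix (λ_max = N) scores 1, and both the
identity matrix (independent channels, λ_max = 1) and the all-zero
idealization (λ_max = 0) score 0. Surrogate-based significance correction
of the index is out of scope. The index is invariant to channel
permutations, and λ_max is monotone in the off-diagonal entries (checked
numerically).

## Seizure propagation

Within each ictal window (default: event start − 2 s to event end, from
ground truth or from reference-channel events; cerebellum is the
conventional brain-wide indicator), each channel's onset comes from the
first difference of the 50-point centered moving average (window truncated
at the trace edges). Two numerical refinements matter at 20 Hz:

* The 2.5-s smoothing span exceeds a fast ictal rise, so the smoothed slope
  saturates into an exact plateau and its argmax is decided by noise
  (within-event onset scatter ~0.19 s, twice the biological lag spacing of
  interest). The default onset is therefore the *half-maximum leading edge*
  of the slope — the first frame where the slope reaches 50% of its window
  maximum — which cuts the scatter to ~0.03 s. `edge_fraction=0` restores
  the strict argmax.
* The crossing is interpolated between frames. Without sub-frame
  resolution, onsets quantize to the 0.05-s frame grid, within-event ties
  become common, and the deterministic anterior-first tie-break imprints a
  spurious anterior-to-posterior ordering on null data.

Relative lags subtract the event's earliest onset; normalized lags divide
by the earliest-to-latest interval, so each event maps onto [0, 1]. Events
with zero interval are flagged degenerate and excluded from tercile
analysis; single-channel events are skipped. Terciles are rank-based (ranks
1–4 early, 5–8 middle, 9–12 late for 12 bilateral channels) rather than
thresholded at 1/3 and 2/3 — rank-based grouping is degenerate-proof and
gives each event exactly 4 points per tercile. Boundary ties break
anterior-first and are logged.

The 6-region × 3-tercile table (2 points per region per event — left and
right channels) is tested with a Pearson χ² of independence, df = 10.
Because each event's 12 points fill the terciles exactly 4/4/4, the table
is rank-constrained rather than multinomial, and the χ²(10) reference is
slightly anticonservative: with flat lag profiles the test is
non-significant at α = 0.05 in ~90% of simulated datasets (~93% when fed
ground-truth lags). With the default anterior-to-posterior lag profile the
planted region ordering is recovered exactly by mean normalized lag and
rejected at p < 0.001 with ~30 events.

## Neuronal ensembles

Coactivity counts the neurons with ≥ 1 event in each 10-frame (0.5-s)
sliding window; a neuron spiking twice in a window counts once. The null
pools the coactivity counts of 2000 surrogates (200 in the bounded-runtime
tests), each a full independent permutation of every neuron's binary event
vector — per-neuron event counts are conserved, all timing is destroyed. A
circular-shift surrogate would preserve within-neuron ISI structure, but
the background model is Bernoulli so the full permutation is exact here.
The significance threshold is the (1 − α) empirical quantile of the pooled
null taken as an order statistic (no interpolation), with α = 0.001, and
flagging requires *strictly* exceeding it. Runs of consecutive flagged
window positions merge into one ensemble event spanning first position
through last position + window; members are the neurons active in that
span. Ensemble centroids are member-centroid means; member distances are
Euclidean.

Observed false-flag rates on null rasters are well inside
α + 3·√(α/n_windows), and a planted 12-of-80-neuron ensemble over 0.002
events/frame/neuron background is recovered with all members in ≥ 9/10
seeds. For recordings containing ictal events, `mask_ictal_frames` zeroes
the raster within ±2 s of each event before analysis, since brain-wide
events would otherwise dominate the coactivity series.

## LFP / calcium event features

Per event, baseline = median of the 5 s preceding the span; noise scale =
1.4826·MAD of the same window; amplitude = max |trace − baseline| within
the span; duration = first-to-last sample of the cleaned supra-threshold
mask (|deviation| > k·SD, k = 3). Mask cleaning is morphological:
sub-threshold gaps < 0.15 s are closed — bridging the zero crossings of an
oscillatory burst — and supra-threshold runs < 0.5 s are dropped —
rejecting isolated noise excursions that would otherwise stretch the
measured duration to whatever outlier happens to sit in the span. Events
with no surviving crossing are excluded with a log entry. A Butterworth
band-limit helper (0.1 Hz high-pass, 1 kHz low-pass when below Nyquist)
mirrors a typical acquisition chain. Paired events are matched by shared
event id and summarized by squared Pearson correlations; zero-variance
features define R² = 0 with a warning.

## The synthetic-data generator

The generator is the package's stand-in for the in-vivo recordings and
defines the study conditions:

* **Epoch**: 300 s at 20 Hz (6000 frames), 12 bilateral region channels,
  75 neurons. Raw F = 100·(1 + ΔF/F) + N(0, 5) camera units (noise sd 0.05
  ΔF/F units per frame).
* **PTZ**: ictal events with amplitude U(1, 3) ΔF/F and nominal duration
  U(5, 15) s, scheduled by a jittered renewal process (gap =
  (60/rate)·U(0.85, 1.15), first event U(2, 20) s) at 1.5/min — which
  yields 6–9 events per 5-min epoch for every seed, matching a 1–2/min
  regime. The transient is a fast-rise (0.3 s) exponential decay reaching
  25% of peak at the nominal duration, then a 0.8-s half-cosine taper to
  zero; the compact support makes the measured baseline-crossing duration
  nearly amplitude-independent. Onset lags per region follow the
  anterior-to-posterior profile (pallium 0, habenula 0.1, neuropil 0.25,
  SPV 0.35, cerebellum 0.5, hindbrain 0.7 s) plus N(0, 0.1 s) per event and
  channel; only the ordering is biologically anchored, the magnitudes are
  free parameters.
* **4-AP**: the same machinery confined to the four cerebellum/hindbrain
  channels, at 8/min with amplitude U(0.1, 0.3) and duration U(0.5, 2) s.
* **Control**: noise only.
* **Neuron rasters**: independent Bernoulli background events
  (0.001/frame/neuron) plus planted ensembles — each member gets exactly
  one event at a uniform offset within the 10-frame coactivation window.
  Traces are kernel-convolved (GCaMP6f-like, 0.1 s rise / 1 s decay) event
  trains on the same raw-F model.
* **LFP**: 40-Hz low-passed noise baseline (sd 0.02) plus one oscillatory
  burst per ictal event — carrier U(4, 10) Hz, Tukey(0.06) envelope,
  duration = planted calcium duration + N(0, jitter), amplitude U(0.5, 2)
  drawn *independently* of the calcium amplitude. Sampled at 200 Hz
  (down-sampled relative to real acquisition; features are band-limited far
  below that).
* **Movies**: per-pixel Gaussian noise around each channel's F inside its
  ROI mask, 16-bit grayscale; extraction recovers traces within
  noise/√(ROI area).

Everything is driven by one `numpy` Generator per call and is
bit-reproducible from (config, seed).

What the generator does **not** emulate: motion artifacts, photobleaching,
optical blur/PSF, neuropil contamination, region-correlated noise,
indicator saturation, interictal spikes, or any biophysical network
dynamics. Passing tests therefore demonstrate that the *analysis chain* is
correct and calibrated under its stated assumptions — not that it is robust
to every nuisance present in real recordings; the manual-correction and
configurable-parameter surfaces exist precisely because real data will
violate these assumptions.

## Pipeline and reproducibility

`run_pipeline` executes simulate/extract → ΔF/F → detection →
{synchronization, propagation, ensembles, LFP correlation} from one JSON
config, deriving per-stage seeds from the base seed and writing a manifest
(package version, parameters, seeds, SHA-256 checksums of all outputs). The
manifest carries no timestamps; timings go to the log file, so identical
config+seed re-runs are byte-identical in every data output. The bounded
problem sizes used in the test suite (e.g. 200 shuffles, 120-s pipeline
epochs, pooled cohorts of 5–8 simulated fish) are chosen so the full suite
exercises every stage at realistic statistical power while remaining quick
to run; all figures/outputs are headless-safe plain text.
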