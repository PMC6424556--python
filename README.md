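# seizurescope

Multi-scale analysis of seizure networks in calcium-imaging recordings —
from raw ROI fluorescence to brain-wide synchronization, seizure-propagation
maps, interictal neuronal ensembles, and LFP/calcium event correlation.

The package targets the kind of experiment done in chemoconvulsant-treated
larval zebrafish: whole-brain confocal imaging of a GCaMP-expressing fish at
20–30 Hz with six bilateral brain-region ROIs (pallium, habenula, tectal
neuropil, SPV, cerebellum, hindbrain), single-neuron imaging of the optic
tectum microcircuit, and simultaneous local-field-potential (LFP)
recordings. PTZ (a GABA_A antagonist) induces recurrent generalized
ictal-like events at ~1–2/min; 4-AP (a potassium-channel blocker) induces
non-seizure hyperexcitability confined to posterior regions. Because such
recordings are rarely shareable, a first-class synthetic-data generator
reproduces all three conditions with known ground truth, so every stage of
the pipeline is testable end to end.

## The analyses

* **ΔF/F** — causal sliding-window baseline: at each sample,
  B(t) = mean of the lower 50% of values in the previous 10-s window, and
  ΔF/F(t) = (F(t) − B(t)) / B(t). A rectified, epoch-normalized area under
  the curve (norm. ΔF/F AUC) summarizes paroxysmal activity per channel.
* **Event detection** — template matching: a time-varying Pearson
  correlation between the trace and a library of unit-peak
  difference-of-exponentials transients; local maxima of the correlation
  with r > 0.85 and transient amplitude ΔF/F > 0.1 become calcium events,
  with file-based manual add/delete corrections and per-5-min firing rates.
* **Synchronization** — instantaneous phases via the Hilbert analytic
  signal; the pairwise phase-locking-value matrix S with
  S_ij = |⟨e^{i(φ_i−φ_j)}⟩_t|; and the eigenvalue-based global
  synchronization index GSI = (λ_max(S) − 1)/(N − 1) ∈ [0, 1]
  (1 = fully synchronized network, 0 = uncorrelated channels).
* **Seizure propagation** — per-region onset inside each ictal event from
  the 50-point-smoothed derivative of ΔF/F; relative lags normalized to
  [0, 1] between the earliest and latest region; rank-based tercile groups
  (early/middle/late); and a 6-region × 3-tercile Pearson χ² test of onset
  ordering (df = 10).
* **Neuronal ensembles** — coactive-neuron counts in a sliding 0.5-s
  (10-frame) window; a surrogate null from 2000 within-neuron shuffles of
  the binary raster; windows exceeding the 99.9th percentile of the pooled
  null (p < 0.001) merge into ensemble events, with centroid-distance
  spatial statistics.
* **LFP coupling** — per-event amplitude (max |deflection| from a robust
  pre-event baseline) and duration (first-to-last baseline crossing at
  ±3 robust SD), paired across modalities and summarized by squared Pearson
  correlations.

## Worked example

Run the whole pipeline on a simulated PTZ fish:

```sh
cat > run.json <<'JSON'
{"condition": "ptz", "seed": 7, "out_dir": "demo", "duration_s": 300.0}
JSON
seizurescope run --config run.json
```

which reports `completed stages: simulate, dff, detect, sync, propagate,
ensembles, lfp-corr` and writes, among other outputs, `demo/sync.json`:

```json
{"global_sync_index": 0.9695}
```

— the simulated seizing brain is near-maximally synchronized (control
simulations score ~0.02) — and `demo/propagation.json` with
`chi2 = 159.8, dof = 10, p = 3.6e-29`: the onset terciles of the 8 detected
ictal events are far from independent of region, reflecting the planted
anterior-to-posterior propagation.

Pooling LFP/calcium event pairs across several simulated fish shows the
duration/amplitude dissociation:

```python
import pandas as pd
import seizurescope as sz
from seizurescope.lfp import EventFeatures, event_features

cfg = sz.SimConfig()                      # 5 min at 20 Hz, PTZ defaults
ca, lf, eid = [], [], 0
for seed in range(1, 9):                  # pool events across 8 fish
    traces, truth = sz.simulate_region_traces(cfg, "ptz", seed)
    dff = sz.compute_dff(traces)          # causal 10-s lower-half baseline
    lfp = sz.simulate_lfp(truth, duration_jitter_sd_s=0.5, seed=seed + 500)
    spans = [(t - 2, min(300, t + d + 3))
             for t, d in zip(truth.event_times_s, truth.event_durations_s)]
    a = event_features(dff.channel("cerebellum_left"), dff.fps, spans)
    b = event_features(lfp.values, lfp.fps, spans, source="lfp")
    a.table["event"] += eid; b.table["event"] += eid; eid += len(spans)
    ca.append(a.table); lf.append(b.table)

report = sz.lfp_calcium_correlation(
    EventFeatures(pd.concat(ca, ignore_index=True), "calcium"),
    EventFeatures(pd.concat(lf, ignore_index=True), "lfp"))
print(f"{report['n_events']} paired events: "
      f"duration R^2 = {report['r2_duration']:.3f}, "
      f"amplitude R^2 = {report['r2_amplitude']:.3f}")
```

prints

```
60 paired events: duration R^2 = 0.940, amplitude R^2 = 0.024
```

ictal durations agree tightly across modalities while amplitudes are
unrelated — the expected signature when electrode placement and indicator
expression decouple amplitudes but the underlying discharge sets both
durations. (On a single fish's handful of events the amplitude R² is noisy;
the dissociation is a pooled-cohort statement.)

Every stage is also exposed individually (`seizurescope simulate | extract |
dff | detect | correct | sync | propagate | ensembles | lfp-corr`), reading
and writing plain CSV/JSON/TIFF.

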