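"""Generator contracts: kernel shape, planted events, rasters, LFP, movies."""
import numpy as np
import pytest

import seizurescope as sz
from seizurescope.core import Roi, RoiSet
from seizurescope.exceptions import ParameterError
from seizurescope.synthetic import FOURAP_CHANNELS


class TestCalciumKernel:
    def test_unit_peak_and_length(self):
        k = sz.generate_calcium_kernel(0.1, 1.0, 20.0, 5.0)
        assert len(k) == 100
        assert k.max() == 1.0
        assert (k >= 0).all()

    def test_rises_then_decays_monotonically(self):
        k = sz.generate_calcium_kernel(0.1, 1.0, 20.0, 5.0)
        p = int(np.argmax(k))
        assert (np.diff(k[: p + 1]) > 0).all()
        assert (np.diff(k[p:]) < 0).all()

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ParameterError):
            sz.generate_calcium_kernel(0.5, 0.5, 20.0, 5.0)

    def test_peak_time_matches_closed_form(self):
        # t* = ln(decay/rise) * rise*decay / (decay - rise), checked against
        # the numeric argmax on a fine grid
        rise, decay, fps = 0.1, 1.0, 1000.0
        k = sz.generate_calcium_kernel(rise, decay, fps, 5.0)
        t_star = np.log(decay / rise) * rise * decay / (decay - rise)
        assert abs(np.argmax(k) / fps - t_star) <= 1.5 / fps


class TestRegionTraces:
    def test_ptz_event_count_in_one_to_two_per_min_band(self, sim_cfg):
        _, gt = sz.simulate_region_traces(sim_cfg, "ptz", seed=7)
        assert 6 <= gt.n_events <= 9

    def test_control_has_no_planted_events(self, sim_cfg):
        _, gt = sz.simulate_region_traces(sim_cfg, "control", seed=7)
        assert gt.n_events == 0
        assert all(len(v) == 0 for v in gt.per_channel_event_times.values())

    def test_4ap_events_only_in_cerebellum_hindbrain(self, sim_cfg):
        _, gt = sz.simulate_region_traces(sim_cfg, "4ap", seed=7)
        assert gt.n_events > 0
        for ch, times in gt.per_channel_event_times.items():
            if ch in FOURAP_CHANNELS:
                assert len(times) == gt.n_events
            else:
                assert len(times) == 0

    def test_ptz_event_conservation_across_channels(self, ptz_dataset):
        _, gt = ptz_dataset
        for ch in gt.channels:
            assert len(gt.per_channel_event_times[ch]) == gt.n_events

    def test_planted_times_within_epoch(self, ptz_dataset):
        _, gt = ptz_dataset
        for times in gt.per_channel_event_times.values():
            assert (times >= 0).all() and (times <= gt.duration_s).all()

    def test_seed_determinism_bit_identical(self, sim_cfg):
        a, _ = sz.simulate_region_traces(sim_cfg, "ptz", seed=3)
        b, _ = sz.simulate_region_traces(sim_cfg, "ptz", seed=3)
        assert np.array_equal(a.values, b.values)

    def test_unknown_condition_rejected(self, sim_cfg):
        with pytest.raises(ParameterError):
            sz.simulate_region_traces(sim_cfg, "kainate", seed=0)


class TestNeuronRaster:
    def test_single_ensemble_no_background(self):
        cfg = sz.SimConfig(n_neurons=75, background_rate=0.0)
        members = np.arange(10)
        _, gt = sz.simulate_neuron_raster(cfg, [(1000, members)], seed=1)
        raster = sz.event_raster(gt)
        assert raster.sum() == 10
        frames = np.flatnonzero(raster.any(axis=1))
        assert frames.min() >= 1000 and frames.max() <= 1009

    def test_background_count_matches_binomial_expectation(self):
        cfg = sz.SimConfig(n_neurons=75, duration_s=300.0, background_rate=0.001)
        _, gt = sz.simulate_neuron_raster(cfg, [], seed=3)
        total = sum(len(v) for v in gt.event_frames.values())
        expect = 75 * cfg.n_frames * 0.001
        sd = np.sqrt(expect * (1 - 0.001))
        assert abs(total - expect) < 4 * sd

    def test_empty_raster_without_background_or_ensembles(self):
        cfg = sz.SimConfig(n_neurons=10, background_rate=0.0)
        _, gt = sz.simulate_neuron_raster(cfg, [], seed=0)
        assert sz.event_raster(gt).sum() == 0

    def test_out_of_range_ensemble_frame_rejected(self):
        cfg = sz.SimConfig(n_neurons=10)
        with pytest.raises(ParameterError):
            sz.simulate_neuron_raster(cfg, [(10**6, np.arange(3))], seed=0)


class TestLfp:
    def test_single_burst_matches_planted_duration(self, sim_cfg):
        _, gt = sz.simulate_region_traces(sim_cfg, "ptz", seed=3)
        lfp = sz.simulate_lfp(gt, duration_jitter_sd_s=0.0, seed=9)
        assert np.allclose(lfp.burst_durations_s, gt.event_durations_s, atol=0.01)

    def test_no_events_gives_noise_only_trace(self, sim_cfg):
        _, gt = sz.simulate_region_traces(sim_cfg, "control", seed=3)
        lfp = sz.simulate_lfp(gt, seed=9)
        assert len(lfp.burst_durations_s) == 0
        assert np.abs(lfp.values).max() < 0.2   # no burst-scale deflections

    def test_jittered_durations_track_planted(self, sim_cfg):
        durs, planted = [], []
        for seed in range(3):
            _, gt = sz.simulate_region_traces(sim_cfg, "ptz", seed=seed)
            lfp = sz.simulate_lfp(gt, duration_jitter_sd_s=0.5, seed=seed + 50)
            durs.append(lfp.burst_durations_s)
            planted.append(gt.event_durations_s)
        x = np.concatenate(planted)
        y = np.concatenate(durs)
        assert len(x) >= 10
        r = np.corrcoef(x, y)[0, 1]
        assert r ** 2 > 0.8


def _four_rois(size=64, side=8):
    rois = []
    for i, (r0, c0) in enumerate([(4, 4), (4, 40), (40, 4), (40, 40)]):
        mask = np.zeros((size, size), bool)
        mask[r0 : r0 + side, c0 : c0 + side] = True
        rois.append(Roi(label=i + 1, name=f"roi{i}", mask=mask))
    return RoiSet(rois)


class TestRenderMovie:
    def test_noise_free_pixels_equal_trace(self):
        rois = _four_rois()
        tm = sz.TraceMatrix(np.full((5, 4), 100.0), fps=20.0,
                            labels=[r.name for r in rois])
        stack = sz.render_movie(tm, rois, noise_sd=0.0)
        for roi in rois:
            assert (stack[:, roi.mask] == 100).all()

    def test_round_trip_recovers_traces_within_noise_bound(self):
        rois = _four_rois()
        rng = np.random.default_rng(5)
        vals = 100.0 + rng.uniform(-10, 10, size=(200, 4))
        tm = sz.TraceMatrix(vals, fps=20.0, labels=[r.name for r in rois])
        stack = sz.render_movie(tm, rois, noise_sd=2.0, seed=11)
        rec = sz.extract_roi_traces(stack, rois, fps=20.0)
        area = rois.rois[0].mask.sum()
        assert np.abs(rec.values - vals).max() < 5 * 2.0 / np.sqrt(area)

    def test_mask_not_fitting_frame_rejected(self):
        rois = _four_rois(size=64)
        tm = sz.TraceMatrix(np.full((5, 4), 100.0), fps=20.0,
                            labels=[r.name for r in rois])
        with pytest.raises(ParameterError):
            sz.render_movie(tm, rois, frame_shape=(32, 32))

    def test_overlapping_masks_rejected(self):
        m1 = np.zeros((16, 16), bool)
        m1[:8] = True
        m2 = np.zeros((16, 16), bool)
        m2[6:] = True
        with pytest.raises(ParameterError):
            RoiSet([Roi(label=1, name="a", mask=m1), Roi(label=2, name="b", mask=m2)])
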