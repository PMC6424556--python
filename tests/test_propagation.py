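"""Onset detection, lag normalization, terciles, chi-square contingency."""
import numpy as np
import pandas as pd
import pytest

import seizurescope as sz
from seizurescope.exceptions import InputError
from seizurescope.propagation import (
    moving_average,
    region_tercile_counts,
    region_tercile_probabilities,
)


def smoothed_diff_oracle(x, n):
    """Naive centered moving average (truncated edges) + first difference."""
    sm = np.empty_like(x, dtype=float)
    half_lo, half_hi = n // 2, n - n // 2 - 1   # matches np.convolve 'same'
    for i in range(len(x)):
        lo = max(0, i - half_lo)
        hi = min(len(x), i + half_hi + 1)
        sm[i] = x[lo:hi].mean()
    return np.diff(sm)


def _dff_tm(values, fps=20.0):
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[:, None]
    return sz.TraceMatrix(values, fps=fps,
                          labels=[f"c{i}" for i in range(values.shape[1])],
                          kind="dff")


class TestDetectOnsets:
    def test_strict_argmax_matches_naive_smoothing_oracle(self):
        fps = 20.0
        t = np.arange(2000) / fps
        x = 2.0 / (1.0 + np.exp(-(t - 50.0) / 0.8))   # unique slope maximum
        tm = _dff_tm(x, fps)
        onsets = sz.detect_onsets(tm, [(30.0, 70.0)], smooth_n=50,
                                  edge_fraction=0.0)
        a, b = int(30 * fps), int(70 * fps)
        d = smoothed_diff_oracle(x, 50)
        expect = (a + int(np.argmax(d[a:b])) + 0.5) / fps
        assert onsets["onset_s"].iloc[0] == expect

    def test_half_max_edge_matches_oracle_rule(self):
        fps = 20.0
        t = np.arange(2000) / fps
        x = 2.0 / (1.0 + np.exp(-(t - 50.0) / 0.8))
        tm = _dff_tm(x, fps)
        onsets = sz.detect_onsets(tm, [(30.0, 70.0)], smooth_n=50)
        a, b = int(30 * fps), int(70 * fps)
        d = smoothed_diff_oracle(x, 50)[a:b]
        thr = 0.5 * d.max()
        i = int(np.argmax(d >= thr))
        frac = i - 1 + (thr - d[i - 1]) / (d[i] - d[i - 1])   # sub-frame crossing
        expect = (a + frac + 0.5) / fps
        assert onsets["onset_s"].iloc[0] == pytest.approx(expect, abs=1e-9)

    def test_ramp_onset_in_midpoint_region_near_oracle(self):
        fps = 20.0
        x = np.zeros(2000)
        x[900:1100] = np.linspace(0, 2, 200)   # linear ramp inside the window
        x[1100:] = 2.0
        tm = _dff_tm(x, fps)
        onsets = sz.detect_onsets(tm, [(30.0, 70.0)], smooth_n=50,
                                  edge_fraction=0.0)
        a, b = int(30 * fps), int(70 * fps)
        d = smoothed_diff_oracle(x, 50)
        expect = (a + int(np.argmax(d[a:b])) + 0.5) / fps
        # the smoothed derivative is flat along the ramp, so the argmax may
        # land on any tied frame; agreement to within the plateau is required
        assert abs(onsets["onset_s"].iloc[0] - expect) <= 2.0 / fps
        assert 45.0 <= onsets["onset_s"].iloc[0] <= 55.0

    def test_planted_half_second_lag_recovered(self):
        fps = 20.0
        k = sz.generate_calcium_kernel(0.3, 3.0, fps, 12.0)
        x = np.zeros((3000, 2))
        x[1000 : 1000 + len(k), 0] = 2 * k
        x[1010 : 1010 + len(k), 1] = 2 * k     # delayed 0.5 s
        onsets = sz.detect_onsets(_dff_tm(x, fps), [(40.0, 70.0)], smooth_n=50)
        lag = onsets["onset_s"].iloc[1] - onsets["onset_s"].iloc[0]
        assert lag == pytest.approx(0.5, abs=1.0 / fps)

    def test_short_window_skipped(self):
        tm = _dff_tm(np.zeros(1000))
        out = sz.detect_onsets(tm, [(0.0, 1.0)], smooth_n=50)   # 20 samples
        assert len(out) == 0


class TestNormalizedLags:
    def _onsets(self, vals):
        return pd.DataFrame(
            {"event": 0, "roi": [f"r{i}" for i in range(len(vals))],
             "onset_s": vals}
        )

    def test_linear_onsets_normalize_to_unit_interval(self):
        out = sz.normalized_lags(self._onsets([0.0, 1.0, 2.0]))
        assert list(out["norm_lag"]) == [0.0, 0.5, 1.0]

    def test_equal_onsets_flagged_degenerate(self):
        out = sz.normalized_lags(self._onsets([1.0, 1.0, 1.0]))
        assert out["degenerate"].all()

    def test_extremes_map_to_zero_and_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 5, size=12)
        out = sz.normalized_lags(self._onsets(vals))
        assert out["norm_lag"].min() == 0.0
        assert out["norm_lag"].max() == 1.0
        assert out.loc[out["onset_s"].idxmin(), "norm_lag"] == 0.0


class TestTercileGroups:
    def _lags(self, vals):
        df = pd.DataFrame(
            {"event": 0, "roi": [f"r{i}" for i in range(len(vals))],
             "onset_s": vals}
        )
        return sz.normalized_lags(df)

    def test_twelve_points_split_four_per_group(self):
        out = sz.tercile_groups(self._lags(list(np.arange(12.0))))
        assert out["tercile"].value_counts().to_dict() == {
            "early": 4, "middle": 4, "late": 4
        }
        assert set(out.loc[out["tercile"] == "early", "roi"]) == {
            "r0", "r1", "r2", "r3"
        }

    def test_region_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        frames = []
        for e in range(5):
            rois = [f"{r}_{s}" for r in sz.REGIONS for s in ("left", "right")]
            frames.append(pd.DataFrame(
                {"event": e, "roi": rois,
                 "onset_s": rng.uniform(0, 3, size=12)}
            ))
        lags = sz.normalized_lags(pd.concat(frames, ignore_index=True))
        labeled = sz.tercile_groups(lags)
        probs = region_tercile_probabilities(labeled)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_anterior_posterior_profile_recovered(self, sim_cfg):
        # pool events over seeds, as across fish in a cohort
        tabs = []
        for seed in range(1, 6):
            tr, gt = sz.simulate_region_traces(sim_cfg, "ptz", seed)
            dff = sz.compute_dff(tr)
            wins = [
                (max(0.0, t - 2.0), min(tr.duration_s, t + d))
                for t, d in zip(gt.event_times_s, gt.event_durations_s)
            ]
            onsets = sz.detect_onsets(dff, wins)
            lags = sz.normalized_lags(onsets)
            lags["event"] = lags["event"].astype(str) + f"_s{seed}"
            tabs.append(sz.tercile_groups(lags, channel_order=list(dff.labels)))
        labeled = pd.concat(tabs, ignore_index=True)
        probs = region_tercile_probabilities(labeled)
        assert probs.loc["pallium", "early"] >= 0.8
        assert probs.loc["hindbrain", "late"] >= 0.8


class TestChiSquare:
    def test_six_by_three_table_has_ten_degrees_of_freedom(self):
        counts = np.full((6, 3), 5)
        _, dof, _ = sz.onset_chi_square(counts)
        assert dof == 10

    def test_identical_rows_give_zero_statistic(self):
        counts = np.tile([4, 7, 9], (6, 1))
        chi2, _, p = sz.onset_chi_square(counts)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_two_by_two_matches_hand_computation(self):
        chi2, dof, _ = sz.onset_chi_square(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)
        assert dof == 1

    def test_empty_row_instructs_pooling(self):
        counts = np.array([[5, 5, 5], [0, 0, 0], [3, 3, 3]])
        with pytest.raises(InputError, match="pool"):
            sz.onset_chi_square(counts)


class TestEndToEnd:
    def test_contingency_rows_count_two_points_per_event(self, ptz_dff):
        dff, gt = ptz_dff
        wins = [
            (max(0.0, t - 2.0), min(dff.duration_s, t + d))
            for t, d in zip(gt.event_times_s, gt.event_durations_s)
        ]
        res = sz.propagation_analysis(dff, wins)
        counts = region_tercile_counts(res.table)
        n_events = res.table["event"].nunique()
        assert (counts.sum(axis=1) == 2 * n_events).all()
        assert res.dof == 10
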