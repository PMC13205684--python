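"""Rhythm analysis: R-peak detection, IBI, HRV metrics, Poincare pairs,
windowed trends and the window outlier filter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radiosem.hrv import (
    compute_ibi,
    detect_r_peaks,
    filter_window_outliers,
    hrv_metrics,
    poincare_pairs,
    windowed_hrv,
)
from radiosem.world import StateParams, render_ecg, sample_cardiac_state


def straight_formula_hrv(ibi):
    """Independent straight-from-definition oracle."""
    ibi = np.asarray(ibi, dtype=float)
    d = ibi[1:] - ibi[:-1]
    rmssd = np.sqrt(np.sum(d * d) / d.size)
    sdnn = np.sqrt(np.sum((ibi - ibi.sum() / ibi.size) ** 2) / ibi.size)
    pnn50 = 100.0 * sum(1 for x in d if abs(x) > 50.0) / d.size
    hr = 60000.0 / (ibi.sum() / ibi.size)
    return rmssd, sdnn, pnn50, hr


class TestDetectRPeaks:
    def test_clean_metronome_ecg_detected_within_10ms(self, metronome_params):
        state = sample_cardiac_state("NORMAL", 30, metronome_params, seed=0)
        rec = render_ecg(state, fs_hz=250)
        peaks = detect_r_peaks(rec.waveform[0], 250)
        assert peaks.size == state.beat_times.size
        assert np.abs(peaks - state.beat_times).max() <= 0.010 + 1e-9

    def test_detection_is_amplitude_scale_invariant(self, normal_state):
        rec = render_ecg(normal_state, fs_hz=250)
        a = detect_r_peaks(rec.waveform[0], 250)
        b = detect_r_peaks(10.0 * rec.waveform[0], 250)
        np.testing.assert_array_equal(a, b)

    def test_refractory_fuses_close_candidates(self):
        fs = 250.0
        t = np.arange(int(4 * fs)) / fs
        ecg = np.zeros_like(t)
        for center in (1.0, 1.15, 2.5):      # two candidates 150 ms apart
            ecg += np.exp(-0.5 * ((t - center) / 0.012) ** 2)
        peaks = detect_r_peaks(ecg, fs)
        assert np.sum((peaks > 0.8) & (peaks < 1.4)) == 1

    def test_flat_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="flat"):
            peaks = detect_r_peaks(np.zeros(1000), 250)
        assert peaks.size == 0

    def test_cohort_median_timing_error_within_10ms(self):
        errs = []
        for seed, rhythm in [(1, "NORMAL"), (2, "AF"), (3, "PB")]:
            state = sample_cardiac_state(rhythm, 30, seed=seed)
            rec = render_ecg(state, fs_hz=250)
            peaks = detect_r_peaks(rec.waveform[0], 250)
            for tb in state.beat_times:
                if peaks.size:
                    errs.append(abs(peaks[np.argmin(np.abs(peaks - tb))] - tb))
        assert np.median(errs) <= 0.010


class TestIbiAndMetrics:
    def test_ibi_from_beat_times(self):
        np.testing.assert_allclose(compute_ibi([1.0, 2.0, 3.0]), [1000.0, 1000.0])

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError, match="insufficient beats"):
            compute_ibi([1.0])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            compute_ibi([1.0, 0.5, 2.0])

    def test_constant_series_zero_variability(self):
        h = hrv_metrics(np.full(100, 800.0))
        assert (h.rmssd_ms, h.sdnn_ms, h.pnn50_pct) == (0.0, 0.0, 0.0)
        assert h.mean_hr_bpm == pytest.approx(75.0)

    def test_worked_example_alternating_800_900(self):
        h = hrv_metrics(np.array([800.0, 900.0, 800.0, 900.0]))
        assert h.rmssd_ms == pytest.approx(100.0)
        assert h.sdnn_ms == pytest.approx(50.0)
        assert h.pnn50_pct == pytest.approx(100.0)

    def test_pnn50_uses_strict_inequality(self):
        ibi = 800.0 + 50.0 * np.arange(6)        # successive diffs exactly 50
        assert hrv_metrics(ibi).pnn50_pct == 0.0

    def test_oracle_equivalence_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 50)
            ibi = rng.uniform(300, 2000, n)
            h = hrv_metrics(ibi)
            rmssd, sdnn, pnn50, hr = straight_formula_hrv(ibi)
            assert abs(h.rmssd_ms - rmssd) < 1e-12 * max(1, rmssd)
            assert abs(h.sdnn_ms - sdnn) < 1e-12 * max(1, sdnn)
            assert h.pnn50_pct == pnn50
            assert abs(h.mean_hr_bpm - hr) < 1e-12 * hr

    def test_sdnn_ddof_switch(self):
        ibi = np.array([700.0, 800.0, 900.0])
        assert hrv_metrics(ibi, sdnn_ddof=1).sdnn_ms == pytest.approx(ibi.std(ddof=1))

    def test_guard_drops_nonphysiological_intervals(self):
        h = hrv_metrics(np.array([800.0, 100.0, 820.0, 4000.0, 810.0]))
        assert h.ibi_ms.size == 3


class TestPoincare:
    def test_constant_series_collapses_to_diagonal_point(self):
        pairs = poincare_pairs(np.full(10, 850.0))
        assert pairs.shape == (9, 2)
        assert np.all(pairs[:, 0] == pairs[:, 1])

    def test_alternating_series_forms_two_off_diagonal_clusters(self):
        pairs = poincare_pairs(np.array([800.0, 900.0] * 5))
        uniq = {tuple(p) for p in pairs}
        assert uniq == {(800.0, 900.0), (900.0, 800.0)}

    def test_empty_when_fewer_than_two_intervals(self):
        assert poincare_pairs(np.array([800.0])).shape == (0, 2)


class TestWindowing:
    def test_ten_minute_constant_recording_gives_two_identical_windows(self):
        beats = np.arange(0, 600, 1.0)
        out = windowed_hrv(beats, window_s=300, step_s=300, duration_s=600)
        assert len(out) == 2
        assert out[0].mean_hr_bpm == pytest.approx(out[1].mean_hr_bpm)

    def test_boundary_beat_belongs_to_later_window(self):
        beats = np.array([299.0, 300.0, 301.0, 302.0])
        out = windowed_hrv(beats, window_s=300, step_s=300, duration_s=600)
        assert len(out) == 1
        assert out[0].window == (300.0, 600.0)
        assert out[0].ibi_ms.size == 2

    def test_sparse_window_skipped(self):
        beats = np.concatenate([np.arange(0, 300, 1.0), [450.0]])
        out = windowed_hrv(beats, window_s=300, step_s=300, duration_s=600)
        assert len(out) == 1

    def test_every_beat_in_exactly_one_window(self):
        rng = np.random.default_rng(1)
        beats = np.cumsum(rng.uniform(0.5, 1.2, 700))
        window = 300.0
        duration = float(np.ceil(beats[-1]))
        out = windowed_hrv(beats, window_s=window, step_s=window, duration_s=duration)
        counted = sum(h.ibi_ms.size + 1 for h in out)
        in_range = beats[beats < duration // window * window]
        assert counted == in_range.size


class TestOutlierFilter:
    def test_constructed_outlier_removed(self):
        np.testing.assert_array_equal(
            filter_window_outliers([1, 1, 1, 1, 100]), [1, 1, 1, 1]
        )

    def test_all_equal_retained(self):
        assert filter_window_outliers([5, 5, 5, 5]).size == 4

    def test_small_spread_retained(self):
        np.testing.assert_array_equal(filter_window_outliers([1, 2, 3, 4]), [1, 2, 3, 4])

    def test_low_values_always_retained(self):
        out = filter_window_outliers([-100, 1, 1, 1, 1])
        assert -100 in out

    def test_requires_four_windows(self):
        with pytest.raises(ValueError):
            filter_window_outliers([1, 2, 3])

    @given(st.lists(st.floats(0, 1000), min_size=4, max_size=30))
    def test_filter_is_idempotent_bound(self, values):
        out = filter_window_outliers(values)
        q1, q3 = np.percentile(values, [25, 75])
        assert np.all(out <= q3 + 1.5 * (q3 - q1))
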