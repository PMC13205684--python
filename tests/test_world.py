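"""Synthetic cardiac world: state sampling, ECG rendering, torso motion
and radar simulation contracts."""

import numpy as np
import pytest

from radiosem.hrv import detect_r_peaks
from radiosem.world import (
    DisplacementField,
    RadarConfig,
    Rhythm,
    StateParams,
    make_grid,
    render_ecg,
    render_torso_displacement,
    sample_cardiac_state,
    simulate_radar,
)


class TestCardiacState:
    def test_zero_variance_hr_gives_exact_one_second_intervals(self, metronome_params):
        state = sample_cardiac_state("NORMAL", 10, metronome_params, seed=0)
        assert state.beat_times.size in (10, 11)
        np.testing.assert_allclose(np.diff(state.beat_times), 1.0, atol=1e-9)

    def test_af_interval_irregularity_exceeds_cv_threshold(self):
        state = sample_cardiac_state("AF", 60, seed=1)
        ibi = np.diff(state.beat_times)
        assert ibi.std() / ibi.mean() >= 0.1

    def test_premature_beats_followed_by_compensatory_pause(self):
        params = StateParams(pb_every=10)
        state = sample_cardiac_state("PB", 60, params, seed=2)
        assert state.pb_beat_indices.size >= 3
        ibi = np.diff(state.beat_times)
        for idx in state.pb_beat_indices:
            lo, hi = max(0, idx - 4), min(ibi.size, idx + 5)
            assert state.beat_times[idx + 1] - state.beat_times[idx] >= 1.1 * ibi[lo:hi].mean()

    @pytest.mark.parametrize("rhythm", ["NORMAL", "AF", "PB"])
    def test_sampling_is_deterministic_and_valid(self, rhythm):
        a = sample_cardiac_state(rhythm, 30, seed=7)
        b = sample_cardiac_state(rhythm, 30, seed=7)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)
        np.testing.assert_array_equal(a.pr_ms, b.pr_ms)
        a.validate()

    def test_infeasible_params_raise_naming_the_invariant(self):
        with pytest.raises(ValueError, match="pr_mean_ms \\+ qt_mean_ms"):
            sample_cardiac_state(
                "NORMAL", 10, StateParams(hr_mean=120, pr_mean_ms=250, qt_mean_ms=450)
            )
        with pytest.raises(ValueError):
            sample_cardiac_state("NORMAL", 5)


class TestRenderEcg:
    def test_r_peaks_land_on_beat_times(self, metronome_params):
        state = sample_cardiac_state("NORMAL", 10, metronome_params, seed=0)
        rec = render_ecg(state, fs_hz=250)
        peaks = detect_r_peaks(rec.waveform[0], 250)
        assert peaks.size == state.beat_times.size
        assert np.abs(peaks - state.beat_times).max() <= 1.0 / 250 + 1e-9

    def test_p_onset_to_r_lag_matches_pr_interval(self):
        state = sample_cardiac_state(
            "NORMAL", 20, StateParams(hr_mean=55, hr_sd=0, ibi_cv=0, pr_mean_ms=160, pr_sd_ms=0),
            seed=3,
        )
        fs = 500.0
        rec = render_ecg(state, fs_hz=fs)
        w = rec.waveform[0]
        lags = []
        for i, tr in enumerate(state.beat_times[1:-1], start=1):
            # locate the P-wave crest in the window before the QRS
            lo = int((tr - 0.30) * fs)
            hi = int((tr - 0.10) * fs)
            p_center = (lo + np.argmax(w[lo:hi])) / fs
            p_onset = p_center - 2 * 0.025      # crest minus two sigma
            lags.append((tr - p_onset) * 1000)
        assert abs(np.mean(lags) - state.pr_ms[1:-1].mean()) <= 5.0

    def test_af_suppresses_p_waves(self):
        params = StateParams(hr_mean=60, af_cv=0.2)
        state = sample_cardiac_state("AF", 30, params, seed=4)
        rec = render_ecg(state, fs_hz=250)
        w = rec.waveform[0]
        r_amp = np.quantile(w, 0.999)
        p_amps = []
        for tr in state.beat_times[1:-1]:
            lo, hi = int((tr - 0.28) * 250), int((tr - 0.12) * 250)
            p_amps.append(w[lo:hi].max())
        # no consistent P wave: typical pre-QRS amplitude stays below 5% of R
        assert np.median(p_amps) < 0.05 * r_amp + 0.05  # ripple allowance

    def test_lead_count_validation(self, normal_state):
        with pytest.raises(ValueError):
            render_ecg(normal_state, n_leads=0)


class TestTorsoDisplacement:
    def test_no_motion_sources_give_constant_field(self, grid_844, normal_state):
        field = render_torso_displacement(
            normal_state, grid_844, respiration_amp_m=0.0, cardiac_amp_m=0.0
        )
        assert np.ptp(field.values, axis=1).max() == 0.0

    def test_longer_qt_spreads_pulse_and_lowers_peak(self, grid_844):
        base = sample_cardiac_state(
            "NORMAL", 12, StateParams(hr_mean=60, hr_sd=0, ibi_cv=0), seed=5
        )
        import dataclasses

        short = dataclasses.replace(base, qt_ms=np.full_like(base.qt_ms, 350.0))
        long = dataclasses.replace(base, qt_ms=np.full_like(base.qt_ms, 450.0))
        f_short = render_torso_displacement(short, grid_844, respiration_amp_m=0.0)
        f_long = render_torso_displacement(long, grid_844, respiration_amp_m=0.0)
        assert f_long.values.max() < f_short.values.max()

    def test_pulse_peak_near_beat_within_electromechanical_delay(self, grid_844):
        state = sample_cardiac_state(
            "NORMAL", 12, StateParams(hr_mean=60, hr_sd=0, ibi_cv=0), seed=6
        )
        field = render_torso_displacement(
            state, grid_844, respiration_amp_m=0.0, emd_s=0.05, fs_hz=100
        )
        v = int(np.argmax(field.values.std(axis=1)))
        beat = state.beat_times[2]
        lo, hi = int((beat - 0.2) * 100), int((beat + 0.3) * 100)
        t_peak = (lo + np.argmax(field.values[v, lo:hi])) / 100
        assert abs(t_peak - (beat + 0.05)) <= 0.06


class TestSimulateRadar:
    def test_static_scene_has_constant_phase(self, grid_844, radar_nonoise):
        from conftest import single_scatterer_cube

        cube = single_scatterer_cube(grid_844, radar_nonoise, node=10)
        phases = np.angle(cube.samples)
        assert np.ptp(phases, axis=2).max() < 1e-6

    def test_sinusoidal_displacement_modulates_phase_by_round_trip_over_lambda(self):
        grid = make_grid((2, 1, 1))
        cfg = RadarConfig(n_pairs=1, n_fast=1, noise_sigma=0.0,
                          pair_positions=np.zeros((1, 3)))
        t = np.arange(500) / cfg.chirp_rate_hz
        one_way = 0.25e-3 * np.sin(2 * np.pi * 1.2 * t)
        from conftest import single_scatterer_cube

        cube = single_scatterer_cube(grid, cfg, node=0, displacement=one_way, n_t=500)
        phase = np.unwrap(np.angle(cube.samples[0, 0]))
        swing = (phase.max() - phase.min()) / 2
        expected = 2 * np.pi * 2 * 0.25e-3 / cfg.wavelength_m
        assert swing == pytest.approx(expected, rel=0.02)

    def test_same_seed_gives_bit_identical_cubes(self, grid_844, normal_state):
        cfg = RadarConfig(noise_sigma=1.0)
        field = render_torso_displacement(normal_state, grid_844, fs_hz=100)
        a = simulate_radar(field, cfg, seed=9)
        b = simulate_radar(field, cfg, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_mismatched_time_base_rejected(self, grid_844, normal_state):
        cfg = RadarConfig(chirp_rate_hz=100.0)
        field = render_torso_displacement(normal_state, grid_844, fs_hz=50)
        with pytest.raises(ValueError, match="chirp rate"):
            simulate_radar(field, cfg)
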