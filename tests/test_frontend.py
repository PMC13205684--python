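"""Radar front end: beamforming, phase extraction, torso localization and
respiration suppression."""

import numpy as np
import pytest

from radiosem.frontend import (
    VoxelSignal,
    beamform,
    beamform_array,
    beamform_naive,
    build_motion_tensor,
    extract_phase,
    localize_torso,
    suppress_respiration,
)
from radiosem.world import (
    DisplacementField,
    RadarConfig,
    RadarCube,
    make_grid,
    render_torso_displacement,
    sample_cardiac_state,
    simulate_radar,
)

from conftest import single_scatterer_cube


class TestBeamform:
    def test_unit_weight_when_single_pair_at_zero_path(self):
        grid = make_grid((1, 1, 1), x_extent=(0, 0), y_extent=(0, 0), z_extent=(0, 0))
        cfg = RadarConfig(n_pairs=1, n_fast=1, pair_positions=np.zeros((1, 3)))
        rng = np.random.default_rng(0)
        y = (rng.normal(size=(1, 1, 32)) + 1j * rng.normal(size=(1, 1, 32))).astype(np.complex64)
        cube = RadarCube(samples=y, config_ref=cfg, t_slow_s=np.arange(32) / 100)
        out = beamform_array(cube, grid)
        np.testing.assert_allclose(out[0], y[0, 0], rtol=1e-6)

    def test_power_argmax_recovers_scatterer_node(self, grid_844, radar_nonoise):
        node = 137
        cube = single_scatterer_cube(grid_844, radar_nonoise, node=node)
        voxels = beamform(cube, grid_844)
        powers = np.array([v.power for v in voxels])
        assert int(np.argmax(powers)) == node

    def test_vectorized_matches_naive_triple_loop(self, grid_844, radar_nonoise):
        cube = single_scatterer_cube(grid_844, radar_nonoise, node=77, n_t=16)
        fast = beamform_array(cube, grid_844)
        slow = beamform_naive(cube, grid_844)
        scale = np.abs(slow).max()
        assert np.abs(fast - slow).max() / scale < 1e-6

    def test_beamformer_linearity(self, grid_844, radar_nonoise):
        c1 = single_scatterer_cube(grid_844, radar_nonoise, node=10, n_t=16)
        c2 = single_scatterer_cube(grid_844, radar_nonoise, node=200, n_t=16)
        combo = RadarCube(
            samples=2.0 * c1.samples + 0.5 * c2.samples,
            config_ref=radar_nonoise,
            t_slow_s=c1.t_slow_s,
        )
        lhs = beamform_array(combo, grid_844)
        rhs = 2.0 * beamform_array(c1, grid_844) + 0.5 * beamform_array(c2, grid_844)
        assert np.abs(lhs - rhs).max() / np.abs(rhs).max() < 1e-5


class TestExtractPhase:
    def test_constant_series_has_zero_phase_variance(self):
        series = np.full(100, 1.0 + 1.0j)
        phase = extract_phase(series)
        assert phase.var() < 1e-20

    def test_recovered_amplitude_matches_round_trip_over_wavelength(self):
        # 0.25 mm one-way (0.5 mm round trip) at the 5 mm carrier
        grid = make_grid((1, 1, 1), x_extent=(0, 0), y_extent=(0.4, 0.4), z_extent=(0, 0))
        cfg = RadarConfig(n_pairs=1, n_fast=1, noise_sigma=0.0,
                          pair_positions=np.zeros((1, 3)))
        t = np.arange(800) / cfg.chirp_rate_hz
        one_way = 0.25e-3 * np.sin(2 * np.pi * 1.2 * t)
        cube = single_scatterer_cube(grid, cfg, node=0, displacement=one_way, n_t=800)
        series = beamform_array(cube, grid)[0]
        phase = extract_phase(series)
        phase = phase - phase.mean()
        swing = (phase.max() - phase.min()) / 2
        assert swing == pytest.approx(2 * np.pi * 0.5e-3 / 5.0e-3, rel=0.02)

    def test_unwrap_leaves_no_jumps_beyond_pi(self):
        t = np.linspace(0, 4, 400)
        series = np.exp(1j * (6 * np.pi * t))      # crosses the branch cut often
        phase = extract_phase(series)
        assert np.abs(np.diff(phase)).max() <= np.pi

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            extract_phase(np.zeros(50, dtype=complex))


class TestLocalizeTorso:
    def _voxels(self, series):
        return [
            VoxelSignal(np.zeros(3), s, i) for i, s in enumerate(series)
        ]

    def test_moving_scatterer_selected_among_static_clutter(self, grid_844):
        cfg = RadarConfig(noise_sigma=0.0)
        state = sample_cardiac_state("NORMAL", 20, seed=3)
        field = render_torso_displacement(state, grid_844, fs_hz=100)
        moving = int(np.argmax(field.values.std(axis=1)))
        from radiosem.world import sample_clutter

        cube = simulate_radar(field, cfg, sample_clutter(4, seed=5), seed=1)
        voxels = beamform(cube, grid_844)
        selected = localize_torso(voxels, top_k=16, fs_hz=100)
        assert moving in selected

    def test_top_k_equal_to_grid_is_identity(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=(5, 300)) + 1j * rng.normal(size=(5, 300))
        sel = localize_torso(self._voxels(series), top_k=5, fs_hz=100)
        np.testing.assert_array_equal(sel, np.arange(5))

    def test_identical_voxels_tie_break_to_lower_index(self):
        t = np.arange(300) / 100
        s = np.exp(1j * 0.5 * np.sin(2 * np.pi * 1.5 * t))
        series = [s.copy(), s.copy(), 0.01 * np.ones(300, dtype=complex)]
        sel = localize_torso(self._voxels(series), top_k=1, fs_hz=100)
        assert sel.tolist() == [0]

    def test_all_zero_signals_raise(self):
        series = [np.zeros(100, dtype=complex)] * 3
        with pytest.raises(ValueError, match="no reflector"):
            localize_torso(self._voxels(series), top_k=1, fs_hz=100)


class TestSuppressRespiration:
    def test_respiration_band_attenuated(self):
        t = np.arange(3000) / 100
        resp = np.sin(2 * np.pi * 0.25 * t)
        out = suppress_respiration(resp, 100)
        assert np.sqrt((out**2).mean()) <= 0.1 * np.sqrt((resp**2).mean())

    def test_cardiac_band_preserved(self):
        t = np.arange(3000) / 100
        card = np.sin(2 * np.pi * 1.2 * t)
        out = suppress_respiration(card, 100)
        assert np.sqrt((out**2).mean()) >= 0.9 * np.sqrt((card**2).mean())

    def test_zero_series_stays_zero(self):
        out = suppress_respiration(np.zeros(500), 100)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            suppress_respiration(np.ones(10), 100)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            suppress_respiration(np.ones(500), 100, band=(30.0, 60.0))


class TestMotionTensor:
    def test_single_scatterer_recovery_correlates_with_truth(self, grid_844):
        state = sample_cardiac_state("NORMAL", 30, seed=8)
        field = render_torso_displacement(
            state, grid_844, respiration_amp_m=0.0, fs_hz=100
        )
        v = int(np.argmax(field.values.std(axis=1)))
        mask = np.zeros(grid_844.n_voxels, dtype=bool)
        mask[v] = True
        single = DisplacementField(
            values=np.where(mask[:, None], field.values, 0.0),
            grid=grid_844,
            fs_hz=100,
            torso_mask=mask,
        )
        cfg = RadarConfig(noise_sigma=0.0)
        cube = simulate_radar(single, cfg, seed=0)
        mt = build_motion_tensor(cube, grid_844, top_k=8)
        rec = mt.flat[v]
        truth = suppress_respiration(field.values[v], 100)
        r = np.corrcoef(rec, truth)[0, 1]
        assert r >= 0.98

    def test_static_scene_yields_near_zero_tensor(self, grid_844, radar_nonoise):
        cube = single_scatterer_cube(grid_844, radar_nonoise, node=33, n_t=600)
        mt = build_motion_tensor(cube, grid_844, top_k=None)
        assert np.abs(mt.values).max() < 1e-6

    def test_same_cube_twice_gives_identical_tensor(self, grid_844, normal_state):
        cfg = RadarConfig(noise_sigma=0.5)
        field = render_torso_displacement(normal_state, grid_844, fs_hz=100)
        cube = simulate_radar(field, cfg, seed=2)
        a = build_motion_tensor(cube, grid_844)
        b = build_motion_tensor(cube, grid_844)
        np.testing.assert_array_equal(a.values, b.values)
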