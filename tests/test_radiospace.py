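"""Radio semantic learning: invariant transform, the four-term objective,
and cross-modal training contracts at toy scale."""

import numpy as np
import pytest

from radiosem import nn
from radiosem.ecgspace import EcgVae
from radiosem.frontend import CARDIAC_BAND_HZ
from radiosem.radiospace import (
    RadioModelConfig,
    RadioSemanticModel,
    noncardiac_component,
    radio_loss,
    semantic_invariant_transform,
)

from test_ecgspace import tiny_config, tiny_segments


def band_rms(x, fs, band=CARDIAC_BAND_HZ):
    x = x - x.mean(axis=-1, keepdims=True)
    win = np.hanning(x.shape[-1])          # limit spectral leakage
    spec = np.abs(np.fft.rfft(x * win, axis=-1))
    freqs = np.fft.rfftfreq(x.shape[-1], 1 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return np.sqrt((spec[..., sel] ** 2).sum())


def pulse_motion(seed, fs=50.0, n_voxels=4, seconds=10.0, f_beat=1.2):
    """Beat-locked smooth pulse train over a few voxels plus white noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(seconds * fs)) / fs
    period = 1 / f_beat
    centred = (t + period / 2) % period - period / 2
    pulse = np.exp(-0.5 * (centred / 0.08) ** 2)
    gains = rng.uniform(0.5, 1.5, (n_voxels, 1))
    return (gains * pulse[None, :] + 0.05 * rng.standard_normal((n_voxels, t.size))).astype(
        np.float32
    )


class TestSemanticInvariantTransform:
    def test_zero_strength_is_identity(self):
        x = pulse_motion(0)
        out = semantic_invariant_transform(x, [pulse_motion(1)], 0.0, seed=0)
        np.testing.assert_array_equal(out, x)

    def test_deterministic_in_seed(self):
        x = pulse_motion(0)
        pool = [pulse_motion(1), pulse_motion(2)]
        a = semantic_invariant_transform(x, pool, 1.0, seed=3, fs_hz=50)
        b = semantic_invariant_transform(x, pool, 1.0, seed=3, fs_hz=50)
        np.testing.assert_array_equal(a, b)

    def test_content_at_target_beat_frequency_preserved(self):
        # donor beats at a different rate; energy at the target's own
        # beat frequency must survive the perturbation
        x = pulse_motion(0, f_beat=1.2)
        donor = pulse_motion(5, f_beat=0.9)
        out = semantic_invariant_transform(x, [donor], 1.0, seed=1, fs_hz=50)
        before = band_rms(x, 50, band=(1.1, 1.3))
        after = band_rms(out, 50, band=(1.1, 1.3))
        assert abs(after - before) / before < 0.05

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="donor"):
            semantic_invariant_transform(pulse_motion(0), [], 1.0, seed=0)

    def test_noncardiac_component_suppresses_beat_fundamental(self):
        donor = pulse_motion(7, f_beat=1.1)
        nc = noncardiac_component(donor, 50.0)
        band = (0.95, 1.25)
        assert band_rms(nc, 50, band) < 0.1 * band_rms(donor, 50, band)


class _StubCoder:
    """Callable standing in for an encoder/decoder with fixed output."""

    def __init__(self, out):
        self.out = np.asarray(out, dtype=np.float32)

    def __call__(self, _):
        return nn.Tensor(self.out)


class _StubNet:
    def __init__(self, z, z_t_unused, xhat):
        self.encoder = _StubCoder(z)
        self.decoder = _StubCoder(xhat)


class TestRadioLoss:
    def _inputs(self):
        x_r = nn.Tensor(np.zeros((1, 2, 4), dtype=np.float32))
        x_e = nn.Tensor(np.zeros((1, 1, 8), dtype=np.float32))
        return x_r, x_e

    def test_hand_computed_total_on_stubs(self):
        # all stub outputs chosen exactly representable in binary floats
        x_r, x_e = self._inputs()
        z = np.array([[1.0, 0.0, 0.0, 0.0]])
        ze = np.array([[0.0, 1.0, 0.0, 0.0]])        # orthogonal -> cos = 0
        xhat = np.full((1, 2, 4), 0.5, dtype=np.float32)
        net = _StubNet(z, z, xhat)
        cfg = RadioModelConfig(alpha=0.5, gamma=1.0, delta=0.25, obs_sigma2=0.01)
        ecg_dec = _StubCoder(np.full((1, 1, 8), 2.0))
        total, comps = radio_loss(x_r, x_r, x_e, ze, net, ecg_dec, cfg)
        # recon: mean(0.5^2)/0.01 = 25; inv: 0; align: 1*(1-0) = 1;
        # cross: 0.25*mean(2^2) = 1
        assert comps["reconstruction"] == pytest.approx(25.0, abs=1e-9)
        assert comps["invariance"] == 0.0
        assert comps["alignment"] == pytest.approx(1.0, abs=1e-9)
        assert comps["cross_decoding"] == pytest.approx(1.0, abs=1e-9)
        assert total.item() == pytest.approx(27.0, abs=1e-9)

    def test_components_sum_to_total(self):
        x_r, x_e = self._inputs()
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, (1, 4)).astype(np.float32)
        ze = rng.normal(0, 1, (1, 4)).astype(np.float32)
        net = _StubNet(z, z, rng.normal(0, 1, (1, 2, 4)).astype(np.float32))
        cfg = RadioModelConfig()
        ecg_dec = _StubCoder(rng.normal(0, 1, (1, 1, 8)).astype(np.float32))
        total, comps = radio_loss(x_r, x_r, x_e, ze, net, ecg_dec, cfg)
        parts = sum(
            comps[k] for k in ("reconstruction", "invariance", "alignment", "cross_decoding")
        )
        assert total.item() == pytest.approx(parts, rel=1e-6)

    def test_parallel_latents_zero_alignment(self):
        x_r, x_e = self._inputs()
        z = np.array([[2.0, 0.0, 0.0, 0.0]])
        ze = np.array([[4.0, 0.0, 0.0, 0.0]])        # parallel -> cos = 1
        net = _StubNet(z, z, np.zeros((1, 2, 4), dtype=np.float32))
        cfg = RadioModelConfig(gamma=1.0)
        _, comps = radio_loss(x_r, x_r, x_e, ze, net, _StubCoder(np.zeros((1, 1, 8))), cfg)
        assert comps["alignment"] == pytest.approx(0.0, abs=1e-6)

    def test_identity_transform_zeroes_invariance(self):
        x_r, x_e = self._inputs()
        z = np.array([[1.0, 1.0, 0.0, 0.0]])
        net = _StubNet(z, z, np.zeros((1, 2, 4), dtype=np.float32))
        _, comps = radio_loss(
            x_r, x_r, x_e, z, net, _StubCoder(np.zeros((1, 1, 8))), RadioModelConfig()
        )
        assert comps["invariance"] == 0.0


@pytest.fixture(scope="module")
def tiny_world():
    """Toy paired dataset plus a frozen toy ECG space."""
    segs, labels = tiny_segments(n=24)
    ecg_space = EcgVae(segs, labels, tiny_config(epochs=4)).fit()
    rng = np.random.default_rng(0)
    motion = np.stack([pulse_motion(i, seconds=5.0, n_voxels=6) for i in range(24)])
    sids = [f"s{i % 8}" for i in range(24)]
    cfg = RadioModelConfig(
        latent_dim=16, global_dims=4, conv_channels=6, temporal_depth=2,
        fs_hz=50.0, segment_s=5.0, epochs=8, batch_size=8, seed=0,
    )
    return motion, segs, sids, ecg_space, cfg


class TestRadioTraining:
    def test_fit_decreases_loss_with_finite_components(self, tiny_world):
        motion, segs, sids, ecg_space, cfg = tiny_world
        model = RadioSemanticModel(motion, segs, sids, ecg_space, cfg)
        res = model.fit()
        for entry in res.training_log:
            for key in ("reconstruction", "invariance", "alignment", "cross_decoding"):
                assert np.isfinite(entry[key])
        # augmentation adds per-epoch noise; compare early vs late averages
        totals = [e["total"] for e in res.training_log]
        assert np.mean(totals[-2:]) < np.mean(totals[:2])

    def test_gradient_isolation_ecg_parameters_untouched(self, tiny_world):
        motion, segs, sids, ecg_space, cfg = tiny_world
        before = [p.data.copy() for p in ecg_space.net.parameters()]
        RadioSemanticModel(motion, segs, sids, ecg_space, cfg).fit()
        for b, p in zip(before, ecg_space.net.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_unfrozen_ecg_space_rejected(self, tiny_world):
        motion, segs, sids, ecg_space, cfg = tiny_world
        ecg_space.net.unfreeze()
        try:
            with pytest.raises(RuntimeError, match="frozen"):
                RadioSemanticModel(motion, segs, sids, ecg_space, cfg)
        finally:
            ecg_space.net.freeze()

    def test_encoder_batch_independence(self, tiny_world):
        motion, segs, sids, ecg_space, cfg = tiny_world
        res = RadioSemanticModel(motion, segs, sids, ecg_space, cfg).fit()
        z = res.encode_batch(motion[:6])
        perm = [3, 1, 0, 5, 2, 4]
        z_perm = res.encode_batch(motion[perm])
        np.testing.assert_allclose(z_perm, z[perm], rtol=1e-5, atol=1e-6)

    def test_project_returns_consistent_triple(self, tiny_world):
        motion, segs, sids, ecg_space, cfg = tiny_world
        res = RadioSemanticModel(motion, segs, sids, ecg_space, cfg).fit()
        factors, ecg_view, radio_view = res.project(motion[0])
        assert factors.mean.shape == (16,)
        assert ecg_view.shape == (ecg_space.config.n_samples,)
        assert radio_view.shape == motion[0].shape
        f2, e2, r2 = res.project(motion[0])
        np.testing.assert_array_equal(factors.mean, f2.mean)
        np.testing.assert_array_equal(ecg_view, e2)

    def test_perturbing_a_factor_at_its_own_value_is_identity(self, tiny_world):
        from radiosem.readout import perturb_factor

        motion, segs, sids, ecg_space, cfg = tiny_world
        res = RadioSemanticModel(motion, segs, sids, ecg_space, cfg).fit()
        factors, ecg_view, radio_view = res.project(motion[0])
        z = factors.mean
        views = perturb_factor(z, 3, [z[3], z[3] + 2.0], ecg_space, res)
        np.testing.assert_allclose(views[0][0], ecg_view, atol=1e-5)
        np.testing.assert_allclose(views[0][1], radio_view, atol=1e-5)
        assert not np.allclose(views[1][0], ecg_view)

    def test_save_load_roundtrip(self, tiny_world, tmp_path):
        motion, segs, sids, ecg_space, cfg = tiny_world
        res = RadioSemanticModel(motion, segs, sids, ecg_space, cfg).fit()
        path = tmp_path / "radio.npz"
        res.save(path)
        from radiosem.radiospace import RadioSemanticResults

        loaded = RadioSemanticResults.load(path, ecg_space)
        np.testing.assert_array_equal(
            loaded.encode_batch(motion[:3]), res.encode_batch(motion[:3])
        )
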