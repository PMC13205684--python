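"""Radio semantic representation learning.

A deterministic radio encoder/decoder pair is trained against the frozen
ECG semantic space with four loss terms: radio reconstruction, latent
invariance under semantic-invariant signal transformations (donor
mixing), cosine alignment between radio and ECG factors, and an
auxiliary ECG reconstruction decoded from the radio latent:

    L = ||X_R - D_R(E_R(X_R))||^2
      + alpha * ||E_R(T(X_R)) - E_R(X_R)||^2
      + gamma * (1 - cos(E_R(X_R), E_E(X_E)))
      + delta * ||X_E - D_E(E_R(X_R))||^2

with defaults alpha=0.1, gamma=1, delta=1e-4. At test time only radio
input is required: the frozen encoder projects it into the semantic
space, and both frozen decoders visualize the factors as radio and ECG
waveforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
from scipy import signal as sp_signal

from . import nn
from .ecgspace import (
    EcgVaeResults,
    Modality,
    SemanticFactors,
    _pooled_stats,
    mulaw_encode,
)
from .frontend import CARDIAC_BAND_HZ


@dataclass
class RadioModelConfig:
    alpha: float = 0.1                # invariance weight
    gamma: float = 1.0                # alignment weight
    delta: float = 1e-4               # cross-decoding weight
    recon_weight: float = 1.0         # radio reconstruction weight (ablation hook)
    latent_dim: int = 64
    global_dims: int = 12             # must match the ECG space layout
    conv_channels: int = 16
    spatial_channels: int = 8
    temporal_depth: int = 4           # residual blocks in the temporal stack
    fs_hz: float = 50.0
    segment_s: float = 10.0
    motion_scale: float = 2.0         # radians; fixed input normalization
    transform_strength: float = 1.0
    obs_sigma2: float = 0.01          # radio reconstruction noise variance
    input_noise: float = 0.02         # white-noise augmentation on inputs
    gain_noise: float = 0.3           # per-voxel propagation-gain augmentation
    augment_prob: float = 0.5         # chance a sample enters as T(x)
    weight_decay: float = 3e-4
    lr: float = 2e-3
    batch_size: int = 32
    epochs: int = 32
    seed: int = 0

    def __post_init__(self):
        if min(self.alpha, self.gamma, self.delta) < 0:
            raise ValueError("alpha, gamma, delta must be nonnegative")
        if self.n_frames % 5 != 0:
            raise ValueError("segment frames (fs_hz * segment_s) must be divisible by 5")

    @property
    def n_frames(self) -> int:
        return int(round(self.fs_hz * self.segment_s))


@dataclass
class PairedSample:
    """Synchronized 10-s motion-tensor and ECG segments from one subject."""

    motion: np.ndarray                # (V, T) at the motion-tensor rate
    ecg_mv: np.ndarray                # (L,) millivolts at the ECG model rate
    subject_id: str
    motion_fs_hz: float = 100.0


# ---------------------------------------------------------------------------
# semantic-invariant transformation T(.)
# ---------------------------------------------------------------------------

def noncardiac_component(
    motion: np.ndarray,
    fs_hz: float,
    band: tuple[float, float] = CARDIAC_BAND_HZ,
) -> np.ndarray:
    """Non-cardiac content of a motion segment: the cardiac-band-stopped
    residual plus the static (DC) spatial pattern."""
    nyq = fs_hz / 2
    sos = sp_signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandstop", output="sos")
    dc = motion.mean(axis=-1, keepdims=True)
    return sp_signal.sosfiltfilt(sos, motion - dc, axis=-1) + dc


def semantic_invariant_transform(
    x: np.ndarray,
    donor_pool: list[np.ndarray],
    strength: float,
    seed: int,
    fs_hz: float = 100.0,
) -> np.ndarray:
    """Perturb `x` with a seeded random donor's non-cardiac component.

    The donor contribution carries no cardiac-band energy at x's beat
    frequency, so the beat-timing ground truth of `x` is unchanged by
    construction. Callers must exclude x's own subject from the pool.
    """
    if len(donor_pool) == 0:
        raise ValueError("empty donor pool")
    if strength == 0:
        return x.copy()
    rng = np.random.default_rng(seed)
    donor = donor_pool[int(rng.integers(len(donor_pool)))]
    return x + strength * noncardiac_component(donor, fs_hz)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class RadioEncoderNet(nn.Module):
    """Spatial compression (1x1 conv over voxels) + temporal conv stack."""

    def __init__(self, cfg: RadioModelConfig, n_voxels: int, rng: np.random.Generator):
        cs, c = cfg.spatial_channels, cfg.conv_channels
        self.spatial = nn.Conv1d(n_voxels, cs, 1, rng)
        self.c_in = nn.Conv1d(cs, c, 11, rng, stride=5, padding=3)
        self.res = [nn.ResBlock1d(c, 9, rng) for _ in range(cfg.temporal_depth // 2)]
        self.flat_dim = c * (cfg.n_frames // 5)
        self.n_global = cfg.global_dims
        # dual-path latent mirroring the ECG encoder: pooled feature
        # statistics feed the global dims, the flattened map the timing dims
        self.out = nn.Linear(self.flat_dim, cfg.latent_dim - self.n_global, rng)
        self.out.w.data *= 0.05
        grid_fs = cfg.fs_hz / 5.0
        self.lag_cells = sorted(
            {max(1, int(round(s * grid_fs))) for s in (0.3, 0.5, 0.8, 1.2)}
        )
        self.out_global = nn.Linear((2 + len(self.lag_cells)) * c, self.n_global, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.spatial(x).relu()
        h = self.c_in(h).relu()
        for blk in self.res:
            h = blk(h)
        z_t = self.out(h.reshape(h.shape[0], self.flat_dim))
        pooled = nn.concat(_pooled_stats(h, self.lag_cells), axis=1)
        z_g = self.out_global(pooled)
        return nn.concat([z_g, z_t], axis=1)


class RadioDecoderNet(nn.Module):
    def __init__(self, cfg: RadioModelConfig, n_voxels: int, rng: np.random.Generator):
        cs, c = cfg.spatial_channels, cfg.conv_channels
        self.c = c
        self.base_len = cfg.n_frames // 5
        self.inp = nn.Linear(cfg.latent_dim, c * self.base_len, rng)
        self.res = [
            nn.ResBlock1d(c, 9, rng)
            for _ in range(cfg.temporal_depth - cfg.temporal_depth // 2)
        ]
        self.up = nn.Conv1d(c, cs, 11, rng)
        self.spatial = nn.Conv1d(cs, n_voxels, 1, rng)
        self.spatial.w.data *= 0.1

    def forward(self, z: nn.Tensor) -> nn.Tensor:
        B = z.shape[0]
        h = self.inp(z).relu().reshape(B, self.c, self.base_len)
        for blk in self.res:
            h = blk(h)
        h = self.up(nn.upsample1d(h, 5)).relu()
        return self.spatial(h)


class RadioNet(nn.Module):
    def __init__(self, cfg: RadioModelConfig, n_voxels: int, rng: np.random.Generator):
        self.encoder = RadioEncoderNet(cfg, n_voxels, rng)
        self.decoder = RadioDecoderNet(cfg, n_voxels, rng)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _row_cosine(a: nn.Tensor, b: nn.Tensor, eps: float = 1e-8) -> nn.Tensor:
    dot = (a * b).sum(axis=1)
    na = ((a**2).sum(axis=1) + eps) ** 0.5
    nb = ((b**2).sum(axis=1) + eps) ** 0.5
    return dot / (na * nb)


def radio_loss(
    x_r: nn.Tensor,
    x_r_transformed: nn.Tensor,
    x_e: nn.Tensor,
    z_e: np.ndarray,
    net: RadioNet,
    ecg_decoder,
    config: RadioModelConfig,
) -> tuple[nn.Tensor, dict]:
    """Four-term radio objective; components are the weighted terms and
    sum exactly to the total.

    ``ecg_decoder`` is the frozen ECG decoder (companded-output callable);
    a hard error is raised if any of its parameters could receive
    gradients.
    """
    if isinstance(ecg_decoder, nn.Module) and not ecg_decoder.frozen:
        raise RuntimeError("ECG decoder must be frozen during radio training")
    # each squared norm is averaged per element (MSE convention) so the
    # four terms are commensurate and the printed weights are meaningful
    zr = net.encoder(x_r)
    zr_t = net.encoder(x_r_transformed)
    xhat = net.decoder(zr)

    recon = config.recon_weight * (((xhat - x_r) ** 2).mean() / config.obs_sigma2)
    inv = config.alpha * (((zr_t - zr) ** 2).mean())
    ze_t = nn.Tensor(np.asarray(z_e, dtype=np.float32))
    # cosine alignment, balanced over the two factor groups: a single
    # whole-vector cosine is dominated by the (many) timing factors and
    # starves the semantic block of training signal
    g = config.global_dims
    if 0 < g < zr.shape[1] and zr.shape[1] == config.latent_dim:
        cos = 0.5 * (
            _row_cosine(zr[:, :g], ze_t[:, :g])
            + _row_cosine(zr[:, g:], ze_t[:, g:])
        )
    else:
        cos = _row_cosine(zr, ze_t)
    align = config.gamma * ((1.0 - cos).mean())
    ehat = ecg_decoder(zr)
    cross = config.delta * (((ehat - x_e) ** 2).mean())
    total = recon + inv + align + cross
    comps = {
        "reconstruction": recon.item(),
        "invariance": inv.item(),
        "alignment": align.item(),
        "cross_decoding": cross.item(),
        "total": total.item(),
    }
    for name, v in comps.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component: {name}")
    return total, comps


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class RadioSemanticModel:
    """Cross-modal model fitted on paired radio-ECG segments.

    ``motion_segments`` are (n, V, T) motion-tensor segments at the
    configured frame rate (use :meth:`from_pairs` to decimate from the
    front-end rate); ``ecg_segments_mv`` are the synchronized ECG
    segments at the frozen ECG model's rate.
    """

    def __init__(
        self,
        motion_segments: np.ndarray,
        ecg_segments_mv: np.ndarray,
        subject_ids: list[str],
        ecg_space: EcgVaeResults,
        config: RadioModelConfig | None = None,
    ):
        self.config = config or RadioModelConfig()
        x = np.asarray(motion_segments, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] < self.config.n_frames:
            raise ValueError(f"motion segments must be (n, V, >= {self.config.n_frames})")
        if len(subject_ids) != x.shape[0] or len(ecg_segments_mv) != x.shape[0]:
            raise ValueError("motion, ecg and subject_ids must align")
        if self.config.latent_dim != ecg_space.config.latent_dim:
            raise ValueError("latent_dim must match the frozen ECG space")
        if not ecg_space.net.frozen:
            raise RuntimeError("ECG space must be frozen before radio training")
        self.x = x / self.config.motion_scale
        self.subject_ids = list(subject_ids)
        self.ecg_space = ecg_space
        ecg = np.asarray(ecg_segments_mv, dtype=float)
        # rows longer than one segment are recordings: training crops
        # random synchronized windows from both modalities
        self.crop_range = x.shape[2] - self.config.n_frames
        self.fs_ratio = ecg_space.config.fs_hz / self.config.fs_hz
        if self.crop_range > 0:
            expect = round((x.shape[2] / self.config.fs_hz) * ecg_space.config.fs_hz)
            if abs(ecg.shape[1] - expect) > 2:
                raise ValueError("motion and ecg recordings cover different spans")
        xe = np.clip(ecg / ecg_space.config.amp_scale_mv, -1, 1)
        self.x_e = mulaw_encode(xe, ecg_space.config.mu_law_mu)[:, None, :].astype(np.float32)
        # alignment target is the per-dimension standardized semantic
        # space: without z-scoring, the whole-vector cosine is dominated
        # by high-variance factors and ignores low-variance semantic ones
        z_stats = self._reference_factors(ecg)
        self.ze_mean = z_stats.mean(axis=0)
        self.ze_sd = np.maximum(z_stats.std(axis=0), 1e-2)
        self.z_e = (
            (z_stats - self.ze_mean) / self.ze_sd if self.crop_range == 0 else None
        )

    def _reference_factors(self, ecg_mv: np.ndarray) -> np.ndarray:
        """ECG posterior means used for standardization statistics (and,
        for fixed-length input, as the per-sample alignment targets)."""
        n_e = self.ecg_space.config.n_samples
        if self.crop_range == 0:
            return self.ecg_space.encode_batch(ecg_mv).astype(np.float32)
        step = n_e // 2
        crops = [
            ecg_mv[:, o : o + n_e] for o in range(0, ecg_mv.shape[1] - n_e + 1, step)
        ]
        return self.ecg_space.encode_batch(np.concatenate(crops)).astype(np.float32)

    @classmethod
    def from_pairs(
        cls,
        pairs: list[PairedSample],
        ecg_space: EcgVaeResults,
        config: RadioModelConfig | None = None,
    ) -> "RadioSemanticModel":
        config = config or RadioModelConfig()
        motions = np.stack(
            [resample_motion(p.motion, p.motion_fs_hz, config.fs_hz) for p in pairs]
        )
        ecgs = np.stack([p.ecg_mv for p in pairs])
        return cls(motions, ecgs, [p.subject_id for p in pairs], ecg_space, config)

    # crop offsets are quantized to this many motion frames so alignment
    # targets can be encoded once per (recording, offset) and cached
    _OFFSET_STEP_S = 0.4

    def _offset_step(self) -> int:
        return max(1, int(round(self._OFFSET_STEP_S * self.config.fs_hz)))

    def _precompute_ze_grid(self) -> np.ndarray:
        """Standardized alignment targets for every quantized crop."""
        n_e = self.ecg_space.config.n_samples
        step_e = int(round(self._offset_step() * self.fs_ratio))
        n_bins = self.crop_range // self._offset_step() + 1
        crops = np.concatenate(
            [self.x_e[:, 0, o * step_e : o * step_e + n_e] for o in range(n_bins)]
        )
        out = []
        for start in range(0, crops.shape[0], 256):
            mu, _ = self.ecg_space.encode_companded(crops[start : start + 256][:, None, :])
            out.append(mu.astype(np.float32))
        z = np.concatenate(out)
        z = (z - self.ze_mean) / self.ze_sd
        return z.reshape(n_bins, self.x.shape[0], -1).transpose(1, 0, 2)

    def _batch(self, idx: np.ndarray, rng: np.random.Generator):
        """Assemble one training batch; long rows get synchronized random
        crops from both modalities with cached alignment targets."""
        cfg = self.config
        if self.crop_range == 0:
            return self.x[idx], self.x_e[idx], self.z_e[idx]
        step = self._offset_step()
        n_e = self.ecg_space.config.n_samples
        bins = rng.integers(0, self.crop_range // step + 1, idx.size)
        offs = bins * step
        xb = np.stack(
            [self.x[i][:, o : o + cfg.n_frames] for i, o in zip(idx, offs)]
        )
        xeb = np.stack(
            [
                self.x_e[i][:, int(round(o * self.fs_ratio)) : int(round(o * self.fs_ratio)) + n_e]
                for i, o in zip(idx, offs)
            ]
        )
        zeb = self._ze_grid[idx, bins]
        return xb, xeb, zeb

    def _precompute_noncardiac(self) -> np.ndarray:
        out = np.empty_like(self.x)
        for i in range(self.x.shape[0]):
            out[i] = noncardiac_component(self.x[i], self.config.fs_hz)
        return out

    def fit(self, epochs: int | None = None, verbose: bool = False) -> "RadioSemanticResults":
        cfg = self.config
        epochs = epochs or cfg.epochs
        rng = np.random.default_rng(cfg.seed + 17)
        n, V, _ = self.x.shape
        net = RadioNet(cfg, V, rng)
        opt = nn.Adam(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        noncardiac = self._precompute_noncardiac() if cfg.alpha > 0 else None
        if self.crop_range > 0:
            self._ze_grid = self._precompute_ze_grid()
        subj = np.array(self.subject_ids)
        ecg_params_before = [p.data.copy() for p in self.ecg_space.net.parameters()]
        log: list[dict] = []
        checkpoint = [a.copy() for a in net.state_arrays()]
        for epoch in range(epochs):
            opt.lr = cfg.lr * (0.3 if epoch >= int(0.75 * epochs) else 1.0)
            order = rng.permutation(n)
            sums: dict[str, float] = {}
            n_batches = 0
            try:
                for start in range(0, n, cfg.batch_size):
                    idx = order[start : start + cfg.batch_size]
                    if idx.size < 2:
                        continue
                    xb, xeb, zeb = self._batch(idx, rng)

                    def donor_crop(donors):
                        if self.crop_range == 0:
                            return noncardiac[donors]
                        offs = rng.integers(0, self.crop_range + 1, donors.size)
                        return np.stack(
                            [
                                noncardiac[j][:, o : o + cfg.n_frames]
                                for j, o in zip(donors, offs)
                            ]
                        )

                    if noncardiac is not None:
                        # data-level semantic-invariant augmentation: some
                        # samples enter the batch as T(x); the semantics
                        # (and hence the alignment target) are unchanged
                        donors0 = _pick_donors(idx, subj, rng)
                        s0 = rng.uniform(0.5, 1.5, (idx.size, 1, 1)).astype(np.float32)
                        aug = (rng.random(idx.size) < cfg.augment_prob)[:, None, None]
                        xb = xb + np.where(
                            aug, cfg.transform_strength * s0 * donor_crop(donors0), 0.0
                        ).astype(np.float32)
                        donors = _pick_donors(idx, subj, rng)
                        s1 = rng.uniform(0.5, 1.5, (idx.size, 1, 1)).astype(np.float32)
                        xb_t = xb + cfg.transform_strength * s1 * donor_crop(donors)
                    else:
                        xb_t = xb
                    if cfg.gain_noise > 0:
                        # per-voxel multiplicative gains emulate propagation
                        # variation; cardiac timing is untouched
                        g = 1.0 + rng.uniform(
                            -cfg.gain_noise, cfg.gain_noise, (idx.size, xb.shape[1], 1)
                        ).astype(np.float32)
                        xb = xb * g
                        g2 = 1.0 + rng.uniform(
                            -cfg.gain_noise, cfg.gain_noise, (idx.size, xb.shape[1], 1)
                        ).astype(np.float32)
                        xb_t = xb_t * g2
                    if cfg.input_noise > 0:
                        xb = xb + rng.normal(0, cfg.input_noise, xb.shape).astype(np.float32)
                        xb_t = xb_t + rng.normal(0, cfg.input_noise, xb_t.shape).astype(np.float32)
                    total, comps = radio_loss(
                        nn.Tensor(xb),
                        nn.Tensor(xb_t),
                        nn.Tensor(xeb),
                        zeb,
                        net,
                        self.ecg_space.net.decoder,
                        cfg,
                    )
                    opt.zero_grad()
                    total.backward()
                    opt.step()
                    for k, v in comps.items():
                        sums[k] = sums.get(k, 0.0) + v
                    n_batches += 1
            except FloatingPointError as err:
                warnings.warn(
                    f"radio training diverged at epoch {epoch} ({err}); "
                    "restoring last good checkpoint",
                    stacklevel=2,
                )
                net.load_state_arrays(checkpoint)
                break
            entry = {k: v / max(n_batches, 1) for k, v in sums.items()}
            entry["epoch"] = epoch
            log.append(entry)
            checkpoint = [a.copy() for a in net.state_arrays()]
            if verbose:
                print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4f}" for k, v in entry.items()))
        for before, p in zip(ecg_params_before, self.ecg_space.net.parameters()):
            if not np.array_equal(before, p.data):
                raise RuntimeError("gradient isolation violated: ECG parameters changed")
        net.freeze()
        return RadioSemanticResults(
            net=net,
            config=cfg,
            ecg_space=self.ecg_space,
            n_voxels=V,
            training_log=log,
            ze_mean=self.ze_mean,
            ze_sd=self.ze_sd,
        )


def _pick_donors(idx: np.ndarray, subj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """For each sample, a random donor index from a different subject."""
    donors = np.empty(idx.size, dtype=int)
    n = subj.size
    for k, i in enumerate(idx):
        j = int(rng.integers(n))
        for _ in range(16):
            if subj[j] != subj[i]:
                break
            j = int(rng.integers(n))
        donors[k] = j
    return donors


def resample_motion(motion: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if abs(fs_in - fs_out) < 1e-9:
        return np.asarray(motion, dtype=np.float32)
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    out = sp_signal.resample_poly(np.asarray(motion, dtype=float), frac.numerator, frac.denominator, axis=-1)
    return out.astype(np.float32)


@dataclass
class RadioSemanticResults:
    """Frozen radio encoder/decoder tied to a frozen ECG space."""

    net: RadioNet
    config: RadioModelConfig
    ecg_space: EcgVaeResults
    n_voxels: int
    training_log: list[dict] = field(default_factory=list)
    ze_mean: np.ndarray | None = None   # standardization of the semantic space
    ze_sd: np.ndarray | None = None

    def standardize_ecg_factors(self, z_e: np.ndarray) -> np.ndarray:
        """Map raw ECG posterior means into the standardized semantic
        space that Z_R lives in."""
        if self.ze_mean is None:
            return z_e
        return (z_e - self.ze_mean) / self.ze_sd

    def _unstandardize(self, z: np.ndarray) -> np.ndarray:
        if self.ze_mean is None:
            return z
        return z * self.ze_sd + self.ze_mean

    def _prepare(self, motion: np.ndarray) -> np.ndarray:
        x = np.asarray(motion, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.n_voxels or x.shape[2] != self.config.n_frames:
            raise ValueError(
                f"motion must be (n, {self.n_voxels}, {self.config.n_frames}); got {x.shape}"
            )
        return x / self.config.motion_scale

    def encode_batch(self, motion: np.ndarray) -> np.ndarray:
        x = self._prepare(motion)
        out = []
        for start in range(0, x.shape[0], 128):
            out.append(self.net.encoder(nn.Tensor(x[start : start + 128])).data.copy())
        return np.concatenate(out, axis=0)

    def encode(self, motion: np.ndarray, source_id: str = "") -> SemanticFactors:
        z = self.encode_batch(motion)[0]
        return SemanticFactors(z, None, Modality.RADIO, source_id)

    def project(
        self, motion: np.ndarray, source_id: str = ""
    ) -> tuple[SemanticFactors, np.ndarray, np.ndarray]:
        """Radio-only test-time projection.

        Returns (semantic factors, ECG-domain view in mV, radio-domain
        view as a (V, T) motion segment).
        """
        x = self._prepare(motion)
        z = self.encode_batch(motion)
        ecg_view = self.ecg_space.decode(self._unstandardize(z))
        radio_view = self.net.decoder(nn.Tensor(z)).data * self.config.motion_scale
        single = np.asarray(motion).ndim == 2
        factors = SemanticFactors(z[0] if single else z, None, Modality.RADIO, source_id)
        if single:
            return factors, ecg_view[0] if ecg_view.ndim > 1 else ecg_view, radio_view[0]
        return factors, ecg_view, radio_view

    def summary(self) -> str:
        cfg = self.config
        lines = ["Radio semantic model", "=" * 34]
        lines.append(
            f"alpha={cfg.alpha}  gamma={cfg.gamma}  delta={cfg.delta}  latent_dim={cfg.latent_dim}"
        )
        lines.append(f"fs={cfg.fs_hz} Hz  segment={cfg.segment_s} s  voxels={self.n_voxels}")
        if self.training_log:
            first, last = self.training_log[0], self.training_log[-1]
            lines.append(
                f"epochs={len(self.training_log)}  loss {first['total']:.4f} -> {last['total']:.4f}"
            )
            lines.append(
                "final components: "
                + " ".join(
                    f"{k}={last[k]:.4f}"
                    for k in ("reconstruction", "invariance", "alignment", "cross_decoding")
                )
            )
        return "\n".join(lines)

    def save(self, path: str) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            __log__=json.dumps(self.training_log),
            __n_voxels__=self.n_voxels,
            __ze_mean__=self.ze_mean if self.ze_mean is not None else np.zeros(0),
            __ze_sd__=self.ze_sd if self.ze_sd is not None else np.zeros(0),
            **arrays,
        )

    @classmethod
    def load(cls, path: str, ecg_space: EcgVaeResults) -> "RadioSemanticResults":
        data = np.load(path, allow_pickle=False)
        cfg = RadioModelConfig(**json.loads(str(data["__config__"])))
        n_voxels = int(data["__n_voxels__"])
        net = RadioNet(cfg, n_voxels, np.random.default_rng(cfg.seed))
        net.load_state_arrays([data[f"p{i}"] for i in range(len(net.parameters()))])
        net.freeze()
        ze_mean = data["__ze_mean__"]
        ze_sd = data["__ze_sd__"]
        return cls(
            net=net,
            config=cfg,
            ecg_space=ecg_space,
            n_voxels=n_voxels,
            training_log=json.loads(str(data["__log__"])),
            ze_mean=ze_mean if ze_mean.size else None,
            ze_sd=ze_sd if ze_sd.size else None,
        )
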