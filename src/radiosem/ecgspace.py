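"""ECG semantic space: mu-law companding and a beta-VAE with a linear
supervised head, trained on 10-s ECG segments and then frozen.

The encoder maps a companded ECG segment to a diagonal-Gaussian
posterior over 64 semantic factors; the decoder reconstructs the
segment; a linear multi-label head predicts the rhythm class from the
latent. The training objective is

    L = recon NLL + beta * KL(q(Z|X) || N(0, I)) + lambda * CE(Y)

with the KL computed in closed form. The fitted space serves as the
semantic reference that radio representations are aligned to.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .world import ECGRecord, Rhythm

RHYTHM_CLASSES = [Rhythm.NORMAL, Rhythm.AF, Rhythm.PB]


class Modality(str, enum.Enum):
    ECG = "ECG"
    RADIO = "RADIO"


@dataclass
class SemanticFactors:
    """A point in the shared semantic space (posterior mean for ECG)."""

    mean: np.ndarray
    logvar: np.ndarray | None
    modality: Modality
    source_id: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("non-finite semantic factors")


@dataclass
class EcgVaeConfig:
    latent_dim: int = 64
    global_dims: int = 12             # latent dims fed from time-pooled features
    beta: float = 1.0
    lambda_sup: float = 30.0
    depth: int = 4                    # residual blocks per coder
    conv_channels: int = 16
    mu_law_mu: float = 255.0
    fs_hz: float = 100.0
    segment_s: float = 10.0
    amp_scale_mv: float = 2.0         # fixed normalization to [-1, 1]
    obs_sigma2: float = 0.02          # Gaussian likelihood variance (companded units)
    deriv_weight: float = 0.0         # optional Sobolev term on first differences
    free_bits: float = 0.25           # per-dimension KL floor (nats) in the penalty
    lr: float = 2e-3
    batch_size: int = 32
    epochs: int = 85
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0 or self.lambda_sup < 0:
            raise ValueError("beta and lambda_sup must be nonnegative")
        if self.n_samples % 5 != 0:
            raise ValueError("segment length (fs_hz * segment_s) must be divisible by 5")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.segment_s))


# ---------------------------------------------------------------------------
# mu-law companding
# ---------------------------------------------------------------------------

def mulaw_encode(x: np.ndarray, mu: float = 255.0) -> np.ndarray:
    """sign(x) * ln(1 + mu|x|) / ln(1 + mu); odd, monotone, maps +-1 -> +-1."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1):
        warnings.warn("mu-law input outside [-1, 1]; clipping", stacklevel=2)
        x = np.clip(x, -1.0, 1.0)
    return np.sign(x) * np.log1p(mu * np.abs(x)) / np.log1p(mu)


def mulaw_decode(y: np.ndarray, mu: float = 255.0) -> np.ndarray:
    """Inverse compander: sign(y) * ((1 + mu)^|y| - 1) / mu."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    y = np.asarray(y, dtype=float)
    return np.sign(y) * (np.power(1.0 + mu, np.abs(y)) - 1.0) / mu


def kl_diag_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag exp(logvar)) || N(0, I) )."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    return float(0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _pooled_stats(h: nn.Tensor, lag_cells: list[int]) -> list[nn.Tensor]:
    """Per-channel mean, second moment, and lagged-product means
    (autocorrelation features) of a (B, C, T) feature map."""
    stats = [h.mean(axis=2), (h * h).mean(axis=2)]
    for lag in lag_cells:
        stats.append((h[:, :, lag:] * h[:, :, :-lag]).mean(axis=2))
    return stats


class EcgEncoderNet(nn.Module):
    """Strided-conv + residual encoder -> (mean, logvar) of the posterior.

    A single stride-5 stage keeps the pre-flatten feature map at a
    50-ms temporal grain, wide enough that exact beat timing survives
    the flatten-to-latent bottleneck.
    """

    def __init__(self, cfg: EcgVaeConfig, rng: np.random.Generator):
        c = cfg.conv_channels
        # padding k//2 - 2 centres the stride-5 stage on input sample
        # 5j + 2, matching the centred upsampling in the decoder
        self.c_in = nn.Conv1d(1, c, 11, rng, stride=5, padding=3)
        self.res = [nn.ResBlock1d(c, 9, rng) for _ in range(cfg.depth // 2)]
        self.flat_dim = c * (cfg.n_samples // 5)
        self.n_global = cfg.global_dims
        n_timing = cfg.latent_dim - self.n_global
        # dual-path latent: the flattened 50-ms map feeds the timing dims;
        # a deeper, wider-receptive-field level feeds time-pooled feature
        # statistics (mean, second moment, max) into the "global" dims,
        # where rates, interval lags and beat-pattern anomalies are
        # near-linear functions of the latent
        self.out = nn.Linear(self.flat_dim, 2 * n_timing, rng)
        self.out.w.data *= 0.05          # start near the N(0, I) prior
        # autocorrelation lags (in feature-grid cells): rhythm statistics
        # such as rate, irregularity and pauses live in the lag structure
        # of beat-locked activations, which plain moments cannot express
        grid_fs = cfg.fs_hz / 5.0
        self.lag_cells = sorted(
            {max(1, int(round(s * grid_fs))) for s in (0.3, 0.5, 0.8, 1.2)}
        )
        n_pool = (2 + len(self.lag_cells)) * c
        self.out_global = nn.Linear(n_pool, 2 * self.n_global, rng)
        self.latent_dim = cfg.latent_dim

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = self.c_in(x).relu()
        for blk in self.res:
            h = blk(h)
        B = h.shape[0]
        stats_t = self.out(h.reshape(B, self.flat_dim))
        pooled = nn.concat(_pooled_stats(h, self.lag_cells), axis=1)
        stats_g = self.out_global(pooled)
        n_t = self.latent_dim - self.n_global
        mu = nn.concat([stats_g[:, : self.n_global], stats_t[:, :n_t]], axis=1)
        logvar = nn.concat([stats_g[:, self.n_global :], stats_t[:, n_t:]], axis=1)
        # bounded posterior scale, initialized small (logvar ~ -4) so the
        # model starts autoencoder-like and opens variance only where the
        # KL trade-off warrants it
        logvar = logvar.tanh() * 7.0 - 4.0
        return mu, logvar


class EcgDecoderNet(nn.Module):
    """Mirror-symmetric decoder: latent -> companded ECG segment."""

    def __init__(self, cfg: EcgVaeConfig, rng: np.random.Generator):
        c = cfg.conv_channels
        self.base_len = cfg.n_samples // 5
        self.c = c
        self.inp = nn.Linear(cfg.latent_dim, c * self.base_len, rng)
        self.res = [nn.ResBlock1d(c, 9, rng) for _ in range(cfg.depth - cfg.depth // 2)]
        self.up = nn.Conv1d(c, c, 11, rng)
        self.out = nn.Conv1d(c, 1, 7, rng)
        self.out.w.data *= 0.1

    def forward(self, z: nn.Tensor) -> nn.Tensor:
        B = z.shape[0]
        h = self.inp(z).relu().reshape(B, self.c, self.base_len)
        for blk in self.res:
            h = blk(h)
        h = self.up(nn.upsample1d(h, 5)).relu()
        return self.out(h)


class EcgVaeNet(nn.Module):
    def __init__(self, cfg: EcgVaeConfig, rng: np.random.Generator):
        self.encoder = EcgEncoderNet(cfg, rng)
        self.decoder = EcgDecoderNet(cfg, rng)
        self.head = nn.Linear(cfg.latent_dim, len(RHYTHM_CLASSES), rng)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def ecg_loss(
    x: nn.Tensor,
    labels: np.ndarray | None,
    net: EcgVaeNet,
    config: EcgVaeConfig,
    rng: np.random.Generator | None = None,
    beta_scale: float = 1.0,
) -> tuple[nn.Tensor, dict]:
    """beta-VAE objective on a batch of companded segments.

    Returns the total loss tensor and the itemized components
    (reconstruction NLL, KL, supervised CE), each averaged per segment.
    Gaussian unit-variance likelihood on companded amplitudes: the
    reconstruction NLL is 0.5 * sum of squared errors.
    """
    B = x.shape[0]
    mu, logvar = net.encoder(x)
    if rng is not None:
        # reparameterized sample; the noise is annealed together with the
        # KL weight so early optimization is not swamped by latent noise
        eps = nn.Tensor((beta_scale * rng.standard_normal(mu.shape)).astype(np.float32))
        z = mu + (logvar * 0.5).exp() * eps
    else:
        z = mu
    xhat = net.decoder(z)
    # Sobolev-type Gaussian likelihood: value error plus weighted
    # first-difference error, with variance calibrated to the companded
    # sensor-noise floor. The derivative term makes the sharp QRS
    # deflections - which carry beat timing - count in proportion to
    # their physiological importance rather than their short support.
    err = xhat - x
    derr = err[:, :, 1:] - err[:, :, :-1]
    recon = ((err**2).sum() + config.deriv_weight * (derr**2).sum()) * (
        0.5 / (B * config.obs_sigma2)
    )
    kl_dim = ((mu**2 + logvar.exp() - 1.0 - logvar) * 0.5).mean(axis=0)  # per dim
    kl = kl_dim.sum()
    # free-bits: dimensions below the floor incur a constant penalty and
    # no gradient, removing the incentive to collapse them individually
    fb = config.free_bits
    kl_penalty = ((kl_dim - fb).relu() + fb).sum() if fb > 0 else kl
    components = {}
    total = recon + (config.beta * beta_scale) * kl_penalty
    if labels is not None and config.lambda_sup > 0:
        onehot = np.zeros((B, len(RHYTHM_CLASSES)), dtype=np.float32)
        onehot[np.arange(B), labels] = 1.0
        # the head reads the posterior mean: a sampled latent only adds
        # variance to the class-direction gradient
        sup = nn.sigmoid_bce(net.head(mu), onehot)
        total = total + config.lambda_sup * sup
        components["supervised"] = sup.item()
    else:
        components["supervised"] = 0.0
    components["reconstruction"] = recon.item()
    components["kl"] = kl.item()
    components["total"] = total.item()
    for name, v in components.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component: {name}")
    return total, components


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class EcgVae:
    """Semantic-space model over a set of companded ECG segments.

    Construct from raw segment arrays (``n x L`` millivolt waveforms) or
    via :meth:`from_records`; :meth:`fit` trains the beta-VAE and returns
    a frozen :class:`EcgVaeResults`.
    """

    def __init__(
        self,
        segments_mv: np.ndarray,
        labels: np.ndarray | None = None,
        config: EcgVaeConfig | None = None,
    ):
        self.config = config or EcgVaeConfig()
        seg = np.asarray(segments_mv, dtype=float)
        if seg.ndim != 2 or seg.shape[1] < self.config.n_samples:
            raise ValueError(
                f"segments must be (n, >= {self.config.n_samples}); got {seg.shape}"
            )
        self.segments = seg
        self.labels = None if labels is None else np.asarray(labels, dtype=int)
        self.x = self._compand(seg)
        # rows longer than one model segment are treated as recordings:
        # each optimizer step crops a random window, so the network sees
        # fresh beat configurations instead of a fixed segment set
        self.crop_range = seg.shape[1] - self.config.n_samples

    @classmethod
    def from_records(
        cls,
        records: list[ECGRecord],
        config: EcgVaeConfig | None = None,
        stride_s: float = 5.0,
    ) -> "EcgVae":
        config = config or EcgVaeConfig()
        segs, labels = [], []
        for rec in records:
            w = _resample_lead(rec, config.fs_hz)
            n = config.n_samples
            step = int(round(stride_s * config.fs_hz))
            for start in range(0, w.size - n + 1, step):
                segs.append(w[start : start + n])
                labels.append(RHYTHM_CLASSES.index(rec.labels) if rec.labels else 0)
        return cls(np.array(segs), np.array(labels), config)

    def _compand(self, seg_mv: np.ndarray) -> np.ndarray:
        x = np.clip(seg_mv / self.config.amp_scale_mv, -1, 1)
        return mulaw_encode(x, self.config.mu_law_mu)[:, None, :].astype(np.float32)

    def fit(self, epochs: int | None = None, verbose: bool = False) -> "EcgVaeResults":
        cfg = self.config
        epochs = epochs or cfg.epochs
        rng = np.random.default_rng(cfg.seed)
        net = EcgVaeNet(cfg, rng)
        opt = nn.Adam(net.parameters(), lr=cfg.lr)
        n = self.x.shape[0]
        log: list[dict] = []
        checkpoint = [a.copy() for a in net.state_arrays()]
        warmup = max(1, int(round(0.3 * epochs)))   # linear KL annealing
        for epoch in range(epochs):
            beta_scale = min(1.0, (epoch + 1) / warmup)
            opt.lr = cfg.lr * (0.3 if epoch >= int(0.75 * epochs) else 1.0)
            order = rng.permutation(n)
            comps_sum: dict[str, float] = {}
            n_batches = 0
            try:
                for start in range(0, n, cfg.batch_size):
                    idx = order[start : start + cfg.batch_size]
                    if idx.size < 2:
                        continue
                    if self.crop_range > 0:
                        offs = rng.integers(0, self.crop_range + 1, idx.size)
                        xb = nn.Tensor(
                            np.stack(
                                [
                                    self.x[i, :, o : o + cfg.n_samples]
                                    for i, o in zip(idx, offs)
                                ]
                            )
                        )
                    else:
                        xb = nn.Tensor(self.x[idx])
                    yb = self.labels[idx] if self.labels is not None else None
                    total, comps = ecg_loss(xb, yb, net, cfg, rng, beta_scale=beta_scale)
                    opt.zero_grad()
                    total.backward()
                    opt.step()
                    for k, v in comps.items():
                        comps_sum[k] = comps_sum.get(k, 0.0) + v
                    n_batches += 1
            except FloatingPointError as err:
                warnings.warn(
                    f"training diverged at epoch {epoch} ({err}); "
                    "restoring last good checkpoint",
                    stacklevel=2,
                )
                net.load_state_arrays(checkpoint)
                break
            entry = {k: v / max(n_batches, 1) for k, v in comps_sum.items()}
            entry["epoch"] = epoch
            log.append(entry)
            checkpoint = [a.copy() for a in net.state_arrays()]
            if verbose:
                print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4f}" for k, v in entry.items()))
        net.freeze()
        return EcgVaeResults(net=net, config=cfg, training_log=log)


@dataclass
class EcgVaeResults:
    """Frozen ECG semantic space: encoder, decoder, head and training log."""

    net: EcgVaeNet
    config: EcgVaeConfig
    training_log: list[dict] = field(default_factory=list)

    # -- encoding / decoding --------------------------------------------------
    def encode_companded(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mean, logvar) for companded input (B, 1, L)."""
        mu, logvar = self.net.encoder(nn.Tensor(np.asarray(x, dtype=np.float32)))
        return mu.data.copy(), logvar.data.copy()

    def encode(self, segment_mv: np.ndarray, source_id: str = "") -> SemanticFactors:
        """Encode one millivolt ECG segment into semantic factors."""
        seg = np.asarray(segment_mv, dtype=float).ravel()
        if seg.size != self.config.n_samples:
            raise ValueError(
                f"segment length {seg.size} != configured {self.config.n_samples}"
            )
        x = np.clip(seg / self.config.amp_scale_mv, -1, 1)
        x = mulaw_encode(x, self.config.mu_law_mu)[None, None, :].astype(np.float32)
        mu, logvar = self.encode_companded(x)
        return SemanticFactors(mu[0], logvar[0], Modality.ECG, source_id)

    def encode_batch(self, segments_mv: np.ndarray) -> np.ndarray:
        """Posterior means (n, latent_dim) for a stack of mV segments."""
        x = np.clip(np.asarray(segments_mv, dtype=float) / self.config.amp_scale_mv, -1, 1)
        x = mulaw_encode(x, self.config.mu_law_mu)[:, None, :].astype(np.float32)
        out = []
        for start in range(0, x.shape[0], 256):
            mu, _ = self.encode_companded(x[start : start + 256])
            out.append(mu)
        return np.concatenate(out, axis=0)

    def decode(self, z: np.ndarray | SemanticFactors) -> np.ndarray:
        """Decode factors to a millivolt ECG segment (inverse mu-law applied)."""
        if isinstance(z, SemanticFactors):
            z = z.mean
        z = np.asarray(z, dtype=np.float32)
        single = z.ndim == 1
        if single:
            z = z[None, :]
        if z.shape[1] != self.config.latent_dim:
            raise ValueError("latent dimension mismatch")
        y = self.net.decoder(nn.Tensor(z)).data[:, 0, :]
        out = mulaw_decode(np.clip(y, -1, 1), self.config.mu_law_mu) * self.config.amp_scale_mv
        return out[0] if single else out

    def classify_logits(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float32))
        return self.net.head(nn.Tensor(z)).data.copy()

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        lines = ["ECG semantic space (beta-VAE)", "=" * 34]
        cfg = self.config
        lines.append(f"latent_dim={cfg.latent_dim}  beta={cfg.beta}  lambda_sup={cfg.lambda_sup}")
        lines.append(f"fs={cfg.fs_hz} Hz  segment={cfg.segment_s} s  depth={cfg.depth}")
        if self.training_log:
            first, last = self.training_log[0], self.training_log[-1]
            lines.append(
                f"epochs={len(self.training_log)}  loss {first['total']:.3f} -> {last['total']:.3f}"
            )
            lines.append(
                f"final components: recon={last['reconstruction']:.3f} "
                f"kl={last['kl']:.3f} sup={last['supervised']:.3f}"
            )
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            __log__=json.dumps(self.training_log),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "EcgVaeResults":
        data = np.load(path, allow_pickle=False)
        cfg = EcgVaeConfig(**json.loads(str(data["__config__"])))
        net = EcgVaeNet(cfg, np.random.default_rng(cfg.seed))
        arrays = [data[f"p{i}"] for i in range(len(net.parameters()))]
        net.load_state_arrays(arrays)
        net.freeze()
        return cls(net=net, config=cfg, training_log=json.loads(str(data["__log__"])))


def _resample_lead(rec: ECGRecord, fs_target: float) -> np.ndarray:
    """Lead-I waveform resampled to the model rate by polyphase filtering."""
    from scipy import signal as sp_signal
    from fractions import Fraction

    w = rec.waveform[0]
    if abs(rec.fs_hz - fs_target) < 1e-9:
        return w
    frac = Fraction(fs_target / rec.fs_hz).limit_denominator(1000)
    return sp_signal.resample_poly(w, frac.numerator, frac.denominator)
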