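"""Coupled synthetic cardiac world: one latent cardiac state drives both
a rendered ECG and a simulated FMCW radar measurement.

The generator emulates the statistical structure that radio cardiac
monitoring assumes: electrical activity (ECG PQRST morphology, PR/QT
intervals, rhythm class) and mechanical activity (millimetre-scale torso
surface displacement) are both functions of the same beat sequence, with
a fixed electromechanical delay between the R peak and the mechanical
pulse. Rhythm phenotypes follow clinical definitions: atrial fibrillation
(AF) has irregular inter-beat intervals and no consistent P wave;
premature beats (PB) are early beats followed by a compensatory pause.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np

C_LIGHT = 299_792_458.0  # m/s


class Rhythm(str, enum.Enum):
    NORMAL = "NORMAL"
    AF = "AF"
    PB = "PB"


@dataclass
class StateParams:
    """Distribution hyperparameters for cohort sampling.

    HR/PR/QT means and SDs are across-subject; ``ibi_cv`` is the
    within-subject beat-to-beat variability of a sinus rhythm; ``af_cv``
    is the target coefficient of variation of AF inter-beat intervals;
    ``pb_every`` inserts one premature beat per that many sinus beats,
    at ``pb_coupling`` times the local cycle length.
    """

    hr_mean: float = 70.0
    hr_sd: float = 12.0
    ibi_cv: float = 0.03
    pr_mean_ms: float = 160.0
    pr_sd_ms: float = 25.0
    qt_mean_ms: float = 400.0
    qt_sd_ms: float = 40.0
    af_cv: float = 0.24
    pb_every: int = 10
    pb_coupling: float = 0.6
    resp_hz_range: tuple[float, float] = (0.2, 0.35)


@dataclass
class CardiacState:
    """Shared latent ground truth driving both modalities."""

    subject_id: str
    duration_s: float
    beat_times: np.ndarray          # R-peak times, s, strictly increasing
    hr_bpm: np.ndarray              # per-beat instantaneous ventricular rate
    pr_ms: np.ndarray               # per-beat PR interval (P onset -> R peak)
    qt_ms: np.ndarray               # per-beat QT interval (Q onset -> T end)
    rhythm: Rhythm
    pb_beat_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    respiration_hz: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.size < 2:
            raise ValueError("cardiac state needs at least two beats")
        if not np.all(np.diff(bt) > 0):
            raise ValueError("invariant violated: beat_times strictly increasing")
        if np.any(self.hr_bpm < 30) or np.any(self.hr_bpm > 220):
            raise ValueError("invariant violated: 30 <= hr_bpm <= 220 per beat")
        cycle_ms = 60000.0 / self.hr_bpm
        if np.any(self.pr_ms + self.qt_ms >= cycle_ms):
            raise ValueError("invariant violated: pr_ms + qt_ms < cycle length")
        ibi = np.diff(bt)
        if self.rhythm == Rhythm.AF:
            cv = ibi.std() / ibi.mean()
            if cv < 0.1:
                raise ValueError("invariant violated: AF requires IBI CV >= 0.1")
        if self.rhythm == Rhythm.PB:
            for idx in np.asarray(self.pb_beat_indices, dtype=int):
                if idx + 1 >= bt.size:
                    continue
                pause = bt[idx + 1] - bt[idx]
                lo, hi = max(0, idx - 4), min(ibi.size, idx + 5)
                local_mean = ibi[lo:hi].mean()
                if pause < 1.1 * local_mean:
                    raise ValueError(
                        "invariant violated: premature beat must be followed by "
                        "a compensatory pause >= 1.1x local mean interval"
                    )

    @property
    def mean_hr_bpm(self) -> float:
        return float(60.0 / np.diff(self.beat_times).mean())


@dataclass
class ECGRecord:
    waveform: np.ndarray            # (leads, samples), millivolts
    fs_hz: float
    lead_names: list[str]
    labels: Rhythm | None = None
    state_ref: CardiacState | None = None

    @property
    def duration_s(self) -> float:
        return self.waveform.shape[1] / self.fs_hz


@dataclass
class RadarConfig:
    """FMCW radar geometry and sampling.

    The carrier sits in the millimetre-wave band (default 60 GHz,
    wavelength 5 mm) with a wide sweep bandwidth so that fast-time
    samples span distinct wavelengths and carry range information.
    """

    carrier_hz: float = 60e9
    bandwidth_hz: float = 4e9
    n_pairs: int = 4
    pair_positions: np.ndarray | None = None   # (M, 3) m; default set in __post_init__
    n_fast: int = 16
    chirp_rate_hz: float = 100.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.pair_positions is None:
            # deliberately irregular planar layout: avoids mirror-symmetric
            # voxel pairs having identical path sets (beamforming ties)
            self.pair_positions = np.array(
                [
                    [0.000, 0.000, 0.000],
                    [0.018, 0.000, 0.004],
                    [0.004, 0.000, 0.022],
                    [0.021, 0.000, 0.019],
                ]
            )[: self.n_pairs]
        self.pair_positions = np.asarray(self.pair_positions, dtype=float)
        if self.pair_positions.shape != (self.n_pairs, 3):
            raise ValueError("pair_positions must have shape (n_pairs, 3)")
        if self.n_pairs < 1 or self.n_fast < 1:
            raise ValueError("need at least one antenna pair and one fast-time sample")

    @property
    def wavelength_m(self) -> float:
        return C_LIGHT / self.carrier_hz

    @property
    def wavelengths_m(self) -> np.ndarray:
        """Per-fast-time-sample wavelengths spanning [carrier, carrier+BW]."""
        if self.n_fast == 1:
            freqs = np.array([self.carrier_hz])
        else:
            freqs = self.carrier_hz + self.bandwidth_hz * np.arange(self.n_fast) / (
                self.n_fast - 1
            )
        return C_LIGHT / freqs


@dataclass
class RadarCube:
    """Raw received signal y_{m,n}(t): antenna pair x fast time x slow time."""

    samples: np.ndarray             # complex (M, N, T)
    config_ref: RadarConfig
    t_slow_s: np.ndarray

    def __post_init__(self):
        M, N, T = self.samples.shape
        if M != self.config_ref.n_pairs or N != self.config_ref.n_fast:
            raise ValueError("cube shape inconsistent with radar config")
        if T != self.t_slow_s.size:
            raise ValueError("slow-time axis inconsistent with timestamps")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("non-finite samples in radar cube")


@dataclass
class Grid:
    """Voxel grid: flat (V, 3) coordinates plus the (X, Y, Z) shape."""

    coords: np.ndarray
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]


def make_grid(
    shape: tuple[int, int, int] = (8, 8, 4),
    x_extent: tuple[float, float] = (-0.14, 0.14),
    z_extent: tuple[float, float] = (-0.14, 0.14),
    y_extent: tuple[float, float] = (0.34, 0.46),
) -> Grid:
    """Right-handed Cartesian voxel grid, radar at the origin, y = range axis."""
    nx, ny, nz = shape
    xs = np.linspace(*x_extent, nx)
    ys = np.linspace(*y_extent, ny)
    zs = np.linspace(*z_extent, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    return Grid(coords=coords, shape=(nx, ny, nz))


@dataclass
class DisplacementField:
    """Per-voxel line-of-sight displacement time series d(p, t), metres (one-way)."""

    values: np.ndarray              # (V, T)
    grid: Grid
    fs_hz: float
    torso_mask: np.ndarray          # (V,) bool
    state_ref: CardiacState | None = None


# ---------------------------------------------------------------------------
# sampling the latent cardiac state
# ---------------------------------------------------------------------------

def sample_cardiac_state(
    rhythm: Rhythm | str,
    duration_s: float,
    params: StateParams | None = None,
    seed: int = 0,
    subject_id: str | None = None,
) -> CardiacState:
    """Draw one subject's latent cardiac state.

    Deterministic in (rhythm, duration_s, params, seed). QT adapts to the
    instantaneous cycle length (Bazett square-root scaling) so that the
    electrical intervals always fit inside the cardiac cycle.
    """
    rhythm = Rhythm(rhythm)
    params = params or StateParams()
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10")
    _check_params_feasible(params)
    rng = np.random.default_rng(seed)

    hr0 = float(np.clip(rng.normal(params.hr_mean, params.hr_sd), 40.0, 150.0))
    base_ibi = 60.0 / hr0

    ibis, pb_idx = _draw_ibis(rhythm, duration_s, base_ibi, params, rng)
    t0 = 0.3
    beat_times = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
    beat_times = beat_times[beat_times <= duration_s - 0.3]
    n = beat_times.size
    if n < 2:
        raise ValueError("duration too short for the sampled heart rate")
    ibis = np.diff(beat_times)
    pb_idx = pb_idx[pb_idx < n - 1]

    # per-beat instantaneous rate from the preceding interval
    hr_bpm = 60.0 / np.concatenate([[ibis[0]], ibis])
    hr_bpm = np.clip(hr_bpm, 30.0, 220.0)

    pr0 = float(np.clip(rng.normal(params.pr_mean_ms, params.pr_sd_ms), 100.0, 260.0))
    qt0 = float(np.clip(rng.normal(params.qt_mean_ms, params.qt_sd_ms), 300.0, 500.0))
    pr = np.clip(pr0 + rng.normal(0, 2.0, n), 80.0, 280.0)
    cycle_s = np.concatenate([[ibis[0]], ibis])
    qt = qt0 * np.sqrt(cycle_s)                       # Bazett adaptation
    qt = qt + rng.normal(0, 2.0, n)
    # hard feasibility: intervals fit inside the cycle with margin
    cycle_ms = 60000.0 / hr_bpm
    qt = np.minimum(qt, 0.88 * cycle_ms - pr)
    qt = np.maximum(qt, 200.0)
    pr = np.minimum(pr, 0.9 * cycle_ms - qt)

    state = CardiacState(
        subject_id=subject_id or f"sub{seed:05d}",
        duration_s=float(duration_s),
        beat_times=beat_times,
        hr_bpm=hr_bpm,
        pr_ms=pr,
        qt_ms=qt,
        rhythm=rhythm,
        pb_beat_indices=pb_idx,
        respiration_hz=float(rng.uniform(*params.resp_hz_range)),
        seed=seed,
    )
    state.validate()
    return state


def _check_params_feasible(params: StateParams) -> None:
    cycle_ms = 60000.0 / params.hr_mean
    if params.pr_mean_ms + params.qt_mean_ms >= cycle_ms:
        raise ValueError(
            "infeasible params: pr_mean_ms + qt_mean_ms >= mean cycle length "
            f"({params.pr_mean_ms + params.qt_mean_ms:.0f} >= {cycle_ms:.0f} ms); "
            "violates the pr + qt < cycle invariant"
        )
    if not 0 < params.pb_coupling < 1:
        raise ValueError("infeasible params: pb_coupling must lie in (0, 1)")
    if params.hr_mean < 30 or params.hr_mean > 220:
        raise ValueError("infeasible params: hr_mean outside [30, 220]")


def _draw_ibis(
    rhythm: Rhythm,
    duration_s: float,
    base_ibi: float,
    params: StateParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n_max = int(np.ceil(duration_s / base_ibi)) + 8
    pb_idx = np.array([], dtype=int)

    if rhythm == Rhythm.NORMAL:
        ibis = base_ibi * (1.0 + params.ibi_cv * rng.standard_normal(n_max))
        ibis = np.clip(ibis, 0.35, 2.0)
    elif rhythm == Rhythm.AF:
        # multiplicative gamma irregularity, then enforce the CV floor exactly
        cv = max(params.af_cv, 0.12)
        shape_k = 1.0 / cv**2
        ibis = base_ibi * rng.gamma(shape_k, 1.0 / shape_k, n_max)
        ibis = np.clip(ibis, 60.0 / 220.0, 2.0)
        got = ibis.std() / ibis.mean()
        if got < 0.1:
            ibis = ibis.mean() + (ibis - ibis.mean()) * (0.12 / max(got, 1e-6))
            ibis = np.clip(ibis, 60.0 / 220.0, 2.0)
    else:  # PB: sinus base with early beats on a fixed schedule
        ibis_list: list[float] = []
        pb_list: list[int] = []
        i = 0
        while len(ibis_list) < n_max:
            run = max(params.pb_every - 1, 2)
            for _ in range(run):
                ibis_list.append(
                    float(np.clip(base_ibi * (1 + params.ibi_cv * rng.standard_normal()),
                                  0.35, 2.0))
                )
            # premature beat: short coupling interval, then full compensatory
            # pause so the premature + pause spans two sinus cycles
            coupling = params.pb_coupling * base_ibi
            ibis_list.append(coupling)
            pb_list.append(len(ibis_list))      # index of the premature beat
            ibis_list.append(2.0 * base_ibi - coupling)
            i += 1
        ibis = np.array(ibis_list[:n_max])
        pb_idx = np.array([j for j in pb_list if j < n_max], dtype=int)
    return ibis, pb_idx


# ---------------------------------------------------------------------------
# ECG rendering
# ---------------------------------------------------------------------------

# per-wave Gaussian bump parameters: (amplitude mV, sigma ms)
_WAVES = {
    "P": (0.15, 25.0),
    "Q": (-0.10, 9.0),
    "R": (1.00, 14.0),
    "S": (-0.18, 9.0),
    "T": (0.35, 55.0),
}


def _gauss(t: np.ndarray, center: float, sigma_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma_s) ** 2)


def render_ecg(state: CardiacState, fs_hz: float = 250.0, n_leads: int = 1) -> ECGRecord:
    """Render the PQRST waveform of a cardiac state as a sum of Gaussians.

    Landmarks are placed analytically: the P-wave onset (centre minus two
    sigma) precedes the R peak by exactly ``pr_ms``; the T-wave end
    (centre plus two sigma) trails the Q onset by exactly ``qt_ms``.
    AF suppresses the P wave entirely and adds a fibrillatory baseline
    ripple. Deterministic given the seed embedded in the state.
    """
    if n_leads < 1:
        raise ValueError("n_leads must be >= 1")
    if fs_hz < 100:
        raise ValueError("fs_hz must be >= 100")
    state.validate()
    n_samp = int(round(state.duration_s * fs_hz))
    t = np.arange(n_samp) / fs_hz
    wave = np.zeros(n_samp)
    rng = np.random.default_rng(state.seed + 1_000_003)

    amp_p, sig_p = _WAVES["P"]
    amp_q, sig_q = _WAVES["Q"]
    amp_r, sig_r = _WAVES["R"]
    amp_s, sig_s = _WAVES["S"]
    amp_t, sig_t = _WAVES["T"]
    sig_p_s, sig_q_s, sig_r_s = sig_p / 1e3, sig_q / 1e3, sig_r / 1e3
    sig_s_s, sig_t_s = sig_s / 1e3, sig_t / 1e3

    for i, tr in enumerate(state.beat_times):
        pr_s = state.pr_ms[i] / 1e3
        qt_s = state.qt_ms[i] / 1e3
        q_center = tr - 0.028
        q_onset = q_center - 2 * sig_q_s
        t_center = q_onset + qt_s - 2 * sig_t_s
        lo = max(0, int((tr - 0.45) * fs_hz))
        hi = min(n_samp, int((tr + qt_s + 0.2) * fs_hz))
        tt = t[lo:hi]
        seg = (
            amp_q * _gauss(tt, q_center, sig_q_s)
            + amp_r * _gauss(tt, tr, sig_r_s)
            + amp_s * _gauss(tt, tr + 0.030, sig_s_s)
            + amp_t * _gauss(tt, t_center, sig_t_s)
        )
        if state.rhythm != Rhythm.AF:
            p_center = tr - pr_s + 2 * sig_p_s
            seg = seg + amp_p * _gauss(tt, p_center, sig_p_s)
        wave[lo:hi] += seg

    if state.rhythm == Rhythm.AF:
        # coarse fibrillatory (f-wave) ripple around 6 Hz with phase drift
        phase = 2 * np.pi * 6.0 * t + np.cumsum(rng.normal(0, 0.15, n_samp))
        wave = wave + 0.04 * np.sin(phase)
    # respiration baseline wander + mild sensor noise
    wave = wave + 0.02 * np.sin(2 * np.pi * state.respiration_hz * t)
    wave = wave + rng.normal(0, 0.004, n_samp)

    gains = 1.0 - 0.25 * np.arange(n_leads) / max(n_leads, 1)
    waveform = np.outer(gains, wave)
    return ECGRecord(
        waveform=waveform,
        fs_hz=float(fs_hz),
        lead_names=[f"L{i+1}" for i in range(n_leads)],
        labels=state.rhythm,
        state_ref=state,
    )


# ---------------------------------------------------------------------------
# torso displacement and radar simulation
# ---------------------------------------------------------------------------

def torso_mask_for_grid(grid: Grid) -> np.ndarray:
    """Front-surface elliptical patch of the grid acting as the torso."""
    coords = grid.coords
    y_front = coords[:, 1].min()
    on_front = np.isclose(coords[:, 1], y_front)
    ellipse = (coords[:, 0] / 0.13) ** 2 + (coords[:, 2] / 0.15) ** 2 <= 1.0
    return on_front & ellipse


def render_torso_displacement(
    state: CardiacState,
    grid: Grid,
    respiration_amp_m: float = 2e-3,
    cardiac_amp_m: float = 4e-4,
    fs_hz: float = 100.0,
    emd_s: float = 0.05,
    qt_ref_ms: float = 400.0,
) -> DisplacementField:
    """Per-voxel line-of-sight displacement driven by the cardiac state.

    Each beat contributes a two-component mechanical pulse: a small atrial
    kick preceding the ventricular pulse by the PR interval, and a main
    ventricular pulse lagging the R peak by the electromechanical delay
    ``emd_s``. The ventricular pulse keeps fixed energy while its width
    scales with QT, so a longer QT spreads the pulse and lowers its peak.
    Respiration adds a slow sinusoid over a broader torso area. Voxels off
    the torso mask return constant (static) displacement.
    """
    if cardiac_amp_m < 0 or respiration_amp_m < 0:
        raise ValueError("amplitudes must be nonnegative")
    n_t = int(round(state.duration_s * fs_hz))
    t = np.arange(n_t) / fs_hz
    mask = torso_mask_for_grid(grid)
    coords = grid.coords

    # spatial weights: cardiac motion concentrated near the heart (left of
    # sternum), respiration spread across the torso patch
    heart = np.array([-0.04, coords[:, 1].min(), 0.02])
    d2 = ((coords[:, 0] - heart[0]) ** 2 + (coords[:, 2] - heart[2]) ** 2)
    w_card = np.exp(-d2 / (2 * 0.06**2)) * mask
    w_resp = np.exp(-d2 / (2 * 0.12**2)) * mask

    pulse = np.zeros(n_t)
    sig_a = 0.030
    for i, tr in enumerate(state.beat_times):
        qt_scale = state.qt_ms[i] / qt_ref_ms
        sig_v = 0.050 * qt_scale
        amp_v = 1.0 / qt_scale            # fixed pulse energy ~ amp * width
        t_v = tr + emd_s
        t_a = tr - state.pr_ms[i] / 1e3 + emd_s
        lo = max(0, int((t_a - 0.25) * fs_hz))
        hi = min(n_t, int((t_v + 0.4) * fs_hz))
        tt = t[lo:hi]
        pulse[lo:hi] += 0.3 * _gauss(tt, t_a, sig_a) + amp_v * _gauss(tt, t_v, sig_v)

    resp = np.sin(2 * np.pi * state.respiration_hz * t)
    values = (
        cardiac_amp_m * w_card[:, None] * pulse[None, :]
        + respiration_amp_m * w_resp[:, None] * resp[None, :]
    )
    return DisplacementField(
        values=values.astype(np.float64),
        grid=grid,
        fs_hz=float(fs_hz),
        torso_mask=mask,
        state_ref=state,
    )


def simulate_radar(
    displacement: DisplacementField,
    config: RadarConfig,
    clutter: list[tuple[np.ndarray, float]] | None = None,
    seed: int = 0,
    reflector_amp: float = 1.0,
) -> RadarCube:
    """Simulate the raw received signal of an FMCW radar.

    Every torso voxel acts as a point reflector whose one-way path to pair
    m changes by its displacement; the reflected signal picks up the phase
    2*pi*d_m/lambda_n where d_m is the round-trip path (static round trip
    plus twice the one-way displacement). Static clutter reflectors and
    complex Gaussian receiver noise are added on top.
    """
    if abs(displacement.fs_hz - config.chirp_rate_hz) > 1e-9:
        raise ValueError(
            "displacement field must be sampled at the radar chirp rate "
            f"({displacement.fs_hz} Hz vs {config.chirp_rate_hz} Hz)"
        )
    rng = np.random.default_rng(seed)
    lams = config.wavelengths_m                       # (N,)
    qs = config.pair_positions                        # (M, 3)
    M, N = config.n_pairs, config.n_fast
    n_t = displacement.values.shape[1]
    cube = np.zeros((M, N, n_t), dtype=np.complex64)

    refl_idx = np.flatnonzero(displacement.torso_mask)
    two_pi_over_lam = 2 * np.pi / lams                # (N,)
    for v in refl_idx:
        p = displacement.grid.coords[v]
        static_rt = 2 * np.linalg.norm(p[None, :] - qs, axis=1)      # (M,)
        d_rt = static_rt[:, None] + 2 * displacement.values[v][None, :]  # (M, T)
        phase = d_rt[:, None, :] * two_pi_over_lam[None, :, None]    # (M, N, T)
        cube += reflector_amp * np.exp(1j * phase).astype(np.complex64)

    for pos, amp in clutter or []:
        p = np.asarray(pos, dtype=float)
        static_rt = 2 * np.linalg.norm(p[None, :] - qs, axis=1)
        phase = static_rt[:, None] * two_pi_over_lam[None, :]
        cube += amp * np.exp(1j * phase)[:, :, None].astype(np.complex64)

    if config.noise_sigma > 0:
        noise = rng.normal(0, config.noise_sigma / np.sqrt(2), (2, M, N, n_t))
        cube = cube + (noise[0] + 1j * noise[1]).astype(np.complex64)

    t_slow = np.arange(n_t) / config.chirp_rate_hz
    return RadarCube(samples=cube, config_ref=config, t_slow_s=t_slow)


def sample_clutter(
    n: int,
    seed: int,
    box: tuple[tuple[float, float], ...] = ((-0.5, 0.5), (0.2, 0.9), (-0.5, 0.5)),
    amp_range: tuple[float, float] = (0.3, 3.0),
) -> list[tuple[np.ndarray, float]]:
    """K static point reflectors with log-uniform amplitudes."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pos = np.array([rng.uniform(*box[i]) for i in range(3)])
        amp = float(np.exp(rng.uniform(np.log(amp_range[0]), np.log(amp_range[1]))))
        out.append((pos, amp))
    return out
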