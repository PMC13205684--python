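# radiosem

Semantic representation learning for contactless cardiac monitoring
with millimetre-wave FMCW radar — exercised end to end on a built-in
synthetic world of coupled radio and ECG recordings.

## The problem

Radio reflections from the torso surface carry cardiac mechanical
motion: a reflection whose round-trip path length is d(t) is phase
modulated by φ(t) = 2π d(t)/λ, so millimetre-scale heartbeats are
visible at a 5 mm wavelength. The raw measurement, however, is a
high-dimensional, uninterpretable spatiotemporal tensor. `radiosem`
turns it into **64 semantic factors** that support clinically phrased
readouts — ventricular rate, PR interval, QT interval — plus rhythm
monitoring (inter-beat intervals, RMSSD/SDNN/pNN50) and linear
arrhythmia classification (atrial fibrillation, premature beats),
all from radio input alone.

The model has three stages:

1. **ECG semantic space.** A β-VAE with a linear supervised head is
   pretrained on 10-s ECG segments:
   `L = E_q[−log p(X_E|Z_E)] + β·KL(q(Z_E|X_E) ‖ N(0,I)) + λ·CE(Y_E)`,
   then frozen. Its 64-factor posterior mean is the semantic reference.
2. **Radio semantic learning.** A deterministic radio encoder/decoder
   is trained on synchronized radio–ECG pairs with
   `L = ‖X_R − D_R(E_R(X_R))‖² + α‖E_R(T(X_R)) − E_R(X_R)‖²
      + γ(1 − cos(E_R(X_R), E_E(X_E))) + δ‖X_E − D_E(E_R(X_R))‖²`
   (α = 0.1, γ = 1, δ = 10⁻⁴), where T(·) injects another recording's
   non-cardiac signal content as a semantic-invariant perturbation.
3. **Test-time projection.** Radio input only: Z_R = E_R(X_R) is
   decoded through both frozen decoders into an ECG-domain and a
   radio-domain view; all downstream analyses are linear in Z_R.

Because paired clinical radar/ECG data are restricted, the package
ships a first-class synthetic world: one latent cardiac state (beat
times, per-beat HR/PR/QT, rhythm class NORMAL/AF/PB, respiration)
drives both a rendered PQRST ECG and a simulated FMCW radar
measurement (voxel point reflectors, clutter, receiver noise), with a
delay-and-sum beamforming front end recovering the 4-D cardiac motion
tensor. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from radiosem import (
    RadarConfig, make_grid, sample_cardiac_state, render_ecg,
    render_torso_displacement, simulate_radar, sample_clutter,
    build_motion_tensor, detect_r_peaks, compute_ibi, hrv_metrics,
)

state = sample_cardiac_state("AF", duration_s=30, seed=1)
ecg = render_ecg(state, fs_hz=250)
grid = make_grid()
field = render_torso_displacement(state, grid, fs_hz=100)
cube = simulate_radar(field, RadarConfig(noise_sigma=1.0),
                      clutter=sample_clutter(5, seed=2), seed=3)
motion = build_motion_tensor(cube, grid, top_k=64)

beats = detect_r_peaks(ecg.waveform[0], ecg.fs_hz)
h = hrv_metrics(compute_ibi(beats))
print(f"beats={beats.size}  mean HR={h.mean_hr_bpm:.1f} bpm  "
      f"RMSSD={h.rmssd_ms:.0f} ms  SDNN={h.sdnn_ms:.0f} ms  pNN50={h.pnn50_pct:.0f}%")
print("motion tensor:", motion.values.shape)
```

prints

```
beats=38  mean HR=76.5 bpm  RMSSD=242 ms  SDNN=155 ms  pNN50=89%
motion tensor: (8, 8, 4, 3000)
```

— an atrial-fibrillation subject: 38 detected beats with the large
beat-to-beat variability (RMSSD/pNN50) that defines the rhythm, and
the 4-D cardiac-motion measurement recovered from the raw radar cube.

The full study — simulate a 200-subject mixed-rhythm cohort, pretrain
the ECG space, learn the radio representation, evaluate readouts,
rhythm monitoring and diagnosis on held-out subjects — is one call:

```python
from radiosem.experiment import ExperimentConfig, run_pipeline
result = run_pipeline(ExperimentConfig(seed=1), progress=True)
print(result.metrics)
```

or from the shell: `radiosem run --config experiment.yaml --out results/`.

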