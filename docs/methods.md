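# Methods

`radiosem` implements semantic representation learning for contactless
cardiac monitoring with millimetre-wave FMCW radar, exercised end to end
on a built-in synthetic world in which one latent cardiac state drives
both an ECG and a radar measurement. This note records the models, the
defaults and why they are what they are, and what the synthetic results
do and do not show.

## Measurement model

Cardiac mechanical activity displaces the torso surface by fractions of
a millimetre. A reflection returning from a point whose round-trip path
length is d(t) carries phase φ(t) = 2π d(t)/λ; throughout the package d
denotes the **round-trip** path, so a one-way surface displacement of
Δ metres modulates the phase by 2π·2Δ/λ. At the 60 GHz carrier
(λ = 5 mm) a 0.25 mm one-way swing produces a 0.63 rad phase swing,
comfortably above the receiver noise floor after beamforming.

Reflections are separated spatially by delay-and-sum beamforming over
antenna pairs m and fast-time samples n:

    x(p, t) = Σ_m Σ_n exp(−j 2π d_m(p) / λ_n) · y_{m,n}(t)

where d_m(p) is the round-trip distance through voxel p for pair m and
λ_n is the wavelength of the n-th fast-time sample, spanning the sweep
bandwidth. Per-voxel phase is extracted with unwrapping, mean-centred
(only variations carry cardiac information; the absolute range is not
estimated), and band-pass filtered (default 0.8–25 Hz, 4th-order
Butterworth applied forward–backward) to suppress the ~0.2–0.4 Hz
respiratory component. The result is the 4-D motion tensor
X_R ∈ R^{X×Y×Z×T}.

**Torso localization.** Voxels carrying cardiac motion are selected by
ranking the fraction of above-respiration phase power that falls in the
cardiac band (0.8–3 Hz), weighted by the squared median reflection
magnitude. The magnitude weighting matters: in scenes with several
coherent reflectors, near-cancellation voxels have low magnitude but
chaotic phase whose raw band power would outrank genuine torso
reflections. Ties break to the lower flat voxel index.

## Synthetic cardiac world

The generator emulates the one property the whole framework rests on:
electrical (ECG) and mechanical (radar) observations are two views of
the same beat sequence.

* **Cardiac state.** Per subject: beat times, per-beat heart rate, PR
  and QT intervals, rhythm class ∈ {NORMAL, AF, PB}, respiration rate.
  Across-subject defaults: HR 70 ± 12 bpm, PR 160 ± 25 ms,
  QT 400 ± 40 ms; within-subject sinus variability CV 3%. QT adapts to
  cycle length by Bazett square-root scaling, which also guarantees the
  intervals fit inside every cycle. AF draws gamma-distributed
  inter-beat intervals with CV 0.24 (floored at 0.12) and suppresses
  the P wave; PB inserts one premature beat per 10 sinus beats at 0.6×
  the cycle length followed by a full compensatory pause (premature
  plus pause spans two sinus cycles).
* **ECG.** Sum-of-Gaussians PQRST (five bumps per beat), so landmarks
  are analytic: the P-wave onset precedes the R peak by exactly PR, and
  the T-wave end trails the Q onset by exactly QT. AF adds a ~6 Hz
  fibrillatory ripple; all rhythms get respiratory baseline wander and
  4 µV-scale sensor noise.
* **Torso displacement.** Each beat contributes a small atrial kick
  (preceding the ventricular pulse by PR) and a main ventricular pulse
  lagging the R peak by a fixed electromechanical delay (default
  50 ms). The ventricular pulse has fixed energy: its width scales with
  QT and its peak with 1/QT, so a longer QT spreads and flattens the
  mechanical impulse. Cardiac motion (default 0.4 mm) concentrates near
  the heart; respiration (default 2 mm) spreads over the torso patch.
* **Radar.** Every torso-surface voxel is a point reflector; static
  clutter reflectors with log-uniform amplitudes and complex Gaussian
  receiver noise (default σ = 1) are added. Desk-scale geometry: 4
  antenna pairs in a deliberately irregular planar layout (a symmetric
  array would create exact mirror-voxel ambiguities), 16 fast-time
  samples across 4 GHz, 100 Hz chirp rate, an 8×8×4 voxel grid roughly
  0.4 m in front of the array.

What the generator does **not** emulate: real torso geometry and
multipath, intra-beat morphology pathology (e.g. ST changes), motion
artefacts, multi-person scenes, sensor drift, or 12-lead vector
physiology (leads are scaled copies). Passing the synthetic recovery
experiments therefore demonstrates that the pipeline is implemented
correctly and that the representation machinery can transfer cardiac
semantics across modalities under the stated noise model — not that it
reaches clinical performance on real patients.

## ECG semantic space

Single-lead 10-s segments, resampled to 100 Hz, normalized by a fixed
2 mV scale and µ-law companded (µ = 255) are encoded by a
strided-convolution + residual network into a 64-factor diagonal
Gaussian posterior; a mirror-symmetric decoder reconstructs the
companded segment; a linear head predicts the rhythm class from the
latent. The objective is reconstruction NLL + β·KL + λ·cross-entropy
with β = 1, λ = 30 by default (the head reads the posterior mean;
sampling only adds variance to the class-direction gradient).

Numerical choices that turned out to be load-bearing:

* **Noise-calibrated likelihood.** The reconstruction term is Gaussian
  with variance fixed at the companded sensor-noise floor
  (`obs_sigma2 = 0.02`), not unit variance. With unit variance the
  achievable KL cost of an informative latent exceeds the attainable
  reconstruction benefit and the β = 1 optimum is exact posterior
  collapse. An optional first-difference (Sobolev) error term exists
  (`deriv_weight`, default 0).
* **Dual-path latent.** 12 of the 64 factors ("global" dims) are fed
  from time-pooled statistics of the convolutional feature map: per
  channel, the mean, the second moment, and lagged-product means
  (autocorrelation features at lags 0.3–1.2 s). The lag features are
  what makes rhythm statistics linear-ready: rate, irregularity and
  compensatory pauses live in the lag structure of beat-locked
  activations, which plain moments cannot express. The remaining 52
  factors come from the same map flattened at 50-ms resolution.
  Pooled activations make rates, interval lags and beat-pattern
  anomalies close to linear functions of the latent — which is what
  linear semantic readouts and the linear diagnosis head need — while
  the timing path preserves beat-level timing through the bottleneck.
  A single stride-5 stage (50 ms cells) feeds the timing path
  deliberately: a deeper pyramid there loses beat timing.
* **Alignment of up/down-sampling.** Upsampling is centred (advanced by
  (factor−1)//2 with edge replication) and the strided encoder convs use
  padding k//2 − 2, so encoder and decoder grids are phase-aligned;
  without this the decoder reproduces the rhythm shifted by a constant
  lag it must waste capacity undoing.
* **Optimization.** Adam (lr 2·10⁻³, ×0.3 for the last quarter of
  epochs), batch 32. The KL weight and the reparameterization noise
  are annealed linearly over the first 30% of epochs, and the
  posterior log-variance is initialized near −4, so early training is
  autoencoder-like. A per-dimension free-bits floor (0.25 nats)
  removes the incentive to collapse individual factors. Training
  aborts to the last finite checkpoint if any loss component goes
  non-finite.
* **Random-crop training.** When the trainer is handed rows longer
  than one model segment (full recordings, as the experiment driver
  does), every optimizer step crops a random window, so the network
  sees fresh beat configurations instead of a fixed segment grid —
  with a few hundred recordings this is the difference between a
  timing code that generalizes to held-out subjects and one that
  memorizes the training segments. An "epoch" is then a pass over
  recordings; the experiment defaults (500 ECG / 260 radio epochs at
  ~120 recordings) correspond to roughly 2000/1000 optimizer steps.

After fitting, encoder, decoder and head are frozen.

## Radio semantic learning

The radio encoder compresses the motion tensor with a 1×1 spatial
convolution over voxels followed by the same temporal stack and
dual-path latent as the ECG encoder (deterministic — the radio
objective has no KL term); the decoder mirrors it. The loss is

    L = ||X_R − D_R(E_R(X_R))||² + α ||E_R(T(X_R)) − E_R(X_R)||²
      + γ (1 − cos(E_R(X_R), E_E(X_E))) + δ ||X_E − D_E(E_R(X_R))||²

with α = 0.1, γ = 1, δ = 10⁻⁴. Each squared norm is averaged per
element, and the radio reconstruction is divided by its calibrated
noise variance (`obs_sigma2 = 0.01`); without a common scale the summed
reconstruction term is ~10⁴ times larger than the alignment term and
the printed weights are meaningless.

* **Standardized, group-balanced alignment target.** The cosine is
  taken against the per-dimension z-scored ECG posterior means
  (statistics from the training set, floored at 10⁻²), and is averaged
  over the two factor groups (global block, timing block). Both
  normalizations exist for the same reason: the raw factor variances
  differ by ~20× and the timing block outnumbers the global block
  ~4:1, so an unnormalized whole-vector cosine starves exactly the
  semantic factors of training signal. Z_R therefore lives in the
  standardized semantic space; decoding a radio latent through the ECG
  decoder first maps it back (z·sd + mean).
* **Semantic-invariant transformation T.** A seeded random donor
  recording (different subject) contributes its non-cardiac component —
  the cardiac-band-stopped residual plus its static spatial pattern —
  added at strength ~U(0.5, 1.5). Beat timing of the target is
  untouched by construction.
* **Regularization against target memorization.** With hundreds (not
  thousands) of paired segments, the alignment term is easy to
  memorize. Training therefore uses AdamW-style weight decay (3·10⁻⁴),
  and data-level augmentation that leaves semantics invariant: donor
  mixing applied to half the batch, per-voxel propagation gains
  (±30%), and white input noise (σ = 0.02). The loss formula is
  unchanged; augmentation only changes which samples it sees.
* Gradient isolation into the frozen ECG model is verified at the end
  of every fit (bit-identical parameters), and the four loss
  components are logged itemized; they sum exactly to the total.

At test time only radio input is used: Z_R = E_R(X_R) and the two
frozen decoders provide the ECG-domain and radio-domain views.

## Readouts, diagnosis, rhythm analysis

* Linear readouts (ventricular rate, PR, QT): ordinary least squares
  per target, ridge (λ = 10⁻³) when under-determined; fitting records
  the training subjects and held-out prediction refuses overlapping
  subject sets.
* Diagnosis: multinomial logistic regression on segment factors —
  linear in the factors; recording-level probability is the mean of
  segment probabilities (threshold 0.5). Per-factor attributions
  (weight × factor SD) expose the decision pathway.
* R-peak detection: band-pass (5–35 Hz) → derivative → squaring →
  150 ms moving-window integration → quantile-based adaptive threshold
  (amplitude-scale invariant) with a 200 ms refractory period, then
  refinement to the local raw-signal maximum. An adapter hook accepts
  an external detector.
* HRV: RMSSD = √mean(Δ²); SDNN uses the population (N) denominator,
  switchable to N−1; pNN50 counts |Δ| strictly greater than 50 ms;
  intervals outside 250–3000 ms are dropped by a physiological guard
  (no further normal-to-normal correction). Five-minute windows are
  half-open [t, t+300); a beat on the boundary belongs to the later
  window. The daily-life window filter discards values strictly above
  Q3 + 1.5·IQR (quartiles by linear interpolation); low values are
  always retained.

## Evaluation protocol and desk scales

The default study simulates 200 subjects × 30 s (NORMAL/AF/PB in
0.5/0.25/0.25 proportions). 60% of subjects are used to fit the
representation (ECG space on 10-s segments at 5-s stride; radio model
on segments at a denser 2.5-s stride). The remaining 40% are never seen
by either network; on them the linear readout and diagnosis heads are
evaluated with subject-disjoint K-fold cross-validation (K = 7), with
leakage asserted at run time. Retraining the full representation per
fold, as the source protocol implies at cohort scale, is replaced by
this single disjoint pretraining split: it preserves strict subject
separation while keeping the experiment tractable on one CPU.

Rhythm metrics come from R-peak detection on the semantic ECG view
decoded from radio-only input; each 10-s segment contributes the beats
in its central 5-s stride region so the stitched beat sequence tiles
the recording without duplicates, and IBI errors compare consecutive
matched beats (matching radius 300 ms). Confidence intervals use the
percentile bootstrap with 2000 resamples (median for error metrics,
mean for correlations); correlations are Pearson with two-sided
p-values.

Ablation experiments (γ = 0, α = 0, and the β sweep over
{0.01, 0.1, 1, 5, 10}) run at a reduced scale — a subset of subjects
and fewer epochs — because they multiply the training cost by the
number of variants; they assert orderings only, never magnitudes.

## Known limitations

* The synthetic world shares one torso geometry across subjects, so
  the radio nuisance variation across subjects is milder than reality;
  the invariance machinery is exercised but not stress-tested.
* The premature-beat schedule is periodic; real ectopy is not.
* Training budgets are sized for a single CPU; the networks are far
  smaller than the source architecture (depth and channel counts are
  config-exposed), and representation quality saturates slowly — the
  defaults are a compromise, not a converged optimum.
* Only donor mixing is implemented for T(·); other propagation
  perturbation families are exposed as hooks.
* Frequency-domain HRV and NN-interval ectopy correction are out of
  scope.
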