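# Methods

This note documents the models, defaults and design decisions behind
`mffnet`, and what the synthetic experiments do and do not demonstrate.

## Signal model and preprocessing

The pipeline's unit of work is a 15 s window of region-mean pixel traces:
`T x I x 3` with `T = 450` frames at 30 fps and `I = 4` facial regions
(forehead, cheeks, chin when the optional video front-end is used; any
region definition works, since the pipeline only sees the means). The
pulsatile component of skin color is small against illumination and motion,
so three normalizations are applied before any learning:

1. **Modified YUV.** A fixed linear map per sample (see README) that
   concentrates the pulse in the luma channel and decorrelates chroma.
   It is exactly linear, so it commutes with everything downstream.
2. **Time-domain normalization (TDN).** Each region-channel trace is
   z-scored (population variance) over the window. No formula is canonical
   for this step in the literature; the whole-window z-score was chosen as
   the parameter-free option, with a sliding-window variant available via
   `tdn_window` (minimum 8 samples). A constant trace — e.g. a region
   masked out of frame — normalizes to zeros and is logged, rather than
   raising, so one dead region cannot kill a batch.
3. **White-noise augmentation** (training only). Gaussian noise scaled to a
   per-trace SNR, default 10 dB. The level is a free parameter; 10 dB makes
   the augmentation visible without drowning the 0-mean unit-variance
   traces. `inf` disables it.

Preprocessing is float64 throughout; the network also runs float64 (the
arrays are small enough that there is no practical reason to drop to
float32 on CPU).

## Multi-band decomposition

Each trace is split into K band-limited copies by orthonormal type-II DCT,
zeroing all coefficients outside the band, and inverse transform. The
orthonormal convention makes Parseval exact and the mask well conditioned;
"zero-padding" is interpreted as zeroing coefficients *in place* (no
compaction), the only reading that returns a length-T signal through the
inverse transform. DCT bin `u` is assigned frequency `u*fps/(2T)` and bands
are half-open so they partition cleanly.

Defaults: K = 3 with bands 0.6-1.5, 1.5-3.0, 3.0-4.2 Hz. The first two
cover pulse fundamentals below and above 90 bpm; the third covers first
harmonics. The K value and edges are configuration, not constants.

## Network

Per band, an encoder/decoder branch with independent weights:

* **Encoder** (x3): TMSC block (parallel same-padded convolutions with
  kernels 3/5/7, outputs concatenated) -> batch norm -> ELU -> stride-2
  average pooling (ceil mode). 450 -> 225 -> 113 -> 57 samples.
* **Decoder** (x3): SSA block -> stride-2 transposed convolution (kernel 4)
  cropped to the mirrored encoder length -> batch norm -> ELU. Restores
  exactly 450 samples.
* **Fusion**: channel concatenation of the K branch outputs and a 1x1
  convolution to a single trace.

**SSA (spectrum self-attention).** The working assumption is that the
spectral content of a pulse signal is similar across time segments, so a
segment whose spectrum deviates from the window consensus is likely
corrupted. Implementation: split the feature map into segments of
`segment_len` (default 15 samples; zero-padded to a multiple, cropped
after), DCT each segment, collapse channels with a learned 1x1 convolution
to one spectral descriptor per segment, unit-normalize the descriptors
(so a high-power segment cannot dominate the consensus), score each
descriptor by its dot product with the mean descriptor, and softmax over
segments (temperature 4.0) into weights that sum to one. Weights are
rescaled by the segment count so uniform attention is the identity, then a
squeeze-excitation channel gate (hidden width 4, gate bias initialized
open) aggregates globally. The similarity rule is declared, test-fixed
behavior, and swappable via configuration.

**Widths and budgets.** Channel widths are not architectural constants of
the method; the normative constraint is the budget pair: at most 11,000
trainable parameters and at most 1.3e8 FLOPs per forward pass, counting one
multiply-accumulate as two FLOPs and batch-norm/activation/pooling once per
element. The defaults (3 channels per TMSC kernel -> 9 branch channels,
3 branches) give 8,335 parameters and ~4.4e6 FLOPs; violating either budget
is a construction-time error. ELU was chosen as a smooth, negative-
preserving activation for zero-mean signals; batch norm uses momentum 0.1.

The network stack (`mffnet.nn`) is a reverse-mode autodiff engine on numpy
arrays written for this package, with convolution via im2col, transposed
convolution via input dilation, and Adam. All layer gradients are verified
against central finite differences in the test suite.

## Training

Loss: `1 - r`, the negative sample Pearson correlation between predicted
and reference waveform, averaged over the batch — scale- and offset-free,
matching how BVP is sensed. Targets are z-scored reference pulses.

Two phases (Adam): phase 1 on plain shuffled batches at 3e-3; phase 2 at
3e-4 on batches stratified by HR group — 10-bpm bins over 40-180 bpm,
equal slots per non-empty bin, remainder round-robin, over-sampling with
replacement inside bins smaller than their quota. Learning rates, epoch
counts and bin edges are configuration; the defaults were fixed during
development as settings at which training converges reliably on the
synthetic task. Divergence (non-finite loss) aborts with a diagnostic.

## Rhythm metrics

* **HR**: 60x the argmax frequency of the Welch spectrum (single segment of
  up to 512 samples, zero-padded to >= 8192 bins) within 0.6-4.2 Hz. The
  zero-padding resolves the peak well below the raw ~4 bpm bin width of a
  15 s window. A spectrum with no in-band power is an error.
* **Peaks/IBIs**: 3rd-order Butterworth band-pass to 0.6-4.2 Hz
  (zero-phase), peaks at least 0.25 s apart with prominence at least 0.3x
  the signal SD; intervals gated to 0.25-2.0 s.
* **HRV**: intervals anchored at their end beat, interpolated to a 4 Hz
  tachogram (cubic when at least 4 intervals), linearly detrended, Welch
  with a single segment (best LF resolution on short windows);
  LF = 0.04-0.15 Hz, HF = 0.15-0.4 Hz, reported in normalized units
  lf_nu = LF/(LF+HF) plus the LF/HF ratio. At least 10 s of intervals are
  required; 15 s windows give only ~1.5 LF cycles, so HRV validation uses
  60 s windows.
* **Error metrics**: MAE, RMSE, Std of the error with the population
  (ddof = 0) convention — hence the identity RMSE^2 = Std^2 + mean(e)^2 —
  and Pearson's r (NaN with a warning for constant inputs).

## Synthetic data generator

The generator emulates what a facial-video front-end plus contact sensor
would deliver, with every disturbance controllable:

* **Pulse**: harmonics (amplitudes 1.0/0.4/0.15) of a beat phase whose
  instantaneous frequency is the target HR modulated multiplicatively at
  0.1 Hz (LF) and 0.3 Hz (HF), depths 0.03/0.02 by default; the window
  mean of the modulation is removed so the realized mean HR equals the
  request. A phase skew (`+0.3 sin(phase)`) sharpens the systolic upstroke.
  Ground-truth beat times are phase crossings of multiples of 2-pi,
  located by linear interpolation.
* **Appearance**: per region/channel baselines (R 120, G 100, B 90) and
  pulsatile gains with green strongest and the chin weakest, pulse
  amplitude 1.5 pixel units on a 0-255 scale.
* **Disturbances**: low-pass (< 0.15 Hz) Gaussian drift of amplitude 2;
  Poisson motion artifacts (1 per window, Hann bumps of ~0.5 s, amplitude
  5); optional narrowband interference (a periodic disturbance at a
  nominal frequency, +-20% per-sample jitter, optional 1/h harmonics);
  white noise at a per-trace SNR relative to the pulsatile power, default
  10 dB.
* **Sampling**: HR uniform on a range or imbalanced over weighted strata;
  all randomness is spawned from one root seed per sample index, so any
  sample regenerates bit-exactly from (config, index).

What the generator does **not** model: real skin photometrics, spatially
correlated motion across regions, camera compression artifacts,
nonstationary HR trends within a window. Passing the synthetic experiments
therefore demonstrates internal consistency and trainability of the
pipeline, not benchmark performance on video datasets.

## Validation experiments and study sizes

* **Parameter recovery**: 480 training windows, 60 held-out (HR uniform
  50-150 bpm, 10 dB SNR, drift and artifacts on), 16 + 6 epochs. Passing
  criteria: held-out HR MAE <= 3 bpm and mean waveform Pearson r >= 0.8.
  Typical results are ~0.5 bpm and r ~ 0.98.
* **Ablations** (3 seeds; 0.3 Hz interferer at amplitude 10, 0 dB white
  noise, drift/artifacts on, 90/10 HR imbalance; 200 training windows,
  40 held-out drawn 50/50 from both strata; 10 + 5 epochs): the full model
  vs (i) the band list truncated to K = 1 — the first band of interest
  cannot carry fundamentals above 90 bpm, so this variant probes the
  coverage role of the multi-band decomposition — and (ii) plain phase-2
  sampling instead of HR-stratified batches.

Two honest negative findings from development:

* A K = 1 variant given one *wide* band (0.6-4.2 Hz) performs on par with
  the multi-band model on this generator once trained to convergence — the
  disturbances here are either out-of-band (removable by any fixed filter a
  convolution can learn) or in-band white noise (irreducible for every
  variant). The advantage of splitting the pulse band into modes is
  expected to come from structured, nonstationary in-band noise of real
  video, which this generator does not attempt to model.
* The over-sampling comparison is statistically a tie on this generator:
  across many regimes (interferer amplitudes 2-14, with and without
  interferer harmonics, imbalances 90/10 and 95/5, 120-320 training
  windows, phase-2 learning rates up to 1e-3), stratified and plain
  phase-2 sampling differ by under ~0.05 bpm in mean held-out HR MAE with
  an unstable sign. The reason is that the denoising the network learns is
  HR-agnostic — a solution fitted on 60-80 bpm windows transfers to
  100-140 bpm for free — so training imbalance costs nothing here. When
  phase 2 is made aggressive (higher learning rate, more epochs) with
  small rare-bin pools, over-sampling with replacement *hurts* by
  overfitting the few rare windows. The benefit reported for this scheme
  on real corpora presumably depends on HR-specific structure (waveform
  shape changes with rate, nonstationary noise) that the generator does
  not emulate; the corresponding directional test documents this
  expectation rather than a robust property of the synthetic task.

## Numerical choices and degenerate inputs

* Population (ddof 0) standard deviations everywhere.
* Constant traces: TDN returns zeros; Pearson loss reports r = 0 (loss 1)
  for a constant prediction and refuses a constant target; error-metric r
  is NaN with a warning.
* Band validation rejects empty bands (no DCT bin) naming the band, and
  overlapping or out-of-Nyquist band lists.
* The budget check runs at construction; a config exceeding either budget
  never instantiates.
* Determinism: every stochastic component (generator, augmentation,
  samplers, weight init, training order) takes an explicit seed; two runs
  with the same configuration and seeds are bit-identical on the same
  platform.

## Known limitations

* The optional video front-end requires a user-supplied landmark backend;
  no face detector ships with the package.
* HRV from 15 s windows is unreliable below ~0.07 Hz by construction;
  use longer windows for LF.
* The spectral HR estimator reports the dominant in-band peak; it does not
  flag harmonic-locking, which peak-based HR (`hr_from_peaks`) can
  cross-check.
* Training is CPU-bound numpy; it is sized for hundreds, not millions, of
  windows.
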