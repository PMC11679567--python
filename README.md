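# mffnet

Camera-based vital-sign monitoring (remote photoplethysmography, rPPG)
recovers the blood-volume pulse (BVP) from the subtle color changes of
facial skin in ordinary video. `mffnet` implements a lightweight
multi-frequency pipeline for this problem: facial-video region-mean RGB
traces ("spatio-temporal maps", nominally 450 frames x 4 regions x 3
channels at 30 fps) are converted to a modified YUV color space,
standardized in time, split into K band-limited modes by DCT spectrum
cutting, refined and reconstructed by a small per-band neural network
(~8k parameters), and fused into a single BVP waveform from which heart
rate (HR) and heart-rate variability (HRV; LF/HF in normalized units) are
derived. A seeded synthetic rPPG generator with full ground truth (BVP,
HR, inter-beat intervals) makes every stage trainable and testable without
any video dataset.

Intended users: researchers working on camera-based physiological
measurement who need a compact, CPU-friendly, fully reproducible reference
pipeline, and anyone who wants controllable synthetic rPPG data.

## Method

**Color transform.** Each region-mean RGB sample is mapped to modified YUV,

    [Y]   [ 0.299  0.587  0.114] [R]
    [U] = [-0.169 -0.331  0.500] [G]
    [V]   [ 0.500 -0.419 -0.081] [B]

concentrating the pulsatile signal in the luma channel. Every
region-channel trace is then z-scored over the window (time-domain
normalization); Gaussian white noise at a configurable SNR is added as a
training-time augmentation.

**Multi-frequency decomposition.** Each trace f_i(n) is transformed with an
orthonormal type-II DCT to F_i(u); for each band of interest [lo_k, hi_k)
the out-of-band coefficients are zeroed and the inverse transform yields a
band-limited copy f'_{i,k}(n). Defaults: K = 3 bands, 0.6-1.5, 1.5-3.0 and
3.0-4.2 Hz (pulse fundamentals below/above 90 bpm plus first harmonics).

**Network (SRRN).** One branch per band with independent weights. Encoder
stage: temporal multiscale convolution (parallel kernels 3/5/7,
concatenated) -> batch norm -> ELU -> stride-2 pooling, three times.
Decoder stage: spectrum self-attention (segments whose DCT spectra deviate
from the window consensus are down-weighted, then a squeeze-excitation
channel gate) -> stride-2 transposed convolution -> batch norm -> ELU,
restoring the 450-sample length exactly. A 1x1 convolution fuses the K
branches into one BVP trace. The default configuration must satisfy hard
budgets — at most 11,000 trainable parameters and 1.3e8 FLOPs per forward
pass (1 multiply-accumulate = 2 FLOPs) — and construction fails otherwise.

**Training.** Loss is 1 - r (negative Pearson correlation) between the
predicted and reference waveform. Two phases: all samples with a large
learning rate, then a small learning rate with batches stratified by HR
group (equal slots per 10-bpm bin, over-sampling scarce bins with
replacement) to counter imbalanced HR distributions.

**Rhythm metrics.** HR is 60x the peak frequency of the Welch spectrum of
the BVP in 0.6-4.2 Hz. Systolic peaks give inter-beat intervals (gated to
0.25-2.0 s); the 4 Hz interpolated tachogram's power in 0.04-0.15 Hz (LF)
and 0.15-0.4 Hz (HF) gives lf_nu = LF/(LF+HF), hf_nu, and LF/HF. Error
metrics: MAE, RMSE, Std of the error, Pearson's r.

The network stack (reverse-mode autodiff, conv/deconv/batch-norm layers,
Adam) is implemented in numpy inside `mffnet.nn`; gradients are verified
against finite differences in the test suite.

## Worked example

```python
import numpy as np
from mffnet import (SynthConfig, preprocess, BandSpec, MFFNet,
                    SampleRecord, TrainPlan, train, hr_from_bvp, BVPSignal)
from mffnet.synth import gen_sample
from mffnet.train import prepare_input

cfg = SynthConfig(hr_range=(50, 150), snr_db=10.0, seed=11)
records = [
    SampleRecord(stmap=preprocess(s.stmap), gt_bvp=s.gt_bvp, gt_hr=s.gt_hr)
    for s in (gen_sample(cfg, i) for i in range(480))
]
model = MFFNet(seed=11)
history = train(model, records, TrainPlan(phase1_epochs=16, phase2_epochs=6,
                                          rng_seed=11))
print(f"final training loss {history[-1]['loss']:.3f}")

held_out = gen_sample(cfg, 1_000_000)
x = prepare_input(preprocess(held_out.stmap), BandSpec(fps=30.0))
bvp = model.predict(x[None])[0]
hr = hr_from_bvp(bvp).hr_bpm
print(f"true HR {held_out.gt_hr:.1f} bpm, recovered {hr:.1f} bpm")
```

Output (seed 11):

```
final training loss 0.020
true HR 112.1 bpm, recovered 114.0 bpm
```

The final loss of 0.02 means the recovered waveform correlates with the
reference at r ~ 0.98 on training windows; across a 60-window held-out set
the same model reaches an HR MAE of ~0.5 bpm (this particular window sits
at the tail of that error distribution).

The same pipeline is scriptable from the shell:

```
mffnet synth --out data/ --n 64 --seed 4
mffnet preprocess --in series.npz --out map.npz
mffnet decompose --in map.npz --bands "0.6-1.5,1.5-3.0,3.0-4.2" --out stack.npz
mffnet train --data data/ --out model.npz
mffnet infer --model model.npz --in map.npz --out bvp.csv
mffnet evaluate --pred bvp.csv --truth bvp_gt.csv --report report.json
```

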