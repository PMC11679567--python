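"""Synthetic rPPG data: pulse waveforms and spatio-temporal maps.

The generator produces the kind of data a facial-video front-end would
deliver — region-mean RGB traces at 30 fps — together with the ground truth
a contact sensor would provide: the pulse waveform, its mean HR and the
inter-beat intervals.  It emulates the disturbances the recovery method
targets:

* a quasi-periodic pulse: harmonics of an instantaneous beat frequency that
  is modulated multiplicatively at LF (0.1 Hz) and HF (0.3 Hz), giving
  controllable HRV, with a phase skew sharpening the systolic upstroke;
* per-region / per-channel pulsatile gains (green/luma strongest);
* slow illumination drift (low-pass noise below 0.15 Hz);
* sparse transient motion artifacts (random smooth bumps);
* additive white noise at a configurable per-trace SNR;
* a controllable, optionally imbalanced, HR distribution across samples.

All randomness flows from one root seed through per-sample spawned streams,
so any single sample is regenerable independently of the rest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .metrics import IBISeries
from .stmap import RGBRegionSeries

__all__ = [
    "SynthConfig", "SynthSample", "gen_bvp_waveform", "gen_stmap",
    "gen_dataset", "DEFAULT_REGION_GAINS",
]

#: Pulsatile gain per region (rows) and RGB channel (columns).  Green
#: carries the strongest pulse, red the weakest, mirroring skin absorption;
#: the forehead and cheeks perfuse more strongly than the chin.
DEFAULT_REGION_GAINS = np.array([
    [0.33, 1.00, 0.60],   # forehead
    [0.30, 0.90, 0.55],   # left cheek
    [0.30, 0.90, 0.55],   # right cheek
    [0.20, 0.60, 0.40],   # chin
])


@dataclass(frozen=True)
class SynthConfig:
    n_samples: int = 100
    duration_s: float = 15.0
    fps: float = 30.0
    hr_range: tuple[float, float] = (50.0, 150.0)
    hr_distribution: str = "uniform"          # or "imbalanced"
    #: for "imbalanced": (weight, (lo, hi)) pairs; weights sum to 1
    hr_weights: tuple[tuple[float, tuple[float, float]], ...] = (
        (0.9, (60.0, 80.0)), (0.1, (100.0, 140.0)))
    lf_freq: float = 0.1
    hf_freq: float = 0.3
    lf_depth: float = 0.03
    hf_depth: float = 0.02
    harmonic_amps: tuple[float, ...] = (1.0, 0.4, 0.15)
    pulse_amp: float = 1.5                    # pixel units on a 0-255 scale
    baseline: tuple[float, float, float] = (120.0, 100.0, 90.0)
    drift_amp: float = 2.0                    # pixel units, < 0.15 Hz
    drift_cutoff: float = 0.15
    artifact_rate: float = 1.0                # expected artifacts per window
    artifact_amp: float = 5.0
    artifact_duration_s: float = 0.5
    snr_db: float = 10.0                      # inf = noiseless
    interference_freq: float = 0.0            # Hz; 0 = off (narrowband tone)
    interference_amp: float = 0.0
    interference_jitter: float = 0.2          # per-sample rel. freq spread
    #: periodic (non-sinusoidal) interference: number of harmonics with
    #: 1/h amplitude decay.  1 = pure tone; >1 puts harmonics of a slow
    #: disturbance (e.g. rhythmic motion or flicker) inside the pulse band.
    interference_harmonics: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (40.0 <= self.hr_range[0] < self.hr_range[1] <= 180.0):
            raise ValueError("hr_range must lie within [40, 180] bpm")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration must be positive")
        if self.hr_distribution not in ("uniform", "imbalanced"):
            raise ValueError(
                f"unknown hr_distribution {self.hr_distribution!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class SynthSample:
    stmap: RGBRegionSeries
    gt_bvp: np.ndarray
    gt_hr: float
    gt_ibi: IBISeries
    index: int = 0


def gen_bvp_waveform(hr_bpm: float, cfg: SynthConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, IBISeries]:
    """Quasi-periodic pulse with HRV modulation; returns (bvp, ibi).

    The instantaneous beat frequency is ``hr/60 * (1 + d_lf sin(2π f_lf t + φ)
    + d_hf sin(2π f_hf t + ψ))``; its integral is the beat phase.  The
    waveform sums the configured harmonics of that phase, skewed so the
    systolic rise is steeper than the fall.  Ground-truth beat times are the
    crossings of phase multiples of 2π, located by linear interpolation.
    """
    n = cfg.n_frames
    t = np.arange(n) / cfg.fps
    phi_lf, phi_hf = rng.uniform(0, 2 * np.pi, size=2)
    mod = (cfg.lf_depth * np.sin(2 * np.pi * cfg.lf_freq * t + phi_lf)
           + cfg.hf_depth * np.sin(2 * np.pi * cfg.hf_freq * t + phi_hf))
    # remove the window-mean of the modulation so the realized mean rate
    # equals the requested HR even when the window holds partial LF cycles
    f_inst = (hr_bpm / 60.0) * (1.0 + mod - mod.mean())
    phase = 2 * np.pi * np.cumsum(f_inst) / cfg.fps
    phase -= phase[0]
    skewed = phase + 0.3 * np.sin(phase)      # sharpened systolic upstroke
    bvp = sum(a * np.cos((h + 1) * skewed)
              for h, a in enumerate(cfg.harmonic_amps))
    # beat times: phase crossings of 2*pi*k
    beat_times = []
    k_max = int(phase[-1] // (2 * np.pi))
    for k in range(0, k_max + 1):
        target = 2 * np.pi * k
        idx = int(np.searchsorted(phase, target))
        if idx == 0:
            beat_times.append(t[0])
        elif idx < n:
            frac = ((target - phase[idx - 1])
                    / (phase[idx] - phase[idx - 1]))
            beat_times.append(t[idx - 1] + frac / cfg.fps)
    beat_times = np.asarray(beat_times)
    ibi = IBISeries(intervals=np.diff(beat_times), peak_times=beat_times)
    return np.asarray(bvp), ibi


def _lowpass_noise(n: int, fps: float, cutoff: float, amp: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth drift: white noise low-passed below ``cutoff`` Hz."""
    raw = rng.normal(size=n)
    sos = sps.butter(2, cutoff / (fps / 2.0), btype="low", output="sos")
    drift = sps.sosfiltfilt(sos, raw)
    sd = drift.std()
    return drift * (amp / sd) if sd > 0 else drift


def _artifacts(n: int, fps: float, cfg: SynthConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Sparse smooth transient bumps (Hann-windowed) at Poisson times."""
    out = np.zeros(n)
    n_events = rng.poisson(cfg.artifact_rate)
    width = max(3, int(round(cfg.artifact_duration_s * fps)))
    for _ in range(n_events):
        center = rng.integers(0, n)
        amp = cfg.artifact_amp * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
        bump = amp * np.hanning(width)
        lo = max(0, center - width // 2)
        hi = min(n, lo + width)
        out[lo:hi] += bump[:hi - lo]
    return out


def gen_stmap(bvp: np.ndarray, cfg: SynthConfig,
              rng: np.random.Generator,
              region_gains: np.ndarray | None = None) -> RGBRegionSeries:
    """Embed a pulse waveform into region-mean RGB traces with disturbances."""
    gains = DEFAULT_REGION_GAINS if region_gains is None else region_gains
    n = len(bvp)
    I, C = gains.shape
    t = np.arange(n) / cfg.fps
    values = np.empty((n, I, C))
    bvp_unit = (bvp - bvp.mean()) / bvp.std()
    # one flicker frequency per sample: narrowband around the nominal value
    interf_freq = cfg.interference_freq * (
        1.0 + cfg.interference_jitter * rng.uniform(-1.0, 1.0))
    for i in range(I):
        for c in range(C):
            trace = cfg.baseline[c] + cfg.pulse_amp * gains[i, c] * bvp_unit
            if cfg.drift_amp > 0:
                trace = trace + _lowpass_noise(n, cfg.fps, cfg.drift_cutoff,
                                               cfg.drift_amp, rng)
            if cfg.artifact_rate > 0 and cfg.artifact_amp > 0:
                trace = trace + _artifacts(n, cfg.fps, cfg, rng)
            if cfg.interference_amp > 0 and cfg.interference_freq > 0:
                for h in range(1, cfg.interference_harmonics + 1):
                    if h * interf_freq >= cfg.fps / 2:
                        break
                    trace = trace + (cfg.interference_amp / h) * np.sin(
                        2 * np.pi * h * interf_freq * t
                        + rng.uniform(0, 2 * np.pi))
            if not np.isinf(cfg.snr_db):
                sig_power = (cfg.pulse_amp * gains[i, c]) ** 2  # unit-var bvp
                noise_sd = np.sqrt(sig_power / 10 ** (cfg.snr_db / 10))
                trace = trace + rng.normal(0, noise_sd, size=n)
            values[:, i, c] = trace
    return RGBRegionSeries(values=values, fps=cfg.fps)


def _draw_hr(cfg: SynthConfig, rng: np.random.Generator) -> float:
    if cfg.hr_distribution == "uniform":
        return float(rng.uniform(*cfg.hr_range))
    if cfg.hr_distribution == "imbalanced":
        weights = np.array([w for w, _ in cfg.hr_weights])
        idx = rng.choice(len(weights), p=weights / weights.sum())
        lo, hi = cfg.hr_weights[idx][1]
        return float(rng.uniform(lo, hi))
    raise ValueError(f"unknown hr_distribution {cfg.hr_distribution!r}")


def gen_sample(cfg: SynthConfig, index: int) -> SynthSample:
    """Generate sample ``index`` of the dataset; bit-reproducible from
    (config, index) alone."""
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(index,))
    rng = np.random.default_rng(ss)
    hr = _draw_hr(cfg, rng)
    bvp, ibi = gen_bvp_waveform(hr, cfg, rng)
    stmap = gen_stmap(bvp, cfg, rng)
    return SynthSample(stmap=stmap, gt_bvp=bvp, gt_hr=hr, gt_ibi=ibi,
                       index=index)


def gen_dataset(cfg: SynthConfig) -> tuple[list[SynthSample], "object"]:
    """Generate ``cfg.n_samples`` samples plus a manifest DataFrame."""
    import pandas as pd

    samples = [gen_sample(cfg, i) for i in range(cfg.n_samples)]
    manifest = pd.DataFrame({
        "index": [s.index for s in samples],
        "hr_bpm": [s.gt_hr for s in samples],
        "seed": [cfg.seed] * len(samples),
    })
    return samples, manifest
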