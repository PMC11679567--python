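"""Spatio-temporal map preprocessing.

A *spatio-temporal map* is the standard compact rPPG network input: for each
video frame, mean pixel values are taken over a handful of facial regions,
giving a ``time x region x color-channel`` array.  This module converts
region-mean RGB series into the modified-YUV color space (which concentrates
the pulsatile component in the luma channel), standardizes each
region-channel trace in time (TDN), and optionally injects Gaussian white
noise at a target SNR as a training-time augmentation.

All preprocessing runs in float64; the network consumes float32 downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RGBRegionSeries", "SpatioTemporalMap", "PreprocessConfig",
    "YUV_MATRIX", "rgb_to_modified_yuv", "temporal_normalize",
    "inject_white_noise", "preprocess", "video_to_region_series",
]

#: Modified-YUV color transform: luma from Rec.601 weights, chroma rows
#: scaled so each channel spans a comparable range.  Applied per sample as
#: (Y,U,V)^T = M (R,G,B)^T.
YUV_MATRIX = np.array([
    [0.299, 0.587, 0.114],
    [-0.169, -0.331, 0.5],
    [0.5, -0.419, -0.081],
])

DEFAULT_REGIONS = ("forehead", "left_cheek", "right_cheek", "chin")


def _validate_values(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3 or values.shape[2] != 3:
        raise ValueError(f"expected a T x I x 3 array, got shape {values.shape}")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if values.shape[1] < 1:
        raise ValueError("need at least 1 region")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in region series")
    return values


@dataclass
class RGBRegionSeries:
    """Region-mean RGB traces: ``values[t, i, c]`` with c in (R, G, B)."""

    values: np.ndarray
    fps: float
    region_labels: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self):
        self.values = _validate_values(self.values)
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if len(self.region_labels) != self.values.shape[1]:
            self.region_labels = tuple(
                f"region_{i}" for i in range(self.values.shape[1]))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class SpatioTemporalMap:
    """Modified-YUV map, optionally temporally normalized."""

    values: np.ndarray
    fps: float
    normalized: bool = False
    region_labels: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self):
        self.values = _validate_values(self.values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class PreprocessConfig:
    """Knobs for normalization and augmentation.

    noise_snr_db: per-trace SNR of the injected white noise, in dB;
        ``inf`` disables the augmentation.
    tdn_window: samples per normalization window; 0 = whole trace.
    """

    noise_snr_db: float = 10.0
    tdn_window: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if np.isnan(self.noise_snr_db):
            raise ValueError("noise_snr_db must not be NaN")
        if self.tdn_window != 0 and not 8 <= self.tdn_window:
            raise ValueError("tdn_window must be 0 or >= 8")


def rgb_to_modified_yuv(series: RGBRegionSeries) -> SpatioTemporalMap:
    """Convert region-mean RGB to modified YUV (exactly linear)."""
    yuv = np.einsum("dc,tic->tid", YUV_MATRIX, series.values)
    return SpatioTemporalMap(values=yuv, fps=series.fps, normalized=False,
                             region_labels=series.region_labels)


def _zscore(trace: np.ndarray) -> np.ndarray:
    mu = trace.mean()
    sd = trace.std()  # population convention
    if sd < 1e-12 * max(1.0, abs(mu)) or sd == 0.0:
        return np.zeros_like(trace)
    return (trace - mu) / sd


def temporal_normalize(stmap: SpatioTemporalMap,
                       cfg: PreprocessConfig | None = None) -> SpatioTemporalMap:
    """Standardize each region-channel trace to zero mean / unit variance.

    Constant traces (e.g. a fully masked region) come back as all zeros
    rather than raising, and are logged as degenerate.  With
    ``cfg.tdn_window > 0`` the z-score is applied per non-overlapping window
    instead of over the whole trace.
    """
    cfg = cfg or PreprocessConfig()
    T, I, C = stmap.values.shape
    win = cfg.tdn_window
    if win > T:
        raise ValueError(f"tdn_window {win} exceeds trace length {T}")
    out = np.empty_like(stmap.values)
    n_degenerate = 0
    for i in range(I):
        for c in range(C):
            trace = stmap.values[:, i, c]
            if trace.std() == 0.0:
                n_degenerate += 1
            if win == 0:
                out[:, i, c] = _zscore(trace)
            else:
                for start in range(0, T, win):
                    seg = trace[start:start + win]
                    out[start:start + win, i, c] = _zscore(seg)
    if n_degenerate:
        logger.warning("temporal_normalize: %d constant trace(s) set to zero",
                       n_degenerate)
    return SpatioTemporalMap(values=out, fps=stmap.fps, normalized=True,
                             region_labels=stmap.region_labels)


def inject_white_noise(stmap: SpatioTemporalMap,
                       cfg: PreprocessConfig) -> SpatioTemporalMap:
    """Add per-trace Gaussian white noise at ``cfg.noise_snr_db``.

    The noise standard deviation for each region-channel trace is set from
    that trace's power so that signal power / noise power equals the
    configured SNR.  ``noise_snr_db = inf`` is the documented sentinel for
    "disabled".  Deterministic under ``cfg.rng_seed``.
    """
    if not stmap.normalized:
        raise ValueError("inject_white_noise expects a normalized map")
    if np.isinf(cfg.noise_snr_db):
        return stmap
    rng = np.random.default_rng(cfg.rng_seed)
    values = stmap.values.copy()
    T, I, C = values.shape
    snr_linear = 10.0 ** (cfg.noise_snr_db / 10.0)
    for i in range(I):
        for c in range(C):
            sig_power = values[:, i, c].var()
            noise_sd = np.sqrt(sig_power / snr_linear) if sig_power > 0 else 0.0
            values[:, i, c] += rng.normal(0.0, noise_sd, size=T)
    return SpatioTemporalMap(values=values, fps=stmap.fps, normalized=True,
                             region_labels=stmap.region_labels)


def preprocess(series: RGBRegionSeries, cfg: PreprocessConfig | None = None,
               augment: bool = False) -> SpatioTemporalMap:
    """Full chain: modified YUV -> TDN -> (optional) noise augmentation."""
    cfg = cfg or PreprocessConfig()
    out = temporal_normalize(rgb_to_modified_yuv(series), cfg)
    if augment:
        out = inject_white_noise(out, cfg)
    return out


def video_to_region_series(frames, fps: float, landmark_backend,
                           region_labels: tuple[str, ...] = DEFAULT_REGIONS,
                           ) -> RGBRegionSeries:
    """Reduce a facial video to per-region mean RGB traces.

    This is the optional video front-end; the landmark model itself is
    external.  ``frames`` is an iterable of H x W x 3 RGB frames (uint8 or
    float).  ``landmark_backend`` is a callable ``frame -> list of I boolean
    masks (or None if no face found)``.  Frames with no detected face carry
    the previous frame's values forward (and are logged); a clip in which no
    frame contains a face is a hard error.
    """
    per_frame: list[np.ndarray | None] = []
    for frame in frames:
        frame = np.asarray(frame, dtype=np.float64)
        masks = landmark_backend(frame)
        if masks is None:
            per_frame.append(None)
        else:
            per_frame.append(
                np.stack([frame[m].mean(axis=0) for m in masks]))
    if all(m is None for m in per_frame):
        raise RuntimeError("no face detected in any frame")
    n_dropout = sum(m is None for m in per_frame)
    first = next(m for m in per_frame if m is not None)
    rows: list[np.ndarray] = []
    prev = first  # leading dropouts take the first detection's values
    for m in per_frame:
        prev = prev if m is None else m
        rows.append(prev)
    if n_dropout:
        logger.warning("video_to_region_series: %d frame(s) without a "
                       "detection; previous values carried forward", n_dropout)
    return RGBRegionSeries(values=np.stack(rows), fps=fps,
                           region_labels=region_labels)
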