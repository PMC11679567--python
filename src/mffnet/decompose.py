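"""Multi-frequency mode decomposition via DCT band slicing.

Each region-channel trace of a normalized spatio-temporal map is split into
K band-limited signals: orthonormal type-II DCT, zeroing of all coefficients
outside the band of interest (the "cut + zero-pad" step), and the inverse
transform back to the time domain.  Stacking the K filtered copies of every
trace yields the multi-band input that the refinement network consumes, one
branch per band.

The DCT bin ``u`` of a length-T trace sampled at ``fps`` is assigned the
frequency ``u * fps / (2 T)`` Hz, so the half-open band ``[lo, hi)`` keeps
exactly the bins with ``lo <= u*fps/(2T) < hi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, idct

from .stmap import SpatioTemporalMap

__all__ = [
    "BandSpec", "Spectrum", "MultiBandStack", "DEFAULT_BANDS",
    "dct_ortho", "idct_ortho", "band_slice_zero_pad", "decompose_multiband",
]

#: Default K = 3 bands (Hz): pulse fundamentals below / above 90 bpm, and
#: the first-harmonic range.  Covers 36-252 bpm fundamentals overall.
DEFAULT_BANDS = ((0.6, 1.5), (1.5, 3.0), (3.0, 4.2))


@dataclass(frozen=True)
class BandSpec:
    """K sorted, non-overlapping half-open frequency intervals in Hz."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    fps: float = 30.0

    def __post_init__(self):
        if len(self.bands) < 1:
            raise ValueError("need at least one band")
        nyquist = self.fps / 2.0
        prev_hi = -np.inf
        for lo, hi in self.bands:
            if not (0.0 <= lo < hi <= nyquist):
                raise ValueError(
                    f"band [{lo}, {hi}) outside [0, {nyquist}] or empty")
            if lo < prev_hi:
                raise ValueError("bands must be sorted and non-overlapping")
            prev_hi = hi

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class Spectrum:
    """Orthonormal DCT-II coefficients of one trace."""

    coeffs: np.ndarray
    fps: float

    def bin_freqs(self) -> np.ndarray:
        T = len(self.coeffs)
        return np.arange(T) * self.fps / (2.0 * T)


@dataclass
class MultiBandStack:
    """Band-limited copies of a map: ``values[k, t, i, c]``."""

    values: np.ndarray
    band_spec: BandSpec

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]


def dct_ortho(trace: np.ndarray, fps: float = 30.0) -> Spectrum:
    """Orthonormal type-II DCT of a 1-D trace (Parseval-exact)."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) < 2:
        raise ValueError("dct_ortho expects a 1-D trace of length >= 2")
    return Spectrum(coeffs=dct(trace, type=2, norm="ortho"), fps=fps)


def idct_ortho(spec: Spectrum) -> np.ndarray:
    """Inverse (type-III) transform; exact inverse of :func:`dct_ortho`."""
    return idct(spec.coeffs, type=2, norm="ortho")


def band_mask(T: int, fps: float, band: tuple[float, float]) -> np.ndarray:
    """Boolean mask of DCT bins whose frequency lies in ``[lo, hi)``."""
    lo, hi = band
    freqs = np.arange(T) * fps / (2.0 * T)
    return (freqs >= lo) & (freqs < hi)


def band_slice_zero_pad(spec: Spectrum, band: tuple[float, float]) -> Spectrum:
    """Keep in-band DCT coefficients in place, zero everything else."""
    mask = band_mask(len(spec.coeffs), spec.fps, band)
    if not mask.any():
        raise ValueError(
            f"band [{band[0]}, {band[1]}) Hz selects no DCT bin at "
            f"T={len(spec.coeffs)}, fps={spec.fps}")
    out = np.where(mask, spec.coeffs, 0.0)
    return Spectrum(coeffs=out, fps=spec.fps)


def decompose_multiband(stmap: SpatioTemporalMap,
                        spec: BandSpec | None = None) -> MultiBandStack:
    """Split every region-channel trace into K band-limited signals.

    Vectorized: one DCT over the whole map, K masked inverse transforms.
    Linear in the input by construction.
    """
    spec = spec or BandSpec(fps=stmap.fps)
    if spec.fps != stmap.fps:
        spec = BandSpec(bands=spec.bands, fps=stmap.fps)
    values = stmap.values  # T x I x C
    T = values.shape[0]
    coeffs = dct(values, type=2, norm="ortho", axis=0)
    out = np.empty((spec.n_bands,) + values.shape)
    for k, band in enumerate(spec.bands):
        mask = band_mask(T, spec.fps, band)
        if not mask.any():
            raise ValueError(
                f"band [{band[0]}, {band[1]}) Hz selects no DCT bin at "
                f"T={T}, fps={spec.fps}")
        out[k] = idct(coeffs * mask[:, None, None], type=2, norm="ortho",
                      axis=0)
    return MultiBandStack(values=out, band_spec=spec)
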