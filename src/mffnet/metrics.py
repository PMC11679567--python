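"""Heart rate, heart-rate variability and evaluation metrics.

HR is read from the Welch power spectrum of the recovered pulse waveform
(one calculation per window); inter-beat intervals come from systolic peak
detection; HRV is summarized by low-frequency (0.04-0.15 Hz) and
high-frequency (0.15-0.4 Hz) power of the interpolated tachogram in
normalized units, plus their ratio.  Error metrics follow the usual rPPG
conventions: MAE, RMSE, Std of the error (population), and Pearson's r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

from .srrn import BVPSignal

logger = logging.getLogger(__name__)

__all__ = [
    "IBISeries", "HRResult", "HRVResult", "HR_BAND", "LF_BAND", "HF_BAND",
    "hr_from_bvp", "detect_peaks", "hrv_lf_hf", "error_metrics",
]

HR_BAND = (0.6, 4.2)     # Hz; 36-252 bpm
LF_BAND = (0.04, 0.15)   # Hz
HF_BAND = (0.15, 0.4)    # Hz
IBI_GATE = (0.25, 2.0)   # s; physiological inter-beat interval range


@dataclass
class IBISeries:
    """Inter-beat intervals (s) and the peak times they join."""

    intervals: np.ndarray
    peak_times: np.ndarray

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        self.peak_times = np.asarray(self.peak_times, dtype=np.float64)

    @property
    def mean_hr_bpm(self) -> float:
        return 60.0 / float(self.intervals.mean())


@dataclass
class HRResult:
    hr_bpm: float
    method: str = "spectral"

    def __post_init__(self):
        if not 36.0 <= self.hr_bpm <= 252.0:
            raise ValueError(f"HR {self.hr_bpm:.1f} bpm outside plausible range")


@dataclass
class HRVResult:
    lf_nu: float
    hf_nu: float
    lf_hf_ratio: float


def hr_from_bvp(bvp: BVPSignal, band: tuple[float, float] = HR_BAND,
                nfft: int = 8192) -> HRResult:
    """HR as 60x the peak frequency of the Welch spectrum within ``band``.

    The spectrum is zero-padded (``nfft``) so the peak location is resolved
    well below the raw spectral bin width of a 15 s window.
    """
    x = np.asarray(bvp.values, dtype=np.float64)
    if len(x) < 256:
        raise ValueError("need at least 256 samples for spectral HR")
    nperseg = min(len(x), 512)
    freqs, pxx = sps.welch(x - x.mean(), fs=bvp.fps, nperseg=nperseg,
                           nfft=max(nfft, nperseg))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(pxx[in_band] > 0):
        raise ValueError("spectrum has no power in the HR band")
    peak_freq = freqs[in_band][np.argmax(pxx[in_band])]
    return HRResult(hr_bpm=60.0 * float(peak_freq), method="spectral")


def hr_from_peaks(ibi: "IBISeries") -> HRResult:
    """Alternative HR estimate: 60 / mean inter-beat interval."""
    return HRResult(hr_bpm=ibi.mean_hr_bpm, method="peak")


def detect_peaks(bvp: BVPSignal, bandpass: bool = True) -> IBISeries:
    """Systolic peaks -> gated inter-beat intervals.

    The waveform is band-passed to the HR band, peaks are required to be at
    least 0.25 s apart with prominence above 0.3x the signal's standard
    deviation, and intervals outside [0.25, 2.0] s are dropped (logged).
    """
    x = np.asarray(bvp.values, dtype=np.float64)
    if np.std(x) == 0:
        raise ValueError("flat signal: no peaks")
    if bandpass:
        nyq = bvp.fps / 2.0
        sos = sps.butter(3, [HR_BAND[0] / nyq, min(HR_BAND[1] / nyq, 0.99)],
                         btype="band", output="sos")
        x = sps.sosfiltfilt(sos, x)
    min_dist = max(1, int(round(IBI_GATE[0] * bvp.fps)))
    peaks, _ = sps.find_peaks(x, distance=min_dist,
                              prominence=0.3 * np.std(x))
    if len(peaks) < 3:
        raise ValueError(f"only {len(peaks)} peak(s) found; need >= 3")
    times = peaks / bvp.fps
    intervals = np.diff(times)
    keep = (intervals >= IBI_GATE[0]) & (intervals <= IBI_GATE[1])
    if not keep.all():
        logger.warning("detect_peaks: dropped %d non-physiological "
                       "interval(s)", int((~keep).sum()))
    return IBISeries(intervals=intervals[keep], peak_times=times)


def hrv_lf_hf(ibi: IBISeries, tachogram_fs: float = 4.0) -> HRVResult:
    """LF/HF power of the tachogram in normalized units.

    The inter-beat series is interpolated to a uniform ``tachogram_fs``
    grid (cubic when enough beats, else linear), linearly detrended, and its
    Welch spectrum integrated over the LF and HF bands;
    ``lf_nu = LF / (LF + HF)`` and symmetrically for HF, so the two
    normalized powers sum to one by construction.
    """
    if len(ibi.intervals) < 2:
        raise ValueError("need at least 2 inter-beat intervals")
    # interval i spans (t_i, t_{i+1}]; anchor it at its end time
    t = ibi.peak_times[1:1 + len(ibi.intervals)]
    if t[-1] - t[0] < 10.0:
        raise ValueError("need inter-beat intervals spanning >= 10 s")
    kind = "cubic" if len(ibi.intervals) >= 4 else "linear"
    f = interp1d(t, ibi.intervals, kind=kind, fill_value="extrapolate")
    grid = np.arange(t[0], t[-1], 1.0 / tachogram_fs)
    tach = sps.detrend(f(grid), type="linear")
    nperseg = len(tach)  # single segment: best LF resolution on short windows
    freqs, pxx = sps.welch(tach, fs=tachogram_fs, nperseg=nperseg,
                           nfft=max(4096, nperseg))
    df = freqs[1] - freqs[0]
    lf = float(pxx[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])].sum() * df)
    hf = float(pxx[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])].sum() * df)
    if lf + hf == 0:
        raise ValueError("no spectral power in the LF+HF bands")
    return HRVResult(lf_nu=lf / (lf + hf), hf_nu=hf / (lf + hf),
                     lf_hf_ratio=lf / hf if hf > 0 else np.inf)


def error_metrics(pred, truth) -> dict[str, float]:
    """MAE, RMSE, Std of the error (population), and Pearson's r."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need equal-length arrays of length >= 2")
    e = pred - truth
    mae = float(np.abs(e).mean())
    rmse = float(np.sqrt((e ** 2).mean()))
    std = float(e.std())  # ddof=0
    if np.std(pred) == 0 or np.std(truth) == 0:
        warnings.warn("constant input: Pearson r undefined, reporting NaN")
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, truth)[0, 1])
    return {"MAE": mae, "RMSE": rmse, "Std": std, "r": r}
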