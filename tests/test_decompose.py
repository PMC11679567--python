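"""Multi-band DCT decomposition against a brute-force matrix oracle."""

import numpy as np
import pytest
from scipy.fft import dct as scipy_dct

from mffnet.decompose import (BandSpec, DEFAULT_BANDS, band_mask,
                              band_slice_zero_pad, dct_ortho,
                              decompose_multiband, idct_ortho)
from mffnet.stmap import SpatioTemporalMap


def brute_force_band_filter(x: np.ndarray, fps: float,
                            band: tuple[float, float]) -> np.ndarray:
    """Oracle: full T x T DCT matrix, zero masked rows, invert."""
    T = len(x)
    D = scipy_dct(np.eye(T), type=2, norm="ortho", axis=0)  # coeffs = D @ x
    mask = band_mask(T, fps, band).astype(float)
    return D.T @ (np.diag(mask) @ (D @ x))


def test_roundtrip_and_parseval(rng):
    x = rng.standard_normal(450)
    spec = dct_ortho(x, fps=30.0)
    np.testing.assert_allclose(idct_ortho(spec), x, atol=1e-10)
    assert abs(np.linalg.norm(spec.coeffs) - np.linalg.norm(x)) < 1e-10


def test_constant_vector_energy_in_dc():
    spec = dct_ortho(np.ones(64), fps=30.0)
    assert abs(spec.coeffs[0] - 8.0) < 1e-12   # sqrt(64) * 1
    assert np.all(np.abs(spec.coeffs[1:]) < 1e-12)


def test_zero_trace_zero_spectrum():
    assert np.all(dct_ortho(np.zeros(450)).coeffs == 0)


def test_full_band_identity(rng):
    x = rng.standard_normal(128)
    spec = dct_ortho(x, fps=30.0)
    out = band_slice_zero_pad(spec, (0.0, 15.0))
    # bin at exactly Nyquist does not exist for DCT-II; all bins kept
    np.testing.assert_allclose(out.coeffs, spec.coeffs)


def test_empty_band_is_hard_error():
    spec = dct_ortho(np.ones(16), fps=30.0)
    # at T=16, fps=30 the bin spacing is 0.9375 Hz; (0.1, 0.2) is between bins
    with pytest.raises(ValueError, match=r"\[0.1, 0.2\)"):
        band_slice_zero_pad(spec, (0.1, 0.2))


def test_cosine_band_pass_and_stop():
    """A bin-aligned 1.2 Hz cosine passes its band exactly and is fully
    rejected by a disjoint band.

    DCT-II basis functions carry a half-sample phase offset, so the tone is
    synthesized as cos(2 pi f (n + 1/2) / fps) to sit on a single bin.
    """
    fps, T = 30.0, 450
    t = (np.arange(T) + 0.5) / fps
    x = np.cos(2 * np.pi * 1.2 * t)
    passed = idct_ortho(band_slice_zero_pad(dct_ortho(x, fps), (0.7, 2.0)))
    stopped = idct_ortho(band_slice_zero_pad(dct_ortho(x, fps), (2.0, 4.0)))
    assert np.linalg.norm(passed - x) / np.linalg.norm(x) < 1e-6
    assert np.linalg.norm(stopped) / np.linalg.norm(x) < 1e-6


@pytest.mark.parametrize("T", [16, 33, 64])
def test_matches_brute_force_oracle(T, rng):
    """Exact equivalence with the DCT-matrix-mask oracle for small T."""
    fps = 30.0
    values = rng.standard_normal((T, 2, 3))
    stmap = SpatioTemporalMap(values, fps=fps, normalized=True)
    bands = BandSpec(fps=fps)
    stack = decompose_multiband(stmap, bands)
    for k, band in enumerate(bands.bands):
        for i in range(2):
            for c in range(3):
                expected = brute_force_band_filter(values[:, i, c], fps, band)
                np.testing.assert_allclose(stack.values[k, :, i, c],
                                           expected, atol=1e-9)


def test_band_limited_invariant(rng):
    stmap = SpatioTemporalMap(rng.standard_normal((450, 4, 3)), fps=30.0,
                              normalized=True)
    bands = BandSpec(fps=30.0)
    stack = decompose_multiband(stmap, bands)
    for k, band in enumerate(bands.bands):
        mask = band_mask(450, 30.0, band)
        coeffs = scipy_dct(stack.values[k], type=2, norm="ortho", axis=0)
        total = (coeffs ** 2).sum()
        outside = (coeffs[~mask] ** 2).sum()
        assert outside < 1e-9 * total


def test_two_tone_separation():
    fps, T = 30.0, 450
    t = (np.arange(T) + 0.5) / fps   # bin-aligned (see above)
    tone1 = np.cos(2 * np.pi * 1.0 * t)
    tone2 = 0.5 * np.cos(2 * np.pi * 3.0 * t)
    values = np.zeros((T, 1, 3))
    values[:, 0, 0] = tone1 + tone2
    stmap = SpatioTemporalMap(values, fps=fps, normalized=True)
    bands = BandSpec(bands=((0.7, 2.0), (2.0, 4.17)), fps=fps)
    stack = decompose_multiband(stmap, bands)
    r1 = np.linalg.norm(stack.values[0, :, 0, 0] - tone1)
    r2 = np.linalg.norm(stack.values[1, :, 0, 0] - tone2)
    assert r1 / np.linalg.norm(tone1) < 1e-6
    assert r2 / np.linalg.norm(tone2) < 1e-6


def test_linearity_and_band_additivity(rng):
    fps = 30.0
    a, b = 1.7, -0.4
    x = SpatioTemporalMap(rng.standard_normal((64, 2, 3)), fps=fps,
                          normalized=True)
    y = SpatioTemporalMap(rng.standard_normal((64, 2, 3)), fps=fps,
                          normalized=True)
    combo = SpatioTemporalMap(a * x.values + b * y.values, fps=fps,
                              normalized=True)
    bands = BandSpec(fps=fps)
    lhs = decompose_multiband(combo, bands).values
    rhs = (a * decompose_multiband(x, bands).values
           + b * decompose_multiband(y, bands).values)
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)
    # sum over bands equals IDCT of the union-masked spectrum
    stack = decompose_multiband(x, bands)
    union = np.zeros(64, dtype=bool)
    for band in bands.bands:
        union |= band_mask(64, fps, band)
    coeffs = scipy_dct(x.values, type=2, norm="ortho", axis=0)
    from scipy.fft import idct as scipy_idct
    expected = scipy_idct(coeffs * union[:, None, None], type=2,
                          norm="ortho", axis=0)
    np.testing.assert_allclose(stack.values.sum(axis=0), expected, atol=1e-9)


def test_zero_map_zero_stack():
    stmap = SpatioTemporalMap(np.zeros((64, 2, 3)), fps=30.0, normalized=True)
    assert np.all(decompose_multiband(stmap).values == 0)


def test_bandspec_validation():
    with pytest.raises(ValueError):
        BandSpec(bands=((1.0, 0.5),), fps=30.0)          # reversed
    with pytest.raises(ValueError):
        BandSpec(bands=((0.5, 1.5), (1.0, 2.0)), fps=30.0)  # overlap
    with pytest.raises(ValueError):
        BandSpec(bands=((0.5, 16.0),), fps=30.0)         # above Nyquist
    assert BandSpec(bands=DEFAULT_BANDS, fps=30.0).n_bands == 3
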