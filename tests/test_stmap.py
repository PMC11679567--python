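"""Preprocessing: modified-YUV transform, TDN normalization, noise."""

import numpy as np
import pytest

from mffnet.stmap import (PreprocessConfig, RGBRegionSeries,
                          SpatioTemporalMap, inject_white_noise, preprocess,
                          rgb_to_modified_yuv, temporal_normalize,
                          video_to_region_series)


def _series_from_rgb(rgb):
    """Two identical frames of one region holding a single RGB triple."""
    values = np.tile(np.asarray(rgb, dtype=float), (2, 1, 1))
    return RGBRegionSeries(values=values, fps=30.0)


@pytest.mark.parametrize("rgb,expected_yuv", [
    ((1, 0, 0), (0.299, -0.169, 0.5)),       # first matrix column
    ((0, 0, 0), (0.0, 0.0, 0.0)),
    ((255, 255, 255), (255.0, 0.0, 0.0)),    # row sums (1, 0, 0)
])
def test_modified_yuv_fixtures(rgb, expected_yuv):
    out = rgb_to_modified_yuv(_series_from_rgb(rgb))
    np.testing.assert_allclose(out.values[0, 0], expected_yuv, atol=1e-12)


def test_modified_yuv_exactly_linear(rng):
    x = RGBRegionSeries(rng.standard_normal((20, 4, 3)), fps=30.0)
    y = RGBRegionSeries(rng.standard_normal((20, 4, 3)), fps=30.0)
    a, b = 2.5, -1.25
    combo = RGBRegionSeries(a * x.values + b * y.values, fps=30.0)
    lhs = rgb_to_modified_yuv(combo).values
    rhs = (a * rgb_to_modified_yuv(x).values
           + b * rgb_to_modified_yuv(y).values)
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_non_finite_input_rejected():
    values = np.ones((5, 2, 3))
    values[2, 1, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        RGBRegionSeries(values=values, fps=30.0)


def test_tdn_zscore_closed_form():
    values = np.zeros((3, 1, 3))
    values[:, 0, 0] = [1.0, 2.0, 3.0]
    values[:, 0, 1] = [5.0, 5.0, 5.0]        # constant: degenerate rule
    values[:, 0, 2] = [0.0, 1.0, -1.0]
    out = temporal_normalize(SpatioTemporalMap(values, fps=30.0))
    np.testing.assert_allclose(out.values[:, 0, 0],
                               [-1.2247448, 0.0, 1.2247448], atol=1e-6)
    np.testing.assert_array_equal(out.values[:, 0, 1], 0.0)
    assert out.normalized


def test_tdn_mean_zero_unit_var_and_idempotent(rng):
    stmap = SpatioTemporalMap(rng.standard_normal((450, 4, 3)) * 7 + 3,
                              fps=30.0)
    out = temporal_normalize(stmap)
    np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-6)
    np.testing.assert_allclose(out.values.var(axis=0), 1.0, atol=1e-6)
    again = temporal_normalize(out)
    np.testing.assert_allclose(again.values, out.values, atol=1e-6)


def test_tdn_sliding_window(rng):
    stmap = SpatioTemporalMap(rng.standard_normal((64, 1, 3)), fps=30.0)
    out = temporal_normalize(stmap, PreprocessConfig(tdn_window=16))
    for start in range(0, 64, 16):
        seg = out.values[start:start + 16, 0, 0]
        assert abs(seg.mean()) < 1e-9 and abs(seg.var() - 1) < 1e-9


def test_noise_disabled_sentinel(rng):
    stmap = temporal_normalize(
        SpatioTemporalMap(rng.standard_normal((100, 2, 3)), fps=30.0))
    out = inject_white_noise(stmap, PreprocessConfig(noise_snr_db=np.inf))
    np.testing.assert_array_equal(out.values, stmap.values)


def test_noise_snr_calibration_and_determinism(rng):
    stmap = temporal_normalize(
        SpatioTemporalMap(rng.standard_normal((450, 4, 3)), fps=30.0))
    cfg = PreprocessConfig(noise_snr_db=0.0, rng_seed=42)
    out1 = inject_white_noise(stmap, cfg)
    out2 = inject_white_noise(stmap, cfg)
    np.testing.assert_array_equal(out1.values, out2.values)
    added = out1.values - stmap.values
    # at 0 dB the added noise variance matches the unit trace variance
    assert np.all(np.abs(added.var(axis=0) - 1.0) < 0.25)
    assert abs(added.var() - 1.0) < 0.1


def test_pipeline_preserves_shape(rgb_series):
    out = preprocess(rgb_series, PreprocessConfig(noise_snr_db=10.0),
                     augment=True)
    assert out.values.shape == rgb_series.values.shape == (450, 4, 3)


# -- optional video front-end -------------------------------------------------

def _box_backend(frame):
    """Fixed-box stand-in for a landmark detector: 4 quadrant masks."""
    h, w, _ = frame.shape
    masks = []
    for (r0, r1, c0, c1) in [(0, h // 2, 0, w // 2), (0, h // 2, w // 2, w),
                             (h // 2, h, 0, w // 2), (h // 2, h, w // 2, w)]:
        m = np.zeros((h, w), dtype=bool)
        m[r0:r1, c0:c1] = True
        masks.append(m)
    return masks


def test_video_uniform_color():
    frames = [np.full((8, 8, 3), 37.0) for _ in range(10)]
    series = video_to_region_series(frames, fps=30.0,
                                    landmark_backend=_box_backend)
    assert series.values.shape == (10, 4, 3)
    np.testing.assert_array_equal(series.values, 37.0)


def test_video_detection_dropout_carries_forward():
    frames = [np.full((8, 8, 3), float(i)) for i in range(5)]

    def flaky(frame):
        return None if frame[0, 0, 0] == 2.0 else _box_backend(frame)

    series = video_to_region_series(frames, fps=30.0, landmark_backend=flaky)
    np.testing.assert_array_equal(series.values[:, 0, 0],
                                  [0.0, 1.0, 1.0, 3.0, 4.0])


def test_video_no_face_is_hard_error():
    frames = [np.zeros((4, 4, 3))] * 3
    with pytest.raises(RuntimeError, match="no face"):
        video_to_region_series(frames, fps=30.0,
                               landmark_backend=lambda f: None)
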