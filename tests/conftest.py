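import numpy as np
import pytest

from mffnet.stmap import RGBRegionSeries
from mffnet.synth import SynthConfig, gen_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rgb_series(rng) -> RGBRegionSeries:
    """Random but finite region series at the nominal 450 x 4 x 3 shape."""
    values = 100.0 + 10.0 * rng.standard_normal((450, 4, 3))
    return RGBRegionSeries(values=values, fps=30.0)


@pytest.fixture
def clean_sample():
    """A noiseless synthetic sample: no drift, artifacts or sensor noise."""
    cfg = SynthConfig(snr_db=np.inf, drift_amp=0.0, artifact_rate=0.0,
                      seed=7)
    return gen_sample(cfg, 0), cfg
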