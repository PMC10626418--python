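import numpy as np
import pandas as pd
import pytest

from memnano import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def csr_map():
    """A CSR localization map with blinking in a 3 x 3 um ROI."""
    blinks = synth.BlinkStatistics.default()
    pat = synth.gen_point_pattern(100.0, (3000.0, 3000.0), seed=1000)
    loc = synth.gen_localizations(pat, blinks, (51.0, 12.0), seed=2000)
    return pat, loc, blinks


@pytest.fixture
def clustered_map():
    """A strongly clustered localization map (60 nm disks, 80% clustered)."""
    blinks = synth.BlinkStatistics.default()
    spec = synth.ClusterSpec(60.0, 0.8, 10.0)
    pat = synth.gen_point_pattern(100.0, (3000.0, 3000.0), spec, seed=201)
    loc = synth.gen_localizations(pat, blinks, (51.0, 12.0), seed=202)
    return pat, loc, blinks


def make_localization_df(x, y, frame=None, sigma=150.0, unc=20.0):
    x = np.asarray(x, float)
    n = len(x)
    return pd.DataFrame(
        {
            "frame": np.ones(n, int) if frame is None else np.asarray(frame, int),
            "x_nm": x,
            "y_nm": np.asarray(y, float),
            "sigma_nm": np.full(n, sigma),
            "uncertainty_nm": np.full(n, unc),
            "intensity": np.full(n, 1000.0),
        }
    )
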