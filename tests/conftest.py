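import numpy as np
import pandas as pd
import pytest

from fractalhrv import RRSeries, builtin_scenarios


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iid_series(rng):
    """A stationary, uncorrelated RR series (mean 800 ms, sd 30 ms, 1000 beats)."""
    return RRSeries(rr=800.0 + 30.0 * rng.standard_normal(1000))


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


def make_alpha_frame(t_end, alpha, hr=None, power=None, valid=True):
    """Assemble a rolling-alpha1 frame by hand for threshold-module tests."""
    t_end = np.asarray(t_end, dtype=float)
    n = t_end.size
    return pd.DataFrame(
        {
            "t_end": t_end,
            "alpha1": np.asarray(alpha, dtype=float),
            "hr": np.full(n, np.nan) if hr is None else np.asarray(hr, dtype=float),
            "power": np.full(n, np.nan) if power is None else np.asarray(power, dtype=float),
            "artifact_pct": 0.0,
            "n_beats": 150,
            "valid": np.full(n, True) if valid is True else np.asarray(valid, dtype=bool),
        }
    )
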