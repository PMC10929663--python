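import numpy as np
import pandas as pd
import pytest

from occuadjust import PopulationFrame, SyntheticConfig, simulate_frame


def make_frame(y, R, elevation=None, protected=None, p_true=None, period=1):
    """Hand-built single-period frame for exact small-sample oracles."""
    y = np.asarray(y)
    R = np.asarray(R)
    N = len(y)
    data = pd.DataFrame(
        {
            "unit_id": [f"u{i}" for i in range(N)],
            "elevation": elevation if elevation is not None else np.arange(N, dtype=float),
            "protected_prop": protected if protected is not None else np.zeros(N),
            f"y_{period}": y,
            f"R_{period}": R,
        }
    )
    if p_true is not None:
        data[f"p_true_{period}"] = p_true
    return PopulationFrame(data=data, periods=(period,))


@pytest.fixture(scope="session")
def default_frame():
    """Mid-sized frame under the default (MAR, biased-sample) conditions."""
    return simulate_frame(SyntheticConfig(N=8000, seed=101))


@pytest.fixture(scope="session")
def small_frame():
    """Small frame for brute-force oracle equivalences."""
    return simulate_frame(SyntheticConfig(N=200, seed=7))


@pytest.fixture(scope="session")
def mar_violating_frame():
    """Occupancy feeds inclusion directly: the MAR assumption fails."""
    return simulate_frame(SyntheticConfig(N=4000, seed=55, gamma_y=-1.5))
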