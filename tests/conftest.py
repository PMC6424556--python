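import numpy as np
import pytest

import seizurescope as sz


@pytest.fixture(scope="session")
def sim_cfg() -> sz.SimConfig:
    """Default study conditions: 5-min epochs at 20 Hz."""
    return sz.SimConfig()


@pytest.fixture(scope="session")
def ptz_dataset(sim_cfg):
    """One PTZ-like simulated dataset shared across read-only tests."""
    traces, gt = sz.simulate_region_traces(sim_cfg, "ptz", seed=7)
    return traces, gt


@pytest.fixture(scope="session")
def ptz_dff(ptz_dataset):
    traces, gt = ptz_dataset
    return sz.compute_dff(traces), gt


def dff_oracle(x: np.ndarray, window: int, fraction: float) -> np.ndarray:
    """Brute-force dF/F oracle: re-sort every causal window independently."""
    import math

    n = len(x)
    out = np.empty(n)
    for t in range(n):
        lo = max(0, t - window + 1)
        win = np.sort(x[lo : t + 1])
        k = math.ceil(fraction * len(win))
        b = np.mean(win[:k])
        out[t] = (x[t] - b) / b
    return out
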