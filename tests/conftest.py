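import numpy as np
import pandas as pd
import pytest

import myxospt as m


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_simulation():
    """A small rendered population movie shared by localization/track tests."""
    cfg = m.PipelineConfig(seed=77)
    cfg.simulate.n_tracks = 120
    sim_rng = np.random.default_rng(cfg.seed)
    sim = m.simulate_population(cfg.simulate, sim_rng, render=True)
    return cfg, sim


@pytest.fixture
def straight_cell():
    return m.make_cell(6.0, 0.7, 0.0, (4.0, 2.0), id=1)


def brute_force_msd(xy_nm: np.ndarray) -> np.ndarray:
    """O(T²) oracle: mean squared displacement over all ordered pairs."""
    t = len(xy_nm)
    out = []
    for k in range(1, t):
        acc = []
        for i in range(t - k):
            d = xy_nm[i + k] - xy_nm[i]
            acc.append(d[0] ** 2 + d[1] ** 2)
        out.append((k, float(np.mean(acc)) / 1e6))
    return np.asarray(out)


def random_track(rng, n=None, scale_nm=200.0):
    n = n or int(rng.integers(4, 13))
    return rng.normal(0.0, scale_nm, size=(n, 2))
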