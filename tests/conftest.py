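import numpy as np
import pandas as pd
import pytest

from rulexgaze.environment import Environment
from rulexgaze.gaze import build_aois
from rulexgaze.model import ModelParams


@pytest.fixture(scope="session")
def env():
    return Environment.multiplicative()


@pytest.fixture(scope="session")
def aois(env):
    return build_aois(env)


@pytest.fixture
def params():
    """A mid-mixture parameter set with cue weights near the least-squares
    values for the default exemplars."""
    return ModelParams(alpha=0.5, beta0=-9.0, beta1=5.0, beta2=3.0, sigma=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_judgments(env, params, n_blocks, rng):
    """Small judgment table drawn from the model itself (test helper)."""
    from rulexgaze.environment import full_grid

    rows = []
    trial = 0
    for block in range(1, n_blocks + 1):
        for s in full_grid():
            trial += 1
            rows.append((block, trial, s.x1, s.x2))
    df = pd.DataFrame(rows, columns=["block", "trial", "x1", "x2"])
    from rulexgaze.model import mixture_prediction

    mu = np.array(
        [
            mixture_prediction((a, b), env, params).c_mix
            for a, b in zip(df["x1"], df["x2"])
        ]
    )
    df["response"] = np.clip(
        np.rint(rng.normal(mu, params.sigma)), env.scale_min, env.scale_max
    )
    df["participant"] = 1
    return df
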