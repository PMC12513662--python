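import numpy as np
import pandas as pd
import pytest

from flydemog import synth


@pytest.fixture(scope="session")
def small_study():
    """One stochastic factorial study at reduced cage size."""
    configs = synth.default_configs(n_flies=40)
    deaths, eggs, truth = synth.simulate_study(configs, n_cages=2, seed=7)
    return deaths, eggs, truth, configs


@pytest.fixture(scope="session")
def noiseless_study():
    """Exact expected censuses from the generating model."""
    configs = synth.default_configs(n_flies=40)
    deaths, eggs, truth = synth.noiseless_study(configs, n_cages=2)
    return deaths, eggs, truth, configs


def deaths_frame(days, dead=None, censored=None, sex="female", cage="c1",
                 regime="HH"):
    """Small helper to build census rows from parallel lists."""
    n = len(days)
    return pd.DataFrame({
        "cage_id": [cage] * n, "regime": [regime] * n, "sex": [sex] * n,
        "day": days,
        "n_dead": dead if dead is not None else [1] * n,
        "n_censored": censored if censored is not None else [0] * n,
    })


def eggs_frame(days, eggs, cage="c1", regime="HH"):
    return pd.DataFrame({
        "cage_id": [cage] * len(days), "regime": [regime] * len(days),
        "day": days, "eggs": eggs,
    })
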