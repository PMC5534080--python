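import numpy as np
import pandas as pd
import pytest

import survforest as sf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def registry():
    return sf.builtin_designs()


@pytest.fixture(scope="session")
def binary_data2(registry):
    """Simulated binary-covariate dataset: n=100, ~50% censoring, decreasing hazard."""
    return sf.gen_dataset(registry["binary_2"], seed=20)


@pytest.fixture(scope="session")
def poly_small(registry):
    """Small polytomous dataset (n=100) for categorical-split exercises."""
    from dataclasses import replace

    design = replace(registry["poly_3"], n=100)
    return sf.gen_dataset(design, seed=21)


def make_dataset(time, event, cov_dict, kinds=None):
    cov = {}
    for name, vals in cov_dict.items():
        if isinstance(vals[0], str):
            cov[name] = pd.Categorical(vals)
        else:
            cov[name] = np.asarray(vals)
    return sf.SurvivalDataset(
        np.asarray(time, dtype=float),
        np.asarray(event, dtype=int),
        pd.DataFrame(cov),
        kinds or {},
    )


@pytest.fixture
def ten_subject_fixture():
    """A binary covariate perfectly separating early deaths from late censorings."""
    time = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
    event = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    x_signal = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    x_noise = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
    return make_dataset(
        time, event, {"signal": x_signal, "noise": x_noise},
        kinds={"signal": "binary", "noise": "binary"},
    )


def random_censored_data(rng, n=60, cens_rate=1.0):
    t_ev = rng.exponential(1.0, n)
    t_c = rng.exponential(cens_rate, n)
    time = np.minimum(t_ev, t_c)
    event = (t_ev <= t_c).astype(int)
    return time, event
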