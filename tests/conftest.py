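import numpy as np
import pandas as pd
import pytest

import idarcyto as ic


@pytest.fixture(scope="session")
def calib():
    return ic.default_calibration()


@pytest.fixture(scope="session")
def tree():
    return ic.build_default_gate_tree()


@pytest.fixture(scope="session")
def healthy_sample(calib):
    return ic.sample_subject("HEALTHY", calib, seed=1)


@pytest.fixture(scope="session")
def healthy_pops(healthy_sample, tree):
    adj = ic.auto_adjust_gates(healthy_sample.events, tree)
    return ic.apply_gate_tree(healthy_sample.events, adj)


def make_toy_table(n=60, informative_shift=3.0, seed=0):
    """Two-feature toy: A separates the classes, B is noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    table = pd.DataFrame({
        "A": rng.normal(y * informative_shift, 1.0),
        "B": rng.normal(0.0, 1.0, n),
    })
    subjects = np.array([f"S{i}" for i in range(n)])
    return table, y, subjects


@pytest.fixture(scope="session")
def toy():
    return make_toy_table()


@pytest.fixture(scope="session")
def toy_model(toy):
    table, y, subjects = toy
    cfg = ic.TrainConfig(n_bootstrap=8, n_estimators=60, seed=3)
    return ic.fit_idar(table, y, cfg, subjects=subjects)


FAST_TRAIN = dict(n_bootstrap=2, n_estimators=25, seed=1)
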