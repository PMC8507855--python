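import numpy as np
import pytest

import gapfill as gf
from gapfill.recurrent import TrainConfig, train_bilstm_i


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_machine_series():
    """Six simulated days of half-hourly machine observations."""
    _, machine = gf.simulate_temperature(gf.WeatherConfig(n_days=6, seed=1))
    return machine


@pytest.fixture(scope="session")
def toy_windows(tiny_machine_series):
    """A single w=6 (m=2, s=2) training window cut from the tiny series."""
    seg = gf.segment_days(tiny_machine_series)
    gap = gf.GapSpec(gap_start_day=2, m=2, s=2)
    return gf.make_windows(seg, gap, stride=1)


@pytest.fixture(scope="session")
def overfit_bilstm(toy_windows):
    """BiLSTM-I driven to convergence on the single toy window."""
    cfg = TrainConfig(hidden=16, dec_hidden=16, max_epochs=400, patience=400,
                      lr=5e-3, val_frac=0.0)
    return train_bilstm_i(toy_windows, cfg, seed=0)
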