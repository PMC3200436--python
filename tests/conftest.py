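import numpy as np
import pandas as pd
import pytest

from axiomerf.containers import EpochedData
from axiomerf.design import build_session_design
from axiomerf.layout import meg_cap_layout


@pytest.fixture(scope="session")
def small_layout():
    return meg_cap_layout(n_channels=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(
    data: np.ndarray, fs: float = 200.0, layout=None, tmin_ms: float = -160.0
) -> EpochedData:
    """Wrap a raw array in an EpochedData with minimal trial metadata."""
    n_tr, n_ch, n_t = data.shape
    if layout is None:
        layout = meg_cap_layout(n_channels=n_ch)
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_tr),
            "block": 1,
            "target_win_prob": 0.5,
            "outcome_valence": ["win", "loss"] * (n_tr // 2)
            + ["win"] * (n_tr % 2),
            "outcome_prob": 0.5,
            "outcome_amount": 1.0,
            "outcome_onset_ms": 0.0,
        }
    )
    time_ms = tmin_ms + np.arange(n_t) * 1000.0 / fs
    return EpochedData(
        data=data, fs=fs, time_ms=time_ms, trials=trials, layout=layout
    )


@pytest.fixture(scope="session")
def tiny_design():
    return build_session_design(
        {0.0: 4, 0.25: 16, 0.5: 8, 0.75: 16, 1.0: 4}, n_blocks=1, seed=7
    )
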