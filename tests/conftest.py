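import numpy as np
import pandas as pd
import pytest

from foragekit import BanditConfig, SessionLog, WSLSParams, simulate_session


@pytest.fixture(scope="session")
def bandit_session():
    """A 300-trial deterministic-bandit WSLS session at study parameters."""
    return simulate_session(
        WSLSParams(w=0.8, l=0.5, lapse=0.25), BanditConfig(1.0, 0.0),
        n_trials=300, seed=7,
    )


@pytest.fixture
def tiny_log():
    """Three-event log: one rewarded left poke, transcribed by hand."""
    ev = pd.DataFrame(
        {
            "time_s": [1.0, 1.2, 4.0],
            "event": ["poke_left", "pellet", "retrieval"],
            "active_side": ["left", "left", "left"],
            "block_index": [0, 0, 0],
        }
    )
    return SessionLog("m1", "F", "fr1", 1, ev)


def trials_frame(choices, outcomes):
    """Hand-built trial table for metric oracles."""
    return pd.DataFrame(
        {
            "index": np.arange(len(choices)),
            "choice": list(choices),
            "outcome": list(outcomes),
            "correct_side": ["left"] * len(choices),
            "poke_time_s": np.nan,
            "retrieval_time_s": np.nan,
        }
    )
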