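import numpy as np
import pytest

from sleepkit.core import Hypnogram
from sleepkit.synthetic import SimConfig, simulate_eeg_emg, simulate_hypnogram


@pytest.fixture(scope="session")
def short_session():
    """One 40-minute synthetic session with all three states present."""
    seed = 3
    while True:
        cfg = SimConfig(seed=seed, duration_s=2400.0)
        h, truth = simulate_hypnogram(cfg)
        if all((h.states == s).any() for s in "WNR"):
            break
        seed += 1
    rec = simulate_eeg_emg(cfg, truth)
    return {"cfg": cfg, "hypnogram": h, "truth": truth, "recording": rec}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_hypnogram(codes: str, epoch_s: float = 2.5) -> Hypnogram:
    return Hypnogram(states=np.array(list(codes.replace(" ", "")), dtype="U1"),
                     epoch_s=epoch_s)
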