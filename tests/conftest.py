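import numpy as np
import pandas as pd
import pytest

from lambwatch import SimConfig, compute_metrics, fit_hmm, label_states, simulate_herd


@pytest.fixture(scope="session")
def small_herd():
    """Four parturient + two non-parturient ewe-seasons with ground truth."""
    return simulate_herd(4, 2, seed=7)


@pytest.fixture(scope="session")
def small_metrics(small_herd):
    trajs, _ = small_herd
    return {a: compute_metrics(t) for a, t in trajs.items()}


@pytest.fixture(scope="session")
def small_model(small_metrics):
    """Labelled 3-state model fitted to the parturient animals of the small herd."""
    train = [m for a, m in small_metrics.items() if a.startswith("P")]
    return label_states(fit_hmm(train, n_restarts=3, seed=1))


def make_states(labels, start="2022-05-15", freq_h=2.0, animal_id="X"):
    """Build a decoded-states frame from a label sequence at a uniform fix rate."""
    t = pd.date_range(start, periods=len(labels), freq=pd.Timedelta(hours=freq_h), tz="UTC")
    return pd.DataFrame({"animal_id": animal_id, "timestamp": t, "label": list(labels)})


@pytest.fixture
def rng():
    return np.random.default_rng(20220515)
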