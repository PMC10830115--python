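import warnings

import numpy as np
import pytest

import navmanifold as nm

warnings.filterwarnings("ignore", message=".*disconnected.*")


@pytest.fixture(scope="session")
def sub_session():
    """SUB-like T-maze session reused across tests (30 units, 400 s)."""
    session, model, truth, _ = nm.make_session(
        "SUBlike", "tmaze", n_units=30, seed=5, duration_s=400
    )
    binned = nm.bin_activity(session.spikes, (0.0, session.t_end))
    behavior = nm.derive_behavior(session.position, session.trials, binned.edges)
    return {"session": session, "model": model, "truth": truth,
            "binned": binned, "behavior": behavior}


@pytest.fixture(scope="session")
def ca1_session():
    session, model, truth, _ = nm.make_session(
        "CA1like", "tmaze", n_units=30, seed=5, duration_s=400
    )
    binned = nm.bin_activity(session.spikes, (0.0, session.t_end))
    behavior = nm.derive_behavior(session.position, session.trials, binned.edges)
    return {"session": session, "model": model, "truth": truth,
            "binned": binned, "behavior": behavior}


@pytest.fixture(scope="session")
def circle_cloud():
    rng = np.random.default_rng(1)
    th = rng.uniform(0, 2 * np.pi, 300)
    return np.c_[np.cos(th), np.sin(th)] + rng.normal(0, 0.02, (300, 2))
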