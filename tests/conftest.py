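import numpy as np
import pytest

import swdsleep as sw


@pytest.fixture(scope="session")
def sim_2h():
    """Clean 2-h simulated animal (no seizure events), shared across tests."""
    cfg = sw.SimConfig(duration_s=2 * 3600, seed=2, swd_rate_per_h=0.0)
    hyp = sw.generate_hypnogram(cfg)
    rec = sw.synthesize_signals(hyp, cfg)
    return cfg, hyp, rec


@pytest.fixture(scope="session")
def sim_30min_injected():
    """30-min simulation with 6 injected 7 Hz spike-wave events."""
    cfg = sw.SimConfig(duration_s=1800, seed=3)
    hyp = sw.generate_hypnogram(cfg)
    rec = sw.synthesize_signals(hyp, cfg)
    rec, events = sw.inject_swd_events(rec, hyp, cfg, n_events=6)
    return cfg, hyp, rec, events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
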