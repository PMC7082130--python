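import numpy as np
import pytest

from ovispindle import (
    SimConfig,
    accepted_events,
    annotate_simultaneity,
    detect_spindles,
    generate_background,
    generate_study,
)

# A two-cycle night excerpt (~30 min) with spindles confined to NREM: the
# shared recovery conditions for the heavier end-to-end tests.
STAGE_SEQ = (
    ("W", 60.0), ("S1", 180.0), ("S2", 600.0), ("R", 90.0),
    ("W", 40.0), ("S1", 180.0), ("S2", 600.0), ("R", 60.0),
)
NREM_ONLY_RATES = {
    "S2": 4.5, "U2": 4.5, "S1": 2.5, "U1": 2.5,
    "W": 0.0, "WU": 0.0, "R": 0.0,
}


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=2, stage_sequence=STAGE_SEQ,
                     spindle_rate_per_stage=dict(NREM_ONLY_RATES))


@pytest.fixture(scope="session")
def study(sim_config):
    """(recording, hypnogram, ground-truth events) for the shared study."""
    return generate_study(sim_config)


@pytest.fixture(scope="session")
def detections(study):
    rec, _, _ = study
    return detect_spindles(rec, rec)


@pytest.fixture(scope="session")
def accepted(detections):
    return accepted_events(detections)


@pytest.fixture(scope="session")
def catalog(accepted):
    return annotate_simultaneity(accepted)


@pytest.fixture(scope="session")
def quiet_background():
    """Single-channel spindle-free NREM background (120 s)."""
    cfg = SimConfig(seed=7, n_channels=1, stage_sequence=(("S1", 120.0),),
                    spindle_rate_per_stage={"S1": 0.0}, spike_rate=0.0)
    return cfg, generate_background(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
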