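import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    from stopover.synthetic import SimConfig

    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def cohort(default_config):
    """A study-sized synthetic cohort (14 redstarts, 21 robins)."""
    from stopover.synthetic import simulate_cohort

    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def recovery_run():
    """100 simulated departures at default noise, segmented and rated."""
    from stopover import synthetic, telemetry

    cfg = synthetic.SimConfig(n_birds_per_species={"CR": 50, "ER": 50}, seed=42)
    _, truth = synthetic.simulate_cohort(cfg)
    stream = synthetic.simulate_detections(truth, cfg)
    ants = synthetic.antenna_table(cfg)
    events = telemetry.process_stream(stream, ants)
    merged = events.merge(truth, on="tag_id", suffixes=("_est", "_true"))
    return cfg, merged
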