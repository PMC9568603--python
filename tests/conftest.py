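import numpy as np
import pytest

import beadcycle as bc
from beadcycle import pipeline, synthetic


@pytest.fixture(scope="session")
def defaults():
    return bc.assay_defaults()


@pytest.fixture(scope="session")
def dists(defaults):
    return synthetic.assay_distributions(defaults)


@pytest.fixture()
def trapped_config(defaults):
    return pipeline.default_trapped_config(0, defaults)


@pytest.fixture()
def weak_trap_config(defaults):
    """Soft trap used for calibration-style tests (slow, large fluctuations)."""
    return bc.SimulationConfig(
        trap=bc.TrapModel(0.05, 0.05, temperature=defaults["temperature_K"]),
        bead=bc.BeadGeometry(1.5), frame_rate=10.0, seed=0)


def brownian_traj(config, n_frames, seed):
    sched = bc.BehaviorSchedule.from_durations(
        [("brownian", n_frames / config.frame_rate)])
    traj, _ = synthetic.simulate_trapped_bead(
        config, sched, rng=np.random.default_rng(seed))
    return traj
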