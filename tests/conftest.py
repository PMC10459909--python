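import warnings

import numpy as np
import pytest

import imugait as ig

# the generator intentionally produces signals that trigger benign pipeline
# warnings (negative lengths on TUG return legs, skipped moving periods)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_profile():
    return ig.GaitProfile()


@pytest.fixture(scope="session")
def walk_session(default_profile):
    """One default-noise straight 7 m walk, simulated once per test session."""
    return ig.simulate_session(
        default_profile, ig.TaskScript.straight_walk(repeats=1), seed=11
    )


@pytest.fixture(scope="session")
def walk_result(walk_session):
    return ig.process_session(walk_session.recordings, walk_session.events, task="walk")


@pytest.fixture(scope="session")
def tug_session(default_profile):
    return ig.simulate_session(default_profile, ig.TaskScript.tug(repeats=3), seed=13)


@pytest.fixture(scope="session")
def tug_result(tug_session):
    return ig.process_session(tug_session.recordings, tug_session.events, task="tug")


def strike_recovery(sim, prep=None, tol=0.02):
    """Fraction of ground-truth heel strikes recovered within tol seconds."""
    if prep is None:
        prep = ig.prepare_session(sim.recordings, sim.events)
    mag = prep.heading["ankle"].magnitude()
    thr = ig.auto_threshold(mag, prep.rate)
    mask = ig.detect_foot_flat(prep.grid, mag, prep.rate, thr)
    det = ig.detect_heel_strikes(prep.grid, prep.heading["ankle"].ap, mask, prep.rate)
    gt = sim.truth.heel_strike_times
    hits = sum(np.min(np.abs(det - h)) <= tol for h in gt)
    return det, hits / len(gt)
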