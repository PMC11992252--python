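"""Shared fixtures: corridor geometry and synthetic sessions.

Expensive synthetic sessions are session-scoped so detection, decoding and
population tests reuse the same simulated data.
"""

import numpy as np
import pytest

from placecode import CorridorConfig, generate_dff, generate_population, generate_trajectory
from placecode.session import SessionData


@pytest.fixture(scope="session")
def corridor():
    return CorridorConfig()


def make_session(traj, dff, day=0, frame_rate_hz=30.0):
    return SessionData(
        dff=dff, position_cm=traj["position_cm"],
        velocity_cm_s=traj["velocity_cm_s"], lick_frames=traj["lick_frames"],
        reward_frames=traj["reward_frames"], trial_bounds=traj["trial_bounds"],
        day=day, frame_rate_hz=frame_rate_hz)


@pytest.fixture(scope="session")
def mixed_session(corridor):
    """20-trial expert session: 20 stable place cells + 20 non-coding cells."""
    traj = generate_trajectory(corridor, 20, "expert", seed=11)
    pop = generate_population(40, proportions=(0.5, 0.0, 0.5), seed=12)
    dff = generate_dff(pop, traj, corridor, seed=13)
    return make_session(traj, dff), pop


@pytest.fixture(scope="session")
def pc_session(corridor):
    """Expert session of 120 stable place cells for decoder tests."""
    traj = generate_trajectory(corridor, 10, "expert", seed=21)
    pop = generate_population(120, proportions=(1.0, 0.0, 0.0), seed=22)
    dff = generate_dff(pop, traj, corridor, seed=23)
    return make_session(traj, dff), pop
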