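"""Score task performance from licking: spatial information of the lick map.

Simulates an expert and a naive agent on the 400 cm corridor and prints the
spatial information (bits) of each lick histogram. Higher SI means licking
is more concentrated in space — trained mice focus it on reward zones.
"""

import numpy as np

from placecode import (CorridorConfig, generate_trajectory, lick_histogram,
                       spatial_information)
from placecode.session import SessionData

cfg = CorridorConfig()
for agent in ("expert", "naive"):
    traj = generate_trajectory(cfg, 20, agent, seed=1)
    s = SessionData(dff=np.zeros((1, len(traj["position_cm"]))),
                    position_cm=traj["position_cm"],
                    velocity_cm_s=traj["velocity_cm_s"],
                    lick_frames=traj["lick_frames"],
                    reward_frames=traj["reward_frames"],
                    trial_bounds=traj["trial_bounds"])
    si = spatial_information(lick_histogram(s, cfg))
    in_rz = cfg.in_reward_zone(traj["position_cm"][traj["lick_frames"]]).mean()
    print(f"{agent:6s}: SI = {si:.3f} bits, {100 * in_rz:.0f}% of licks in reward zones")

print("\nThe expert's licking carries clearly more spatial information; a")
print("perfectly uniform licker would approach 0 bits (finite-trial noise")
print("keeps the naive agent's estimate above that floor).")
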