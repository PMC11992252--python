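"""Population vector correlation across a session pair, stable vs remapped.

Two experiments: a population of stable place cells imaged 3 days apart,
and one whose cells all remap between the sessions. The PVC y-intercept
(network stability) and initial slope (spatial precision) separate the two
regimes; ΔP shows that place-cell identity persists above chance only in
the stable network.
"""

import numpy as np

from placecode import (CorridorConfig, generate_experiment, generate_population,
                       pvc_curve_stats, pvc_matrix, shuffled_delta_p)
from placecode.spatial import bin_activity

cfg = CorridorConfig()
for label, props in (("stable", (1.0, 0.0, 0.0)), ("remapping", (0.0, 1.0, 0.0))):
    pop = generate_population(80, proportions=props, seed=9)
    exp = generate_experiment([-4, -1], pop, config=cfg, n_trials=10, seed=10)
    maps_a = bin_activity(exp.sessions[-4], cfg).smoothed
    maps_b = bin_activity(exp.sessions[-1], cfg).smoothed
    res = pvc_curve_stats(pvc_matrix(maps_a, maps_b), cfg)
    print(f"{label:9s}: PVC y-intercept = {res.y_intercept:.3f}, "
          f"initial slope = {res.initial_slope:.2f} per 100 cm")

print("\nThe stable network keeps a high same-position correlation across days;")
print("full remapping collapses the y-intercept toward the across-position floor.")

# class persistence against a shuffled-class null
rng = np.random.default_rng(11)
labels = rng.choice(["pc", "nc"], 200, p=[0.4, 0.6])
stats = shuffled_delta_p(labels, labels, n_shuffles=500, seed=12,
                         classes=("pc", "nc"))
dp = stats.delta_p.loc["pc", "pc"]
sd = stats.shuffle_sd.loc["pc", "pc"]
print(f"\nperfect persistence: ΔP(pc→pc) = {dp:.3f} ({dp / sd:.1f}× shuffle sd)")
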