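"""Raw multiplexed gas trace -> per-bird metabolic rates.

Runs the full processing chain (lag alignment, per-dwell smoothing and
z-transform, stable-window extraction, water-vapor dilution correction,
ambient baselining, pull-mode gas-exchange equations) on a short simulated
campaign and compares the result with the simulator's ground truth.
"""

import numpy as np

import aviphen
from aviphen import respirometry
from aviphen.params import ChamberConfig, EnvironmentProgram

config = aviphen.ExperimentConfig(
    chamber=ChamberConfig(n_chambers=2),        # 1 bird + 1 empty control
    environment=EnvironmentProgram(days=2, setpoints_c=[25.0, 10.0]),
    birds={1: aviphen.BirdParams()},
)
sim = aviphen.simulate_experiment(config, seed=3)
points = respirometry.process_gas_trace(
    sim.gas_trace, config.schedule, config.chamber,
    config.processing, config.ambient)

p1 = points[points["chamber"] == 1]
truth = sim.truth[1]["true_vo2"].to_numpy()
measured = p1["vo2"].to_numpy()
true_at_points = np.array([truth[int(ti) - 7:int(ti) + 8].mean()
                           for ti in p1["time_s"]])
err = 100 * np.abs(measured - true_at_points) / true_at_points
print(f"{len(p1)} metabolic points for bird 1 (one per 3 min cycle here)")
print(f"VO2 day 1 (25 degC): {measured[:360].mean():.2f} ml/min; "
      f"day 2 (10 degC): {measured[-360:].mean():.2f} ml/min")
print(f"median |error| vs ground truth: {np.median(err):.1f}%")
# Cooling below the lower critical temperature raises VO2; the pipeline
# tracks the simulator's true rates to within a few percent per point.
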