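"""Load-cell denoising, event classification and daily energy budget.

Reduces a bird's 1 Hz load-cell log ~600-fold to stable points, classifies
mass deltas (consumption / refill / body-mass recode / outlier), and sums
hourly gas exchange into Weir energy expenditure and daily minimum MR.
"""

import aviphen
from aviphen import biomonitor, energetics

config = aviphen.ExperimentConfig.default(n_birds=1, days=3)
config.environment.setpoints_c = (25.0, 15.0, 5.0)
sim = aviphen.simulate_experiment(config, seed=5)

mass = biomonitor.process_mass_trace(sim.mass[1], config.processing)
n_in = len(sim.mass[1].data)
n_out = len(mass.filtered)
print(f"load cells: {n_in:,} raw rows -> {n_out} stable points "
      f"({3 * n_in / n_out:.0f}x reduction per channel)")
print("event classes:",
      mass.events["event_class"].value_counts().to_dict())
daily = mass.daily
print(f"daily food {daily['food_g'].round(1).tolist()} g, "
      f"water {daily['water_g'].round(1).tolist()} g, "
      f"body mass {daily['mass_g'].round(1).tolist()} g")

res = aviphen.run_pipeline(sim)
ee = res.daily_energy.query("chamber == 1")["ee_kj"]
mr = res.daily_min_mr.query("chamber == 1")["min_vo2"]
print(f"daily EE: {[round(x, 1) for x in ee]} kJ "
      "(rises as the chamber cools)")
print(f"daily minimum VO2: {[round(x, 2) for x in mr]} ml/min "
      "(mean of the two lowest points per 24 h)")
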