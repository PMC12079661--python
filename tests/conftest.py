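"""Shared fixtures: one small noisy campaign and one noise-free oracle run.

The noisy campaign (3 birds, 3 days, 25 -> 15 -> 5 degC) exercises the whole
chain under the default noise model; the quiet run (1 bird, linear 25 -> 5
ramp then a steady day, all stochastic terms off) provides ground-truth
oracle comparisons.
"""

import numpy as np
import pytest
from hypothesis import settings

import aviphen
from aviphen.params import AnalyzerModel, ChamberConfig, EnvironmentProgram

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

RAMP_SEED = 42


@pytest.fixture(scope="session")
def ramp_run():
    """3 birds, 3 days, daily steps 25/15/5 degC, default (noisy) models."""
    cfg = aviphen.ExperimentConfig.default(n_birds=3, days=3)
    cfg.environment.setpoints_c = (25.0, 15.0, 5.0)
    sim = aviphen.simulate_experiment(cfg, RAMP_SEED)
    res = aviphen.run_pipeline(sim)
    return cfg, sim, res


@pytest.fixture(scope="session")
def quiet_run():
    """1 bird, noise-free: day 1 ramps 25 -> 5 degC linearly, day 2 steady."""
    bird = aviphen.BirdParams().quiet()
    cfg = aviphen.ExperimentConfig(
        chamber=ChamberConfig(n_chambers=2),
        analyzer=AnalyzerModel.noiseless(),
        environment=EnvironmentProgram(days=2, setpoints_c=[25.0, 5.0],
                                       interp="linear", rh_sd=0.0),
        birds={1: bird},
    )
    sim = aviphen.simulate_experiment(cfg, 0)
    points = aviphen.respirometry.process_gas_trace(
        sim.gas_trace, cfg.schedule, cfg.chamber, cfg.processing, cfg.ambient)
    return cfg, sim, points


def truth_window_mean(truth, column, times, half_s=7):
    """Ground-truth rate averaged over each point's stable window (+-half_s)."""
    arr = truth[column].to_numpy()
    out = np.empty(len(times))
    for j, t in enumerate(np.asarray(times, dtype=int)):
        out[j] = arr[max(0, t - half_s): t + half_s + 1].mean()
    return out
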