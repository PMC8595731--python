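import logging

import numpy as np
import pandas as pd
import pytest

import pursuithist as ph
from pursuithist import preprocess as pre

logging.getLogger("pursuithist").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_model():
    """Generator settings with no trace noise and no saccades."""
    import dataclasses
    return dataclasses.replace(ph.SimModel(), position_noise_sd=0.0,
                               saccade_rate=0.0, pursuit_gain=1.0)


@pytest.fixture(scope="session")
def noiseless_observer(noiseless_model):
    """One noiseless unpredictable-condition observer, fully simulated."""
    rng = np.random.default_rng(11)
    seq = ph.generate_stimulus_sequence("unpredictable", "s01", rng)
    traj = ph.render_target_trajectory(seq)
    timings = ph.simulate_reversal_timings(seq, noiseless_model, rng)
    trace, truth = ph.synthesize_eye_trace(traj, timings, noiseless_model,
                                           rng)
    return seq, traj, timings, trace, truth


def simulate_timing_table(seed, n_obs=12, condition="unpredictable",
                          model=None):
    """Trial table of simulated reversal timings (no traces), all included."""
    model = ph.SimModel() if model is None else model
    root = np.random.default_rng(seed)
    rows = []
    for oi, rng in enumerate(root.spawn(n_obs)):
        obs = f"s{oi + 1:02d}"
        seq = ph.generate_stimulus_sequence(condition, obs, rng)
        tim = ph.simulate_reversal_timings(seq, model, rng)
        for i, (bi, ti, vl) in enumerate(seq.trial_rows()):
            rows.append({"observer": obs, "condition": condition,
                         "block": bi, "trial": ti, "leftward_velocity": vl,
                         "eye_reversal": tim[i], "included": True})
    return pd.DataFrame(rows)


def velocity_trace(t_ms, values):
    return pre.SignalTrace(t=np.asarray(t_ms, float),
                           value=np.asarray(values, float), kind="velocity")
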