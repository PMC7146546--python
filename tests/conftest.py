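import numpy as np
import pandas as pd
import pytest

from patchforage import IBParams, SBParams, run_agent, segment_trials
from patchforage.behavior_analysis import SIM_FILTERS
from patchforage.task_env import EnvParams


def cohort_log(model, env, n_subjects, n_trials, seed, params=None):
    """Concatenate several simulated subjects into one event log."""
    if params is None:
        params = (SBParams() if model == "stimulus_bound"
                  else IBParams(p_rwd_hat=env.p_rwd, p_sw_hat=env.p_sw))
    logs = []
    for i in range(n_subjects):
        rng = np.random.default_rng(seed + i)
        logs.append(run_agent(model, params, env, n_trials, rng,
                              subject_id=f"s{i:02d}", record_traces=False))
    return pd.concat(logs, ignore_index=True)


@pytest.fixture(scope="session")
def medium_env():
    return EnvParams.from_protocol("medium")


@pytest.fixture(scope="session")
def ib_log(medium_env):
    """Small inference-based cohort in the medium schedule."""
    return cohort_log("inference_based", medium_env, 3, 1500, seed=10)


@pytest.fixture(scope="session")
def sb_log(medium_env):
    """Small stimulus-bound cohort in the medium schedule."""
    return cohort_log("stimulus_bound", medium_env, 3, 1500, seed=20)


@pytest.fixture(scope="session")
def ib_bouts(ib_log):
    return segment_trials(ib_log, SIM_FILTERS)


@pytest.fixture(scope="session")
def sb_bouts(sb_log):
    return segment_trials(sb_log, SIM_FILTERS)
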