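"""Behavioral controllers for the hidden-state foraging task.

Two generative models of stay/leave behavior are implemented.

**Stimulus-bound** control assigns value directly to observable outcomes:
the relative value V (left minus right) is a leaky integral of signed
outcomes o = r * s (site s is +1 left, -1 right),

    V_{t+1} = (1 - gamma) V_t + gamma o_{t+1}.

Rewards accumulate, so rich visits inflate the current site's value and
delay leaving; failures merely decay V toward zero.

**Inference-based** control tracks the posterior over the hidden state.
The sufficient statistic is the likelihood ratio
R = P(current site inactive) / P(current site active) given history.  Per
poke, a transition prior is applied, inverted when the subject changes
site, and the outcome multiplies in its evidence:

    R' = ((R + p_sw) / (1 - p_sw)) ** (s_t * s_{t+1}) * L(r),

with L(reward) = 0 (a reward proves the site active: R resets to zero
exactly) and L(failure) = 1 / (1 - p_rwd).  Over a run of t same-site
failures after a reward, R grows geometrically with factor
rho = 1 / ((1 - p_sw)(1 - p_rwd)):

    R(t) = p_sw * rho * (rho**t - 1) / (rho - 1),

so evidence for leaving accrues at rate log(rho) per failure — faster the
richer or more volatile the world.  The relative value is
V = p_rwd_hat * s * (1 - R) / (1 + R), i.e. the posterior difference
P(LeftActive) - P(RightActive) scaled by the assumed reward probability.

Both controllers act through the same softmax policy with a staying bias
T that offsets the travel cost:

    P(NextLeft | V, s) = sigmoid(beta * (V + s * T)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .task_env import (
    LEFT,
    RIGHT,
    EnvParams,
    EnvState,
    TimingParams,
    step,
)

STIMULUS_BOUND = "stimulus_bound"
INFERENCE_BASED = "inference_based"


@dataclass(frozen=True)
class SBParams:
    """Stimulus-bound (leaky integrator) agent parameters.

    gamma : decay/learning coefficient in (0, 1]
    beta  : softmax inverse temperature, > 0
    T     : staying bias, >= 0 (larger under higher travel cost)
    v0    : initial relative value
    """

    gamma: float = 0.5
    beta: float = 5.0
    T: float = 0.25
    v0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")


@dataclass(frozen=True)
class IBParams:
    """Inference-based agent parameters.

    p_rwd_hat, p_sw_hat : the agent's assumed task probabilities, in
        (0, 1) strictly (the evidence factor rho must be finite).  They
        default to the true environment values in simulations (optimal
        agent) but can be set independently to model miscalibration.
    beta, T : softmax inverse temperature and staying bias, as for SB.
    """

    p_rwd_hat: float = 0.9
    p_sw_hat: float = 0.3
    beta: float = 5.0
    T: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.p_rwd_hat < 1.0):
            raise ValueError("p_rwd_hat must be in (0, 1)")
        if not (0.0 < self.p_sw_hat < 1.0):
            raise ValueError("p_sw_hat must be in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")


@dataclass(frozen=True)
class BeliefState:
    """Likelihood ratio P(Inactive)/P(Active) for the current site.

    R >= 0 always; R == 0 exactly after any reward (certainty that the
    current site is active).  ``site`` is the site of the last poke.
    """

    R: float = 1.0
    site: int = LEFT

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if self.site not in (LEFT, RIGHT):
            raise ValueError("site must be +1 or -1")


def sb_update(v: float, o: float, gamma: float) -> float:
    """One leaky-integrator step: (1 - gamma) * v + gamma * o."""
    return (1.0 - gamma) * v + gamma * o


def sb_closed_form(v0: float, outcomes, gamma: float) -> float:
    """Closed form of the leaky integrator after a finite outcome sequence.

    V_t = (1-gamma)^t v0 + gamma * sum_i (1-gamma)^(t-i) o_i; equal to
    iterating :func:`sb_update` over the sequence.
    """
    o = np.asarray(outcomes, dtype=float)
    t = o.size
    decay = (1.0 - gamma) ** np.arange(t - 1, -1, -1)
    return (1.0 - gamma) ** t * v0 + gamma * float(decay @ o) if t else float(v0)


def ib_update(belief: BeliefState, next_site: int, r: int, params: IBParams) -> BeliefState:
    """One likelihood-ratio update for the poke at ``next_site`` with outcome ``r``.

    Two stages: (i) transition prior (R + p_sw)/(1 - p_sw), inverted when
    the poke changes site (the ratio is defined relative to the current
    site); (ii) outcome evidence — a reward resets R to 0 exactly, a
    failure multiplies by 1/(1 - p_rwd_hat).
    """
    ratio = (belief.R + params.p_sw_hat) / (1.0 - params.p_sw_hat)
    if next_site != belief.site:
        ratio = 1.0 / ratio
    if r:
        return BeliefState(R=0.0, site=next_site)
    return BeliefState(R=ratio / (1.0 - params.p_rwd_hat), site=next_site)


def evidence_growth_factor(params: IBParams) -> float:
    """rho = 1 / ((1 - p_sw_hat)(1 - p_rwd_hat)) > 1."""
    return 1.0 / ((1.0 - params.p_sw_hat) * (1.0 - params.p_rwd_hat))


def ib_closed_form_failure_run(t: int, params: IBParams) -> float:
    """Likelihood ratio after t consecutive same-site failures from R = 0.

    R(t) = p_sw_hat * rho * (rho**t - 1) / (rho - 1), the unique solution
    of the recursion R_{k+1} = rho * (R_k + p_sw_hat) with R(0) = 0.
    Matches t-fold iteration of :func:`ib_update` to high relative
    accuracy.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rho = evidence_growth_factor(params)
    if t == 0:
        return 0.0
    return params.p_sw_hat * rho * (rho**t - 1.0) / (rho - 1.0)


def evidence_growth_rate(params: IBParams) -> float:
    """log(rho) = -log(1 - p_rwd_hat) - log(1 - p_sw_hat).

    The per-failure rate of evidence accumulation for a state switch;
    strictly increasing in both assumed probabilities.
    """
    return -np.log1p(-params.p_rwd_hat) - np.log1p(-params.p_sw_hat)


def belief_to_value(belief: BeliefState, p_rwd_hat: float) -> float:
    """Relative value V = p_rwd_hat * s * (1 - R) / (1 + R).

    With P(active at current site) = 1/(1 + R) this equals
    p_rwd_hat * (P(LeftActive) - P(RightActive)).
    """
    return p_rwd_hat * belief.site * (1.0 - belief.R) / (1.0 + belief.R)


def _sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def p_next_left(v: float, s: int, beta: float, T: float) -> float:
    """Softmax policy P(NextLeft | V, s) = sigmoid(beta * (V + s * T))."""
    return float(_sigmoid(beta * (v + s * T)))


def p_stay(v: float, s: int, beta: float, T: float) -> float:
    """P(stay at current site) = sigmoid(beta * (s * V + T)).

    Consistent with :func:`p_next_left`: staying means NextLeft iff the
    current site is left (s = +1).
    """
    return float(_sigmoid(beta * (s * v + T)))


# ---------------------------------------------------------------------------
# Closed-loop simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimConfig:
    """Within-session inactivation emulation.

    target : ``OFC_like`` (controller forced to stimulus-bound on
        stimulated trials), ``ACC_like`` (staying bias multiplied by
        1 + effect_size, controller unchanged) or ``control`` (no effect).
    stim_fraction : probability that a trial is stimulated (i.i.d.).
    effect_size : multiplicative scaling of T for the ACC-like target.
    """

    target: str = "control"
    stim_fraction: float = 0.5
    effect_size: float = 0.1

    def __post_init__(self) -> None:
        if self.target not in ("OFC_like", "ACC_like", "control"):
            raise ValueError(f"unknown stimulation target {self.target!r}")
        if not (0.0 <= self.stim_fraction <= 1.0):
            raise ValueError("stim_fraction must be in [0, 1]")


def simulate_session(
    env: EnvParams,
    n_trials: int,
    rng: np.random.Generator,
    sb_params: Optional[SBParams] = None,
    ib_params: Optional[IBParams] = None,
    w_inference: float = 1.0,
    stim: Optional[StimConfig] = None,
    timing: Optional[TimingParams] = None,
    record_traces: bool = False,
    max_pokes_per_trial: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-loop simulation of one session against the environment.

    Each trial (same-site poke bout) is controlled by the inference-based
    agent with probability ``w_inference`` and by the stimulus-bound agent
    otherwise; both internal states are updated on every poke regardless
    of which controller is acting, so switching controllers mid-session is
    coherent.  The stay/leave decision is evaluated after every poke,
    rewarded or not.

    Returns
    -------
    (pokes, trials) : pair of DataFrames
        ``pokes`` has one row per poke (internal +1/-1 site codes);
        ``trials`` records the controller and stimulation flag per trial.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    sb_params = sb_params or SBParams()
    # default: optimal agent assuming the true environment probabilities
    ib_params = ib_params or IBParams(
        p_rwd_hat=min(env.p_rwd, 0.99), p_sw_hat=min(env.p_sw, 0.99))
    timing = timing or TimingParams()

    state = EnvState(active_site=int(rng.choice([LEFT, RIGHT])))
    site = int(rng.choice([LEFT, RIGHT]))
    v_sb = sb_params.v0
    belief = BeliefState(R=1.0, site=site)
    t_clock = 0.0
    poke_rows: list[tuple] = []
    trial_rows: list[tuple] = []

    for trial in range(1, n_trials + 1):
        use_ib = rng.random() < w_inference
        stimulated = stim is not None and rng.random() < stim.stim_fraction
        sb_T, ib_T = sb_params.T, ib_params.T
        if stimulated:
            if stim.target == "OFC_like":
                use_ib = False
            elif stim.target == "ACC_like":
                factor = 1.0 + stim.effect_size
                sb_T, ib_T = sb_T * factor, ib_T * factor
        controller = INFERENCE_BASED if use_ib else STIMULUS_BOUND
        trial_rows.append((trial, controller, int(stimulated)))

        for poke in range(1, max_pokes_per_trial + 1):
            reward, state = step(state, site, env, rng)
            v_sb = sb_update(v_sb, reward * site, sb_params.gamma)
            belief = ib_update(belief, site, reward, ib_params)
            v_ib = belief_to_value(belief, ib_params.p_rwd_hat)
            if use_ib:
                p_left = p_next_left(v_ib, site, ib_params.beta, ib_T)
            else:
                p_left = p_next_left(v_sb, site, sb_params.beta, sb_T)
            go_left = rng.random() < p_left
            stayed = (go_left and site == LEFT) or (not go_left and site == RIGHT)
            if poke >= max_pokes_per_trial:
                stayed = False
            dur = timing.draw(
                timing.rewarded_poke_duration if reward
                else timing.unrewarded_poke_duration, rng)
            row = (trial, poke, site, reward, t_clock, t_clock + dur,
                   state.active_site, int(stimulated))
            if record_traces:
                row = row + (controller, v_sb, v_ib, belief.R)
            poke_rows.append(row)
            t_clock += dur
            if stayed:
                t_clock += timing.draw(timing.inter_poke_interval, rng)
            else:
                t_clock += timing.draw(timing.travel_time, rng)
                site = -site
                break

    columns = ["trial", "poke", "site", "reward", "poke_in", "poke_out",
               "active_site", "stim"]
    if record_traces:
        columns += ["controller", "v_sb", "v_ib", "R_ib"]
    pokes = pd.DataFrame(poke_rows, columns=columns)
    trials = pd.DataFrame(trial_rows, columns=["trial", "controller", "stim"])
    return pokes, trials


def _to_eventlog(
    pokes: pd.DataFrame,
    env: EnvParams,
    subject_id: str = "sim",
    group: str = "sim",
    day: int = 1,
    session: int = 1,
    barrier: int = 0,
    reward_volume: float = 6.0,
) -> pd.DataFrame:
    """Format internal poke rows as the on-disk event-log schema."""
    out = pd.DataFrame({
        "subject_id": subject_id,
        "group": group,
        "day": day,
        "session": session,
        "protocol": env.protocol_label,
        "p_rwd": env.p_rwd,
        "p_sw": env.p_sw,
        "barrier": barrier,
        "stim": pokes["stim"].to_numpy(),
        "trial": pokes["trial"].to_numpy(),
        "poke": pokes["poke"].to_numpy(),
        "site": pokes["site"].map(io.SITE_TO_LETTER).to_numpy(),
        "reward": pokes["reward"].to_numpy(),
        "poke_in": pokes["poke_in"].to_numpy(),
        "poke_out": pokes["poke_out"].to_numpy(),
        "reward_volume": pokes["reward"].to_numpy() * reward_volume,
        "active_site": pokes["active_site"].map(io.SITE_TO_LETTER).to_numpy(),
    })
    for extra in ("controller", "v_sb", "v_ib", "R_ib"):
        if extra in pokes.columns:
            out[extra] = pokes[extra].to_numpy()
    return out


def run_agent(
    model: str,
    params: SBParams | IBParams,
    env: EnvParams,
    n_trials: int,
    rng: np.random.Generator,
    subject_id: str = "sim",
    session: int = 1,
    timing: Optional[TimingParams] = None,
    record_traces: bool = True,
) -> pd.DataFrame:
    """Simulate one agent closed-loop and return an event-log DataFrame.

    ``model`` is ``"stimulus_bound"`` or ``"inference_based"``; ``params``
    must match.  Per-poke value traces (and the likelihood ratio for the
    inference-based agent) are included as extra columns when
    ``record_traces`` is set.
    """
    if model == STIMULUS_BOUND:
        if not isinstance(params, SBParams):
            raise TypeError("stimulus_bound model requires SBParams")
        pokes, _ = simulate_session(
            env, n_trials, rng, sb_params=params, w_inference=0.0,
            timing=timing, record_traces=record_traces)
    elif model == INFERENCE_BASED:
        if not isinstance(params, IBParams):
            raise TypeError("inference_based model requires IBParams")
        pokes, _ = simulate_session(
            env, n_trials, rng, ib_params=params, w_inference=1.0,
            timing=timing, record_traces=record_traces)
    else:
        raise ValueError(f"unknown model {model!r}")
    return _to_eventlog(pokes, env, subject_id=subject_id, session=session)
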