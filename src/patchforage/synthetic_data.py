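"""Synthetic cohort generation.

Builds complete event logs with the statistical structure the behavioral
analyses assume: sessions of poke bouts generated by the hidden Markov
environment under the three named reward schedules, barrier (travel-cost)
conditions, a learning trajectory, and inactivation conditions.

Learning is emulated as a per-trial mixture of the two controllers: on
each trial the inference-based controller acts with probability w(day)
and the stimulus-bound controller otherwise, with w ramping from 0 to 1
over the first eight days by default (naive animals behave stimulus-bound,
trained animals inference-based).  Both controllers' internal states are
updated on every poke, so the mixture is coherent.

Inactivation is emulated at the trial level, on a random half of trials
by default: an OFC-like manipulation swaps the acting controller to
stimulus-bound (a strategy change), an ACC-like manipulation multiplies
the staying bias T by (1 + effect_size) (a graded delay in leaving),
and a control manipulation does nothing but set the flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import io
from .agents import (
    IBParams,
    SBParams,
    StimConfig,
    _to_eventlog,
    simulate_session,
)
from .task_env import (
    PROTOCOLS,
    TRAVEL_TIME_BARRIER,
    TRAVEL_TIME_NO_BARRIER,
    EnvParams,
    TimingParams,
)

#: water per correct trial is held constant at 6 ul across schedules
WATER_PER_CORRECT_TRIAL = 6.0

REWARD_MAGNITUDE = {"easy": 6.0, "medium": 2.0, "hard": 6.0}


def reward_magnitude(protocol: str, custom: Optional[float] = None) -> float:
    """Reward volume (ul) per rewarded poke for a named schedule.

    Chosen so that magnitude * p_rwd / p_sw = 6 ul in every schedule:
    6 ul in easy and hard (one reward per correct trial on average), 2 ul
    in medium (three rewards).  A custom schedule needs an explicit value.
    """
    if protocol in REWARD_MAGNITUDE:
        return REWARD_MAGNITUDE[protocol]
    if custom is None:
        raise ValueError("custom protocol requires an explicit reward magnitude")
    return custom


def default_learning_curve(day: int, ramp_days: int = 8) -> float:
    """Mixture weight of the inference-based controller on a given day.

    Linear ramp from 0 on day 1 to 1 on day ``ramp_days``, then 1.
    """
    return float(np.clip((day - 1) / (ramp_days - 1), 0.0, 1.0))


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    protocol_schedule : ordered (protocol_label, barrier_flag, n_days)
        blocks; days are numbered consecutively across blocks.
    learning_curve : map day -> mixture weight w of the inference-based
        controller, or None for the default ramp.  Scalars are allowed
        and mean a constant weight.
    inactivation : optional :class:`~patchforage.agents.StimConfig`.
    barrier_T_bonus : additive increase of the staying bias under the
        barrier (the normative link: higher travel cost raises the
        leaving threshold).
    """

    n_subjects: int = 18
    protocol_schedule: tuple = (("medium", 0, 12),)
    trials_per_session: int = 60
    learning_curve: Optional[object] = None
    inactivation: Optional[StimConfig] = None
    seed: int = 0
    sb_params: SBParams = field(default_factory=SBParams)
    ib_params: Optional[IBParams] = None
    barrier_T_bonus: float = 0.15
    group: str = "A"

    def weight(self, day: int) -> float:
        lc = self.learning_curve
        if lc is None:
            return default_learning_curve(day)
        if callable(lc):
            return float(lc(day))
        if isinstance(lc, dict):
            return float(lc[day])
        return float(lc)

    def days(self) -> list[tuple[int, str, int]]:
        """Expand the schedule to (day, protocol, barrier) triples."""
        out = []
        day = 1
        for protocol, barrier, n_days in self.protocol_schedule:
            if protocol not in PROTOCOLS:
                raise ValueError(f"unknown protocol {protocol!r} in schedule")
            if n_days < 1:
                raise ValueError("schedule blocks need n_days >= 1")
            for _ in range(n_days):
                out.append((day, protocol, int(barrier)))
                day += 1
        return out


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns
    -------
    (log, ground_truth) : pair of DataFrames
        ``log`` follows the event-log schema (ground-truth active site
        included); ``ground_truth`` has one row per trial with the acting
        controller and the stimulation flag.
    """
    schedule = config.days()
    seed_seq = np.random.SeedSequence(config.seed)
    subject_seeds = seed_seq.spawn(config.n_subjects)
    logs, truths = [], []
    for i in range(config.n_subjects):
        subject_id = f"m{i + 1:02d}"
        rng = np.random.default_rng(subject_seeds[i])
        for day, protocol, barrier in schedule:
            travel = TRAVEL_TIME_BARRIER if barrier else TRAVEL_TIME_NO_BARRIER
            env = EnvParams.from_protocol(protocol, travel_cost=travel)
            timing = TimingParams(travel_time=travel)
            bonus = config.barrier_T_bonus if barrier else 0.0
            sb = SBParams(gamma=config.sb_params.gamma,
                          beta=config.sb_params.beta,
                          T=config.sb_params.T + bonus,
                          v0=config.sb_params.v0)
            if config.ib_params is None:
                ib = IBParams(p_rwd_hat=env.p_rwd, p_sw_hat=env.p_sw,
                              beta=sb.beta, T=config.sb_params.T + bonus)
            else:
                ib = IBParams(p_rwd_hat=config.ib_params.p_rwd_hat,
                              p_sw_hat=config.ib_params.p_sw_hat,
                              beta=config.ib_params.beta,
                              T=config.ib_params.T + bonus)
            pokes, trials = simulate_session(
                env, config.trials_per_session, rng,
                sb_params=sb, ib_params=ib,
                w_inference=config.weight(day),
                stim=config.inactivation, timing=timing)
            log = _to_eventlog(
                pokes, env, subject_id=subject_id, group=config.group,
                day=day, session=day, barrier=barrier,
                reward_volume=reward_magnitude(protocol))
            logs.append(log)
            truth = trials.assign(subject_id=subject_id, session=day, day=day)
            truths.append(truth)
    log = pd.concat(logs, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)[
        ["subject_id", "session", "day", "trial", "controller", "stim"]]
    return log, truth
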