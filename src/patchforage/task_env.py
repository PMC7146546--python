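"""Two-site hidden-state foraging environment.

The world is a two-state hidden Markov model: exactly one of two foraging
sites (left = +1, right = -1) is *active* at any moment.  Each poke at the
active site yields reward with probability ``p_rwd`` and, independently,
triggers a switch of the active site with probability ``p_sw``; the switch
takes effect only after the current poke's outcome is delivered.  Pokes at
the inactive site are never rewarded and never move the state, so a subject
that leaves too early must travel back to recover the reward stream.

The expected number of rewarded pokes per correct visit ("trial") is
``p_rwd / p_sw``: occupancy of the active state is geometric with mean
``1 / p_sw`` pokes and each poke is rewarded with probability ``p_rwd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

LEFT = 1
RIGHT = -1

#: (p_rwd, p_sw) for the three named reward schedules.
PROTOCOLS = {
    "easy": (0.9, 0.9),
    "medium": (0.9, 0.3),
    "hard": (0.3, 0.3),
}

#: Default travel durations in seconds (without / with a physical barrier).
TRAVEL_TIME_NO_BARRIER = 1.86
TRAVEL_TIME_BARRIER = 2.69


@dataclass(frozen=True)
class EnvParams:
    """Parameters of the hidden-state foraging environment.

    Parameters
    ----------
    p_rwd : float
        Probability of reward per poke at the active site, in (0, 1].
    p_sw : float
        Probability that a poke at the active site switches the hidden
        state (after the poke's outcome), in (0, 1].
    travel_cost : float
        Abstract travel cost between sites, >= 0; larger under a barrier.
    protocol_label : str
        One of ``easy``, ``medium``, ``hard`` or ``custom``.  The named
        labels pin (p_rwd, p_sw) to the printed schedules.
    """

    p_rwd: float
    p_sw: float
    travel_cost: float = 0.0
    protocol_label: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_rwd <= 1.0):
            raise ValueError(f"p_rwd must be in (0, 1], got {self.p_rwd}")
        if not (0.0 < self.p_sw <= 1.0):
            raise ValueError(f"p_sw must be in (0, 1], got {self.p_sw}")
        if self.travel_cost < 0:
            raise ValueError("travel_cost must be >= 0")
        if self.protocol_label not in PROTOCOLS and self.protocol_label != "custom":
            raise ValueError(f"unknown protocol_label {self.protocol_label!r}")
        if self.protocol_label in PROTOCOLS:
            expected = PROTOCOLS[self.protocol_label]
            if (self.p_rwd, self.p_sw) != expected:
                raise ValueError(
                    f"protocol {self.protocol_label!r} requires (p_rwd, p_sw) = "
                    f"{expected}, got {(self.p_rwd, self.p_sw)}"
                )

    @classmethod
    def from_protocol(cls, label: str, travel_cost: float = 0.0) -> "EnvParams":
        """Build parameters from a named protocol label."""
        if label not in PROTOCOLS:
            raise ValueError(f"unknown protocol {label!r}")
        p_rwd, p_sw = PROTOCOLS[label]
        return cls(p_rwd=p_rwd, p_sw=p_sw, travel_cost=travel_cost, protocol_label=label)


@dataclass
class EnvState:
    """Hidden state: which site is currently active (+1 left, -1 right)."""

    active_site: int = LEFT

    def __post_init__(self) -> None:
        if self.active_site not in (LEFT, RIGHT):
            raise ValueError("active_site must be +1 or -1")


def step(
    state: EnvState,
    poked_site: int,
    params: EnvParams,
    rng: np.random.Generator,
) -> tuple[int, EnvState]:
    """Advance the environment by one poke.

    At the active site the reward draw (Bernoulli p_rwd) and the switch
    draw (Bernoulli p_sw) are independent, and a rewarded poke *can*
    trigger the switch — the switch takes effect after the outcome.  This
    ordering is what makes the expected rewards per correct visit equal
    p_rwd / p_sw.  Pokes at the inactive site return no reward and leave
    the state untouched.

    Returns
    -------
    (reward, next_state) : tuple[int, EnvState]
    """
    if poked_site not in (LEFT, RIGHT):
        raise ValueError("poked_site must be +1 or -1")
    if poked_site != state.active_site:
        return 0, state
    reward = int(rng.random() < params.p_rwd)
    if rng.random() < params.p_sw:
        return reward, EnvState(active_site=-state.active_site)
    return reward, state


def expected_rewards_per_correct_trial(params: EnvParams) -> float:
    """Expected number of rewarded pokes per visit to the active site.

    Equals ``p_rwd / p_sw``: 3 in the medium schedule, 1 in easy and hard.
    """
    return params.p_rwd / params.p_sw


@dataclass(frozen=True)
class TimingParams:
    """Lognormal timing model for simulated event logs.

    Means are in seconds and match the printed summary statistics of the
    mouse task (inter-poke interval 0.16 s; unrewarded poke duration
    0.33 s; travel 1.86 s without barrier, 2.69 s with).  The rewarded poke
    duration is not printed; the default assumes drinking lengthens the
    poke.  ``sigma`` is the lognormal shape parameter shared by all draws.
    """

    inter_poke_interval: float = 0.16
    unrewarded_poke_duration: float = 0.33
    rewarded_poke_duration: float = 0.45
    travel_time: float = TRAVEL_TIME_NO_BARRIER
    sigma: float = 0.2

    def draw(self, mean: float, rng: np.random.Generator) -> float:
        """One lognormal draw with the given mean."""
        mu = np.log(mean) - 0.5 * self.sigma**2
        return float(rng.lognormal(mu, self.sigma))


def simulate_episode(
    params: EnvParams,
    policy: Callable[[list[int]], bool],
    max_pokes: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    start_site: Optional[int] = None,
    timing: Optional[TimingParams] = None,
) -> pd.DataFrame:
    """Drive a stay/leave policy through the environment.

    ``policy`` receives the outcome history (list of 0/1 rewards) of the
    current same-site visit and returns True to stay for another poke.
    The returned frame has one row per poke with the ground-truth active
    site; leaving while the current site is still active is recorded as an
    ``error_transition`` (the other site pays nothing until the subject
    returns).  If ``max_pokes`` is reached the episode is truncated and
    flagged in ``frame.attrs["truncated"]``.
    """
    rng = np.random.default_rng() if rng is None else rng
    timing = TimingParams() if timing is None else timing
    state = EnvState(active_site=start_site if start_site is not None
                     else int(rng.choice([LEFT, RIGHT])))
    site = state.active_site  # start at the active site by convention
    rows: list[dict] = []
    bout_outcomes: list[int] = []
    trial = 1
    t = 0.0
    stayed = True
    for _ in range(max_pokes):
        was_active = state.active_site == site
        reward, state = step(state, site, params, rng)
        bout_outcomes.append(reward)
        dur = timing.draw(
            timing.rewarded_poke_duration if reward else timing.unrewarded_poke_duration,
            rng,
        )
        rows.append({
            "trial": trial,
            "poke": len(bout_outcomes),
            "site": site,
            "reward": reward,
            "poke_in": t,
            "poke_out": t + dur,
            "active_site": state.active_site,
            "site_was_active": was_active,
            "error_transition": False,
        })
        t += dur
        stayed = bool(policy(list(bout_outcomes)))
        if stayed:
            t += timing.draw(timing.inter_poke_interval, rng)
            continue
        # leaving: error if the abandoned site is still the active one
        rows[-1]["error_transition"] = state.active_site == site
        site = -site
        trial += 1
        bout_outcomes = []
        t += timing.draw(timing.travel_time, rng)
    frame = pd.DataFrame(rows)
    # truncated: the poke budget ran out while the policy wanted to stay
    frame.attrs["truncated"] = stayed
    return frame


def simulate_active_bouts(
    params: EnvParams, n_bouts: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate repeated stays at the active site until the state switches.

    Vectorized Monte-Carlo of the occupancy statistics: each bout pokes the
    active site until the switch takes effect.  Returns one row per bout
    with the number of active pokes and the number of rewarded pokes.
    Occupancy is geometric with mean 1/p_sw and the expected rewards per
    bout equal p_rwd / p_sw.
    """
    pokes = rng.geometric(params.p_sw, size=n_bouts)
    rewards = rng.binomial(pokes, params.p_rwd)
    return pd.DataFrame({"n_pokes": pokes, "n_rewards": rewards})


def mc_rewards_per_correct_trial(
    params: EnvParams, n_bouts: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo estimate of rewarded pokes per correct visit via ``step``.

    Pokes the active site through the full generative ``step`` dynamics
    (independent reward and switch draws; switch effective after the
    outcome) until the switch takes effect, ``n_bouts`` times, and returns
    the mean rewarded pokes per bout.  Converges to p_rwd / p_sw.
    """
    total_rewards = 0
    for _ in range(n_bouts):
        state = EnvState(active_site=LEFT)
        while state.active_site == LEFT:
            reward, state = step(state, LEFT, params, rng)
            total_rewards += reward
    return total_rewards / n_bouts
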