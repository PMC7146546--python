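"""Static figure helpers mirroring the main analysis panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_value_trace(log: pd.DataFrame, ax=None, max_pokes: int = 120):
    """Per-poke relative value trace with rewards and the hidden state.

    Expects a trace-annotated log from ``run_agent`` (columns ``v_sb`` or
    ``v_ib``).  Rewards are drawn in green, failures in gray; the shaded
    band marks when the left site is active.
    """
    ax = ax or plt.gca()
    df = log.head(max_pokes)
    value_col = "v_ib" if "v_ib" in df.columns else "v_sb"
    x = np.arange(len(df))
    ax.fill_between(x, -1, 1, where=(df["active_site"] == "L"),
                    color="0.9", step="mid", label="left active")
    ax.plot(x, df[value_col], lw=1.2, color="k")
    rewarded = df["reward"] == 1
    ax.scatter(x[rewarded], df.loc[rewarded, value_col], s=14, color="green",
               zorder=3, label="reward")
    ax.scatter(x[~rewarded], df.loc[~rewarded, value_col], s=8, color="0.5",
               zorder=3, label="failure")
    ax.set(xlabel="poke", ylabel="relative value (L - R)", ylim=(-1.05, 1.05))
    ax.legend(loc="upper right", fontsize=7)
    return ax


def plot_leaving_surface(surface: pd.DataFrame, ax=None):
    """Heatmap of P(leave) over (rewards so far, consecutive failures)."""
    ax = ax or plt.gca()
    im = ax.imshow(surface.to_numpy(), origin="lower", aspect="auto",
                   vmin=0, vmax=1, cmap="viridis")
    ax.set(xlabel="consecutive failures", ylabel="rewards so far")
    plt.colorbar(im, ax=ax, label="P(leave)")
    return ax


def plot_cf_by_reward_number(bouts: pd.DataFrame, by: str = "subject_id",
                             ax=None, max_rewards: int = 4):
    """Mean consecutive failures vs reward number (mean +/- SEM across
    subjects), the model-discrimination panel."""
    ax = ax or plt.gca()
    df = bouts.copy()
    df["rn"] = df["reward_number"].clip(upper=max_rewards)
    per = df.groupby([by, "rn"])["consecutive_failures"].mean().reset_index()
    agg = per.groupby("rn")["consecutive_failures"].agg(["mean", "sem"])
    ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], marker="o", color="k")
    ax.set(xlabel="reward number", ylabel="consecutive failures before leaving")
    return ax


def plot_slope_by_day(bouts: pd.DataFrame, ax=None):
    """Evolution of the per-subject reward-number slope across days."""
    from .behavior_analysis import slope_cf_vs_rewards

    ax = ax or plt.gca()
    days = sorted(bouts["day"].unique())
    means, sems = [], []
    for day in days:
        ts = slope_cf_vs_rewards(bouts[bouts["day"] == day])
        means.append(ts.mean)
        sems.append(ts.sem)
    ax.errorbar(days, means, yerr=sems, marker="o", color="k")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set(xlabel="training day", ylabel="reward-number slope")
    return ax
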