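"""Behavioral hallmark statistics for the foraging task.

Everything here consumes the poke-level event log and works through a
common segmentation: a *bout* (= trial) is a maximal run of same-site
pokes.  The primary dependent variable is the number of *consecutive
failures* before leaving — the trailing run of unrewarded pokes after the
last reward of a bout.  Its relationship to the number of rewards in the
bout discriminates the two controllers: a leaky integrator inflates value
with every reward (positive slope), whereas hidden-state inference resets
on every reward (flat).

Filters mirror the experimental analysis: pokes shorter than 100 ms are
discarded before segmentation, then per session the first 10 bouts are
skipped and the next 50 kept, and zero-reward bouts are excluded — in
that order.

The experimental mixed-effects models (random intercept per subject) are
approximated by two-stage estimation: an ordinary regression per subject,
then a mean +/- SEM and one-sample t test across subjects.  Pooled GLMs
use subject fixed effects instead of random intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import io


@dataclass(frozen=True)
class FilterConfig:
    """Bout-filtering settings (defaults match the experimental analysis)."""

    skip_first: int = 10
    keep_next: int = 50
    exclude_zero_reward: bool = True
    min_poke_duration: float = 0.100

    def __post_init__(self) -> None:
        if self.skip_first < 0 or self.keep_next < 0:
            raise ValueError("counts must be >= 0")


#: no-op filters, handy for analyzing raw simulations
RAW = FilterConfig(skip_first=0, keep_next=10**9, exclude_zero_reward=False,
                   min_poke_duration=0.0)

#: keep every bout of a clean simulation but drop zero-reward bouts,
#: matching the experimental exclusion without the session windowing
SIM_FILTERS = FilterConfig(skip_first=0, keep_next=10**9,
                           exclude_zero_reward=True, min_poke_duration=0.0)


@dataclass
class TwoStage:
    """Per-subject estimates plus the across-subject summary."""

    per_subject: pd.DataFrame
    mean: float
    sem: float
    tstat: float
    pvalue: float
    n_subjects: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"TwoStage(mean={self.mean:.4f}, sem={self.sem:.4f}, "
                f"t={self.tstat:.2f}, p={self.pvalue:.3g}, n={self.n_subjects})")


def _trailing_failures(outcomes: Sequence[int]) -> int:
    n = 0
    for o in reversed(outcomes):
        if o:
            break
        n += 1
    return n


def _prepare(log: pd.DataFrame, filters: FilterConfig) -> pd.DataFrame:
    """Drop short pokes, assign bout ids, apply the per-session filters.

    Returns the surviving poke-level rows with ``bout``, ``reward_number``
    and ``consecutive_failures`` columns attached.  Filter order is fixed:
    duration -> skip_first -> keep_next -> zero-reward exclusion.
    """
    df = log.copy()
    if not np.issubdtype(df["site"].dtype, np.number):
        df["site_sign"] = df["site"].map(io.LETTER_TO_SITE)
    else:
        df["site_sign"] = df["site"]
    df = df[df["poke_out"] - df["poke_in"] >= filters.min_poke_duration]
    df = df.sort_values(["subject_id", "session", "poke_in"], kind="stable")

    parts = []
    for (subj, sess), grp in df.groupby(["subject_id", "session"], sort=False):
        grp = grp.copy()
        grp["bout"] = (grp["site_sign"] != grp["site_sign"].shift()).cumsum()
        n_bouts = grp["bout"].iloc[-1]
        lo = filters.skip_first + 1
        hi = filters.skip_first + filters.keep_next
        grp = grp[(grp["bout"] >= lo) & (grp["bout"] <= hi)]
        if grp.empty:
            continue
        rn = grp.groupby("bout")["reward"].transform("sum")
        grp["reward_number"] = rn
        grp["consecutive_failures"] = grp.groupby("bout")["reward"].transform(
            lambda r: _trailing_failures(r.tolist()))
        if filters.exclude_zero_reward:
            grp = grp[grp["reward_number"] > 0]
        parts.append(grp)
    if not parts:
        raise ValueError("no bouts survived filters")
    return pd.concat(parts, ignore_index=True)


def segment_trials(log: pd.DataFrame, filters: Optional[FilterConfig] = None
                   ) -> pd.DataFrame:
    """Segment an event log into filtered bouts (one row per bout).

    Columns include the ordered ``outcomes`` tuple, ``reward_number``,
    ``consecutive_failures``, the per-bout ``stim`` flag, condition labels
    and (when ground truth is present) whether the leave was ``correct``
    (the hidden state had already switched away).
    """
    filters = filters or FilterConfig()
    pokes = _prepare(log, filters)

    def agg(grp: pd.DataFrame) -> pd.Series:
        outcomes = tuple(int(r) for r in grp["reward"])
        last = grp.iloc[-1]
        correct = np.nan
        if "active_site" in grp.columns and isinstance(last.get("active_site"), str) \
                and last["active_site"] in ("L", "R"):
            correct = float(last["active_site"] != last["site"])
        return pd.Series({
            "site": last["site"],
            "n_pokes": len(outcomes),
            "outcomes": outcomes,
            "reward_number": int(sum(outcomes)),
            "consecutive_failures": _trailing_failures(outcomes),
            "stim": int(grp["stim"].max()) if "stim" in grp.columns else 0,
            "protocol": last.get("protocol", "custom"),
            "barrier": int(last.get("barrier", 0)),
            "day": int(last.get("day", 1)),
            "correct": correct,
            "t_start": grp["poke_in"].iloc[0],
        })

    bouts = (pokes.groupby(["subject_id", "session", "bout"], sort=True)
             .apply(agg, include_groups=False).reset_index())
    return bouts.rename(columns={"bout": "trial_index"})


def _per_subject_slope(bouts: pd.DataFrame, x: str, y: str) -> pd.DataFrame:
    rows = []
    for subj, grp in bouts.groupby("subject_id"):
        xv = grp[x].to_numpy(float)
        yv = grp[y].to_numpy(float)
        if np.unique(xv).size < 2:
            rows.append({"subject_id": subj, "slope": np.nan,
                         "intercept": np.nan, "n": len(grp), "degenerate": True})
            continue
        res = scipy.stats.linregress(xv, yv)
        rows.append({"subject_id": subj, "slope": res.slope,
                     "intercept": res.intercept, "n": len(grp),
                     "degenerate": False})
    return pd.DataFrame(rows)


def _two_stage(per_subject: pd.DataFrame, column: str = "slope") -> TwoStage:
    vals = per_subject.loc[~per_subject.get("degenerate", False), column].dropna()
    vals = np.asarray(vals, float)
    n = vals.size
    if n == 0:
        raise ValueError("no usable subjects")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    if n > 1 and sem > 0:
        t, p = scipy.stats.ttest_1samp(vals, 0.0)
    else:
        t, p = np.nan, np.nan
    return TwoStage(per_subject, mean, sem, float(t), float(p), n)


def slope_cf_vs_rewards(bouts: pd.DataFrame) -> TwoStage:
    """Per-subject OLS slope of consecutive failures on reward number.

    The model-discrimination hallmark: positive under stimulus-bound
    control, ~0 under inference (reward reset).  Subjects with a
    degenerate design (a single reward-number value) are flagged and
    excluded from the pooled summary.
    """
    per = _per_subject_slope(bouts, "reward_number", "consecutive_failures")
    return _two_stage(per)


def reset_analysis(bouts: pd.DataFrame) -> TwoStage:
    """Slope of failures-after-reward on failures-before-reward.

    Restricted to single-reward bouts.  Under inference the reward resets
    the evidence count, so the slope is ~0; under a leaky integrator the
    later the reward arrives the lower the value it tops up, giving a
    negative slope.
    """
    single = bouts[bouts["reward_number"] == 1].copy()
    if single.empty:
        raise ValueError("no single-reward bouts")
    single["failures_before"] = single["outcomes"].map(
        lambda o: int(np.argmax(np.asarray(o) == 1)))
    single["failures_after"] = single["consecutive_failures"]
    per = _per_subject_slope(single, "failures_before", "failures_after")
    return _two_stage(per)


def leaving_surface(
    bouts: pd.DataFrame,
    max_rewards: int = 4,
    max_failures: int = 8,
    min_count: int = 10,
    include_final: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical leaving hazard on a (rewards so far, failures so far) grid.

    Every poke is an opportunity; its cell is indexed by the number of
    rewards collected so far in the bout and the current trailing-failure
    count (both evaluated after the poke's outcome, when the stay/leave
    decision is made).  The cell value is leaves / opportunities.  Both
    axes pool at their caps; cells with fewer than ``min_count``
    opportunities are NaN-masked in the probability grid (counts are
    returned unmasked).
    """
    if max_rewards < 1 or max_failures < 1:
        raise ValueError("grid bounds must be >= 1")
    leaves = np.zeros((max_rewards + 1, max_failures + 1))
    counts = np.zeros_like(leaves)
    for outcomes in bouts["outcomes"]:
        rewards = 0
        trailing = 0
        last = len(outcomes) - 1
        for i, o in enumerate(outcomes):
            if o:
                rewards += 1
                trailing = 0
            else:
                trailing += 1
            r_idx = min(rewards, max_rewards)
            f_idx = min(trailing, max_failures)
            is_leave = i == last
            if is_leave and not include_final:
                continue
            counts[r_idx, f_idx] += 1
            leaves[r_idx, f_idx] += is_leave
    with np.errstate(invalid="ignore", divide="ignore"):
        p = leaves / counts
    p[counts < min_count] = np.nan
    idx = pd.Index(range(max_rewards + 1), name="rewards_so_far")
    cols = pd.Index(range(max_failures + 1), name="consecutive_failures")
    return (pd.DataFrame(p, index=idx, columns=cols),
            pd.DataFrame(counts, index=idx, columns=cols))


def condition_contrasts(
    bouts: pd.DataFrame,
    factors: Sequence[str] = ("protocol", "barrier", "stim"),
) -> pd.DataFrame:
    """Per subject x condition mean consecutive failures, with contrasts.

    Returns a tidy table of cell means.  When ``stim`` is among the
    factors, each stimulated cell also carries the additive contrast
    (difference) and the multiplicative contrast (ratio) against the
    matching non-stimulated cell of the same subject x condition — the
    latter is the "renormalized" analysis used to test whether an effect
    scales with the baseline.
    """
    factors = [f for f in factors if f in bouts.columns]
    keys = ["subject_id"] + list(factors)
    cells = (bouts.groupby(keys)["consecutive_failures"]
             .agg(["mean", "count"]).reset_index()
             .rename(columns={"mean": "cf_mean", "count": "n_bouts"}))
    if "stim" in factors:
        base_keys = ["subject_id"] + [f for f in factors if f != "stim"]
        control = cells[cells["stim"] == 0].set_index(base_keys)["cf_mean"]
        def _lookup(row):
            key = tuple(row[k] for k in base_keys)
            key = key[0] if len(key) == 1 else key
            return control.get(key, np.nan)
        baseline = cells.apply(_lookup, axis=1)
        cells["difference"] = cells["cf_mean"] - baseline
        cells["ratio"] = cells["cf_mean"] / baseline
        cells.loc[cells["stim"] == 0, ["difference", "ratio"]] = np.nan
    missing = cells[cells["n_bouts"] == 0]
    cells.attrs["missing_cells"] = missing[keys].to_dict("records")
    return cells


def stim_reward_interaction(bouts: pd.DataFrame) -> TwoStage:
    """Per-subject stimulation x reward-number interaction on failures.

    OLS of consecutive failures on stimulation, reward number and their
    interaction, per subject; the interaction coefficient is the readout
    (positive when stimulation re-instates reward-number sensitivity,
    i.e. a controller change; ~0 when stimulation merely scales the
    staying bias).
    """
    rows = []
    for subj, grp in bouts.groupby("subject_id"):
        if grp["stim"].nunique() < 2 or grp["reward_number"].nunique() < 2:
            rows.append({"subject_id": subj, "interaction": np.nan,
                         "se": np.nan, "degenerate": True})
            continue
        fit = smf.ols(
            "consecutive_failures ~ stim * reward_number", data=grp).fit()
        name = "stim:reward_number"
        rows.append({"subject_id": subj,
                     "interaction": fit.params[name],
                     "se": fit.bse[name],
                     "degenerate": not np.isfinite(fit.params[name])})
    per = pd.DataFrame(rows)
    return _two_stage(per, column="interaction")


@dataclass
class LeavingModelResult:
    """One poke-level logistic leaving model."""

    name: str
    params: pd.Series
    bse: pd.Series
    llf: float
    deviance: float
    n_obs: int
    separation_warning: bool = False

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"LeavingModelResult({self.name!r}, deviance={self.deviance:.1f}, "
                f"n={self.n_obs})")


def poke_predictors(
    log: pd.DataFrame,
    filters: Optional[FilterConfig] = None,
    include_final: bool = True,
) -> pd.DataFrame:
    """Poke-level table with leaving predictors.

    ``leave`` marks the last poke of a bout (the next valid poke is at
    the other site, or the session ends — the final bout counts as a
    leaving opportunity unless ``include_final`` is off).
    ``consecutive_failure_index`` is the trailing-failure count at the
    decision; ``time_at_port`` is seconds since the first poke of the
    bout, at poke onset.
    """
    filters = filters or FilterConfig()
    pokes = _prepare(log, filters)
    grp = pokes.groupby(["subject_id", "session", "bout"], sort=False)
    pokes = pokes.assign(
        consecutive_failure_index=grp["reward"].transform(_running_trailing),
        time_at_port=pokes["poke_in"] - grp["poke_in"].transform("first"),
        leave=(grp.cumcount(ascending=False) == 0).astype(int),
    )
    if not include_final:
        last_of_session = pokes.groupby(["subject_id", "session"], sort=False) \
            .cumcount(ascending=False) == 0
        pokes = pokes[~last_of_session]
    return pokes


def _running_trailing(rewards: pd.Series) -> np.ndarray:
    """Trailing-failure count after each poke of a bout."""
    out = np.empty(len(rewards), dtype=int)
    run = 0
    for i, r in enumerate(rewards.to_numpy()):
        run = 0 if r else run + 1
        out[i] = run
    return out


def logistic_leaving_models(
    log: pd.DataFrame,
    filters: Optional[FilterConfig] = None,
) -> dict[str, LeavingModelResult]:
    """Poke-level logistic regressions of leaving.

    Fits leave ~ ConsecutiveFailureIndex, leave ~ TimeSpentAtPort and the
    combined model (subject fixed effects added when several subjects are
    present) and reports coefficients and deviances for comparison; the
    failure-count model wins when leaving is evidence-driven.
    """
    pokes = poke_predictors(log, filters)
    multi = pokes["subject_id"].nunique() > 1
    fe = " + C(subject_id)" if multi else ""
    formulas = {
        "failure": "leave ~ consecutive_failure_index" + fe,
        "time": "leave ~ time_at_port" + fe,
        "combined": "leave ~ consecutive_failure_index + time_at_port" + fe,
    }
    out: dict[str, LeavingModelResult] = {}
    for name, formula in formulas.items():
        sep = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = smf.glm(formula, data=pokes,
                          family=sm.families.Binomial()).fit()
            sep = any("separation" in str(w.message).lower() or
                      np.abs(fit.params).max() > 50 for w in caught) \
                or bool(np.abs(fit.params).max() > 50)
        out[name] = LeavingModelResult(
            name=name, params=fit.params, bse=fit.bse, llf=float(fit.llf),
            deviance=float(-2.0 * fit.llf), n_obs=int(fit.nobs),
            separation_warning=sep)
    return out


def subtractive_normalization(
    df: pd.DataFrame,
    value: str = "consecutive_failures",
    group: Sequence[str] = ("subject_id",),
) -> pd.Series:
    """Center a value on its within-group grand mean.

    Used before aggregating failures by reward number so that subjects
    (or models) with different overall staying tendencies can be
    averaged; per-group means of the output are exactly zero, and
    per-subject centering leaves within-subject regression slopes
    untouched.
    """
    return df[value] - df.groupby(list(group))[value].transform("mean")
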