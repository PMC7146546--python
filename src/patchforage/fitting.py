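"""Maximum-likelihood fitting of the behavioral controllers.

Organized like a statsmodels model: build a model object from a
decision sequence (:meth:`ForagingChoiceModel.from_eventlog`), call
``fit()`` and get a :class:`ForagingFitResults` carrying estimates,
standard errors, NLL/deviance/AIC, convergence diagnostics and a
``summary()`` table.

The likelihood of a parameter vector is the product over pokes of the
softmax choice probability of the *observed* next site,
``P(NextLeft | V_t, s_t) = sigmoid(beta (V_t + s_t T))``, with the value
trace V_t computed by running the designated controller forward over the
subject's full poke history (beliefs carried across bouts with the
site-change inversion, and reset at session boundaries: R = 1, V = 0).
The last poke of each session has no observed successor and contributes
no term.

The experiments this toolbox emulates fit no models; the whole fitting
procedure (bounded L-BFGS-B with seeded multi-start, finite-difference
standard errors) is analysis plumbing for simulation-based parameter and
model recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.signal

from . import io
from .agents import IBParams, INFERENCE_BASED, SBParams, STIMULUS_BOUND

_R_CAP = 1e300


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    model : ``"stimulus_bound"`` or ``"inference_based"``.
    fix_env : for the inference-based model, pin (p_rwd_hat, p_sw_hat) to
        the environment probabilities recorded in the log (the optimal
        agent); when False they are free parameters in (0.01, 0.99),
        modelling miscalibrated inference.
    restarts : number of optimizer starts (>= 1), seeded.
    """

    model: str = INFERENCE_BASED
    fix_env: bool = True
    restarts: int = 10
    seed: int = 0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.model not in (STIMULUS_BOUND, INFERENCE_BASED):
            raise ValueError(f"unknown model {self.model!r}")
        if self.restarts < 1:
            raise ValueError("need >= 1 restart")

    @property
    def label(self) -> str:
        return self.name or self.model


class ForagingChoiceModel:
    """Base class: a stay/leave decision sequence plus a likelihood.

    Subclasses define ``param_names``, ``bounds`` and ``values(theta)``
    (the per-poke value trace).  The data are arrays over all pokes of
    one subject, with ``session_starts`` marking reset points.
    """

    param_names: tuple[str, ...] = ()
    bounds: tuple[tuple[float, float], ...] = ()

    def __init__(self, site: np.ndarray, reward: np.ndarray,
                 session_ids: np.ndarray, subject_id: str = "?"):
        self.site = np.asarray(site, dtype=float)
        self.reward = np.asarray(reward, dtype=float)
        self.session_ids = np.asarray(session_ids)
        self.subject_id = subject_id
        n = self.site.size
        if n < 2:
            raise ValueError("need at least two pokes")
        same_session = self.session_ids[:-1] == self.session_ids[1:]
        self.decision_idx = np.flatnonzero(same_session)
        # observed choice: is the *next* poke on the left?
        self.next_left = (self.site[self.decision_idx + 1] > 0).astype(float)
        self.session_starts = np.flatnonzero(
            np.r_[True, self.session_ids[1:] != self.session_ids[:-1]])
        if self.decision_idx.size < 100:
            import warnings
            warnings.warn("fewer than 100 decisions; estimates will be noisy",
                          stacklevel=2)

    # -- construction -------------------------------------------------
    @classmethod
    def from_eventlog(cls, log: pd.DataFrame, subject_id: Optional[str] = None,
                      **kwargs) -> "ForagingChoiceModel":
        """Build from an event log (one subject; sessions concatenated)."""
        df = log
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        elif df["subject_id"].nunique() > 1:
            raise ValueError("log contains several subjects; pass subject_id")
        else:
            subject_id = str(df["subject_id"].iloc[0])
        df = df.sort_values(["session", "poke_in"], kind="stable")
        site = df["site"].map(io.LETTER_TO_SITE).to_numpy() \
            if df["site"].dtype == object else df["site"].to_numpy()
        if cls is InferenceBasedModel and kwargs.get("fix_env", True):
            kwargs.setdefault("p_rwd_hat", float(df["p_rwd"].iloc[0]))
            kwargs.setdefault("p_sw_hat", float(df["p_sw"].iloc[0]))
        return cls(site, df["reward"].to_numpy(),
                   df["session"].to_numpy(), subject_id=subject_id, **kwargs)

    # -- likelihood ---------------------------------------------------
    def values(self, theta: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _beta_T(self, theta: np.ndarray) -> tuple[float, float]:
        return float(theta[-2]), float(theta[-1])

    def nll_per_decision(self, theta: np.ndarray) -> np.ndarray:
        """-log P(observed next site) for each decision poke."""
        beta, T = self._beta_T(theta)
        v = self.values(theta)[self.decision_idx]
        s = self.site[self.decision_idx]
        logits = beta * (v + s * T)
        ll = np.where(self.next_left > 0.5, _log_sigmoid(logits),
                      _log_sigmoid(-logits))
        return -ll

    def nll(self, theta: np.ndarray) -> float:
        """Total negative log-likelihood (+inf on invalid parameters)."""
        try:
            out = float(self.nll_per_decision(theta).sum())
        except (FloatingPointError, ValueError):
            return np.inf
        return out if np.isfinite(out) else np.inf

    # -- fitting ------------------------------------------------------
    def fit(self, restarts: int = 10, seed: int = 0,
            start_params: Optional[Sequence[float]] = None
            ) -> "ForagingFitResults":
        """Best-of-restarts bounded MLE (L-BFGS-B), deterministic by seed."""
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        starts = [np.asarray(start_params, float)] if start_params is not None \
            else [0.5 * (lo + hi)]
        while len(starts) < restarts:
            starts.append(lo + rng.random(lo.size) * (hi - lo))
        records = []
        best = None
        for x0 in starts[:restarts]:
            res = scipy.optimize.minimize(
                self.nll, x0, method="L-BFGS-B", bounds=self.bounds)
            records.append((tuple(res.x), float(res.fun), bool(res.success)))
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(
                f"no optimizer restart converged; trace: {records}")
        restart_df = pd.DataFrame(records, columns=["x", "nll", "converged"])
        params = pd.Series(best.x, index=self.param_names)
        bse = self._standard_errors(best.x, lo, hi)
        return ForagingFitResults(
            model=self, params=params, bse=bse, nll=float(best.fun),
            converged=True, restarts=restart_df,
            n_decisions=int(self.decision_idx.size))

    def _standard_errors(self, x: np.ndarray, lo: np.ndarray, hi: np.ndarray
                         ) -> pd.Series:
        """Finite-difference Hessian SEs; NaN for estimates at a bound."""
        k = x.size
        h = 1e-4 * np.maximum(np.abs(x), 1.0)
        at_bound = (x - lo < 2 * h) | (hi - x < 2 * h)
        hess = np.full((k, k), np.nan)
        f0 = self.nll(x)
        for i in range(k):
            for j in range(i, k):
                if at_bound[i] or at_bound[j]:
                    continue
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    d2 = (self.nll(x + ei) - 2 * f0 + self.nll(x - ei)) / h[i]**2
                else:
                    d2 = (self.nll(x + ei + ej) - self.nll(x + ei - ej)
                          - self.nll(x - ei + ej) + self.nll(x - ei - ej)) \
                        / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = d2
        se = np.full(k, np.nan)
        free = ~at_bound & np.isfinite(hess).all(axis=1)
        if free.any():
            sub = hess[np.ix_(free, free)]
            try:
                cov = np.linalg.pinv(sub)
                diag = np.diag(cov)
                se[free] = np.sqrt(np.where(diag > 0, diag, np.nan))
            except np.linalg.LinAlgError:
                pass
        return pd.Series(se, index=self.param_names)


class StimulusBoundModel(ForagingChoiceModel):
    """Leaky-integrator controller: free (gamma, beta, T), v0 fixed at 0."""

    param_names = ("gamma", "beta", "T")
    bounds = ((1e-3, 1.0), (1e-3, 50.0), (0.0, 5.0))

    def __init__(self, *args, v0: float = 0.0, **kwargs):
        super().__init__(*args, **kwargs)
        self.v0 = v0
        self._signed = self.site * self.reward

    def values(self, theta: np.ndarray) -> np.ndarray:
        gamma = float(theta[0])
        v = np.empty_like(self._signed)
        for start, stop in zip(self.session_starts,
                               np.r_[self.session_starts[1:], self._signed.size]):
            o = self._signed[start:stop]
            seg = scipy.signal.lfilter([gamma], [1.0, -(1.0 - gamma)], o)
            if self.v0 != 0.0:
                seg = seg + self.v0 * (1.0 - gamma) ** np.arange(1, o.size + 1)
            v[start:stop] = seg
        return v


class InferenceBasedModel(ForagingChoiceModel):
    """Hidden-state inference controller.

    With ``fix_env`` (default) the assumed probabilities are pinned and
    the free parameters are (beta, T); otherwise (p_rwd_hat, p_sw_hat,
    beta, T) are all free.  The value trace for a given probability pair
    is cached, so the fixed-environment fit costs one forward pass.
    """

    def __init__(self, *args, p_rwd_hat: float = 0.9, p_sw_hat: float = 0.3,
                 fix_env: bool = True, **kwargs):
        super().__init__(*args, **kwargs)
        self.fix_env = fix_env
        self.p_rwd_hat = float(np.clip(p_rwd_hat, 0.01, 0.99))
        self.p_sw_hat = float(np.clip(p_sw_hat, 0.01, 0.99))
        if fix_env:
            self.param_names = ("beta", "T")
            self.bounds = ((1e-3, 50.0), (0.0, 5.0))
        else:
            self.param_names = ("p_rwd_hat", "p_sw_hat", "beta", "T")
            self.bounds = ((0.01, 0.99), (0.01, 0.99), (1e-3, 50.0), (0.0, 5.0))
        self._cache: dict[tuple[float, float], np.ndarray] = {}

    def _trace(self, p_rwd: float, p_sw: float) -> np.ndarray:
        key = (round(p_rwd, 12), round(p_sw, 12))
        if key in self._cache:
            return self._cache[key]
        site, reward = self.site, self.reward
        n = site.size
        v = np.empty(n)
        starts = set(self.session_starts.tolist())
        R = 1.0
        s_prev = site[0]
        for t in range(n):
            if t in starts:
                R, s_prev = 1.0, site[t]
            ratio = (R + p_sw) / (1.0 - p_sw)
            if site[t] != s_prev:
                ratio = 1.0 / ratio if ratio > 0 else _R_CAP
            if reward[t]:
                R = 0.0
            else:
                R = min(ratio / (1.0 - p_rwd), _R_CAP)
            v[t] = p_rwd * site[t] * ((1.0 - R) / (1.0 + R) if R < 1e12 else -1.0)
            s_prev = site[t]
        if len(self._cache) > 64:
            self._cache.clear()
        self._cache[key] = v
        return v

    def values(self, theta: np.ndarray) -> np.ndarray:
        if self.fix_env:
            return self._trace(self.p_rwd_hat, self.p_sw_hat)
        return self._trace(float(theta[0]), float(theta[1]))


@dataclass
class ForagingFitResults:
    """MLE results for one subject and one controller.

    ``deviance`` is 2 * NLL (logistic convention) and
    ``aic = 2k + 2 * NLL``.  Standard errors are finite-difference
    curvature estimates and are NaN for parameters at a bound.
    """

    model: ForagingChoiceModel
    params: pd.Series
    bse: pd.Series
    nll: float
    converged: bool
    restarts: pd.DataFrame
    n_decisions: int

    @property
    def k(self) -> int:
        return int(self.params.size)

    @property
    def deviance(self) -> float:
        return 2.0 * self.nll

    @property
    def aic(self) -> float:
        return 2.0 * self.k + 2.0 * self.nll

    @property
    def restart_dispersion(self) -> float:
        """Spread of converged restart NLLs (max - min)."""
        vals = self.restarts.loc[self.restarts["converged"], "nll"]
        return float(vals.max() - vals.min()) if len(vals) else np.nan

    def summary(self) -> str:
        name = type(self.model).__name__
        lines = [
            f"{name} fit — subject {self.model.subject_id}",
            f"  decisions: {self.n_decisions}   NLL: {self.nll:.3f}   "
            f"deviance: {self.deviance:.3f}   AIC: {self.aic:.3f}",
            f"  converged: {self.converged}   restart spread: "
            f"{self.restart_dispersion:.2e}",
            f"  {'param':>10} {'estimate':>12} {'std err':>12}",
        ]
        for p in self.params.index:
            se = self.bse[p]
            se_s = f"{se:12.4f}" if np.isfinite(se) else "   (at bound)"
            lines.append(f"  {p:>10} {self.params[p]:12.4f} {se_s}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.summary()


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def _model_for(log: pd.DataFrame, spec: FitSpec,
               subject_id: Optional[str] = None) -> ForagingChoiceModel:
    if spec.model == STIMULUS_BOUND:
        return StimulusBoundModel.from_eventlog(log, subject_id=subject_id)
    return InferenceBasedModel.from_eventlog(
        log, subject_id=subject_id, fix_env=spec.fix_env)


def sequence_nll(log: pd.DataFrame, model: str,
                 params: SBParams | IBParams) -> float:
    """NLL of an event log's stay/leave choices under given parameters."""
    if model == STIMULUS_BOUND:
        if not isinstance(params, SBParams):
            raise TypeError("stimulus_bound takes SBParams")
        m = StimulusBoundModel.from_eventlog(log)
        m.v0 = params.v0
        return m.nll(np.array([params.gamma, params.beta, params.T]))
    if model == INFERENCE_BASED:
        if not isinstance(params, IBParams):
            raise TypeError("inference_based takes IBParams")
        m = InferenceBasedModel.from_eventlog(
            log, fix_env=True, p_rwd_hat=params.p_rwd_hat,
            p_sw_hat=params.p_sw_hat)
        m.p_rwd_hat, m.p_sw_hat = params.p_rwd_hat, params.p_sw_hat
        return m.nll(np.array([params.beta, params.T]))
    raise ValueError(f"unknown model {model!r}")


def fit(log: pd.DataFrame, spec: FitSpec,
        subject_id: Optional[str] = None) -> ForagingFitResults:
    """Fit one controller to one subject's log per the fit specification."""
    m = _model_for(log, spec, subject_id)
    return m.fit(restarts=spec.restarts, seed=spec.seed)


def model_compare(log: pd.DataFrame, specs: Sequence[FitSpec]) -> pd.DataFrame:
    """Fit every spec to every subject; rank by AIC.

    Returns one row per subject x spec with NLL, deviance, AIC and
    ``delta_aic`` (AIC minus the subject's best AIC; 0 marks the
    preferred model).  A pooled block (AICs summed over subjects) is
    appended with subject_id ``"pooled"``.
    """
    if len(specs) < 2:
        raise ValueError("need >= 2 specs to compare")
    rows = []
    for subj in sorted(log["subject_id"].unique()):
        for spec in specs:
            res = fit(log, spec, subject_id=subj)
            rows.append({"subject_id": subj, "model": spec.label,
                         "k": res.k, "nll": res.nll,
                         "deviance": res.deviance, "aic": res.aic})
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df.groupby("subject_id")["aic"].transform("min")
    pooled = (df.groupby("model", sort=False)[["nll", "deviance", "aic"]]
              .sum().reset_index())
    pooled["subject_id"] = "pooled"
    pooled["k"] = df.groupby("model", sort=False)["k"].first().to_numpy()
    pooled["delta_aic"] = pooled["aic"] - pooled["aic"].min()
    return pd.concat([df, pooled], ignore_index=True)
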