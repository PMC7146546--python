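# Methods

## The generative task model

The environment is a two-state hidden Markov model over which of two sites
is active. One poke at the active site draws, independently, a reward
(Bernoulli p_RWD) and a switch (Bernoulli p_SW); the switch takes effect
*after* the outcome, so a rewarded poke can be the last rewarded poke of a
state occupancy. This ordering is forced by the occupancy arithmetic: pokes
per active occupancy are geometric with mean 1/p_SW, each rewarded with
probability p_RWD, so the expected rewards per correct visit equal
p_RWD/p_SW (3 in the medium schedule, 1 in easy and hard). Pokes at the
inactive site pay nothing and never move the state — premature leaving
cannot self-correct; the subject has to travel back. We assume the state
never switches spontaneously between pokes (switches are poke-triggered
only), and the initial active site of a session is drawn uniformly.

Named schedules: easy (0.9, 0.9), medium (0.9, 0.3), hard (0.3, 0.3).
Reward volume per rewarded poke is 6 µl in easy/hard and 2 µl in medium so
that volume × p_RWD/p_SW = 6 µl everywhere.

Event timing is cosmetic for most analyses but exercised by the
time-at-port regressions. Durations are lognormal (shape σ = 0.2) with
means matching the summary statistics of the mouse task: inter-poke
interval 0.16 s, unrewarded poke 0.33 s, travel 1.86 s (2.69 s with a
barrier). The rewarded-poke duration is not a printed quantity; we use
0.45 s on the assumption that drinking lengthens the poke.

## Controllers

**Stimulus-bound.** V_{t+1} = (1−γ) V_t + γ o_{t+1} with o = r·s, V global
across sites (left minus right), v0 = 0 at session start. Defaults:
γ = 0.5, β = 5, T = 0.25. γ = 0.5 was chosen (within the fast-decay half
of the admissible range) because both naive-behavior hallmarks express
there — see "Reset analysis" below; β and T were set to give bout
statistics in the empirical range (roughly 4–9 pokes per bout, a few
trailing failures).

**Inference-based.** Likelihood ratio R for the current site, R = 1
(uniform prior) at session start; per poke one transition-prior
application (R + p̂_SW)/(1 − p̂_SW), inverted when the poke changes site;
reward ⇒ R = 0 exactly, failure ⇒ ×1/(1 − p̂_RWD). Value
V = p̂_RWD·s·(1 − R)/(1 + R). The assumed (p̂_RWD, p̂_SW) default to the
true environment values (the optimal agent) but are settable to model
miscalibrated inference. The closed form for a same-site failure run from
R = 0 is R(t) = p̂_SW·ρ·(ρ^t − 1)/(ρ − 1) with
ρ = 1/((1 − p̂_SW)(1 − p̂_RWD)); this is the unique solution of the
recursion R_{k+1} = ρ(R_k + p̂_SW) and is verified against direct
iteration to 1e−9 relative error in the tests. In the likelihood code R is
capped at 1e300 and the value saturates at −p̂_RWD for R > 1e12 to avoid
overflow; both caps are far beyond any behaviorally distinguishable
regime.

**Policy.** P(NextLeft | V, s) = σ(β(V + sT)); equivalently
P(stay) = σ(β(sV + T)). The stay/leave decision is evaluated after every
poke, including rewarded ones. Decisions are the unit of the likelihood.

## Synthetic cohorts

`generate_cohort` runs closed-loop sessions per subject and day. Learning
is emulated as a per-trial mixture: the inference-based controller acts
with probability w(day), the stimulus-bound controller otherwise; both
internal states update on every poke, so the mixture is coherent. The
default w ramps linearly from 0 (day 1) to 1 (day 8) and stays at 1 — a
schedule knob, not a learned quantity. Sessions default to 60 bouts so the
"50 bouts after the first 10" filter is exactly satisfiable. Barrier
sessions use the longer travel time and a staying bias raised by +0.15
(the normative link between travel cost and leaving threshold); the bonus
is roughly proportional to the relative travel-time increase.

Inactivation is emulated at trial level on a random fraction of trials
(default 0.5): an OFC-like manipulation forces the acting controller to
stimulus-bound (a strategy change); an ACC-like manipulation multiplies T
by 1 + effect_size (default 0.1, matching a ~10% increase in failure
tolerance at hard-schedule baselines); a control manipulation only sets
the flag. Within-trial dynamics of stimulation are deliberately not
modelled.

What the generator does *not* emulate: satiety and motivation drifts,
session-time structure beyond lognormal durations, sub-100 ms invalid
pokes, side biases, or any within-trial stimulation dynamics. Passing
tests therefore demonstrate the internal consistency of the analysis
chain and the discriminability of the two controllers under clean
conditions, not that real animals satisfy the same effect sizes.

## Behavioral statistics

Bouts are maximal same-site poke runs. Filters apply in a fixed order:
drop pokes shorter than 100 ms, re-segment, then per session skip the
first 10 bouts, keep the next 50, and finally exclude zero-reward bouts.
The order matters (a short poke can merge two bouts; exclusion happens
after windowing and is not back-filled) and is locked by a regression
test.

Mixed-effects models with random subject intercepts are approximated by
(i) two-stage estimation — an OLS/GLM per subject, then mean ± SEM and a
one-sample t test across subjects — and (ii) subject fixed effects in
pooled logistic models. The inferential targets here are signs and
orderings, which two-stage estimation preserves; exact REML machinery is
out of scope.

Poke-level leaving models regress leave/stay on the trailing-failure
count and on time-at-port (cumulative time since the bout's first poke,
measured at poke onset — the natural reading, since no operational
definition is printed). "Leaving" means the next valid poke is at the
other site or the session ends; the final bout's last poke counts as an
opportunity by default, with an option to censor it instead. Deviance is
reported as −2·log-likelihood.

The leaving-probability surface is an empirical hazard on a (rewards so
far, trailing failures so far) grid, both axes pooled at their caps
(default 4 rewards, 8 failures), cells with fewer than 10 opportunities
masked. Subtractive normalization centers failure counts on the
within-subject (or within-model) grand mean before group aggregation; the
baseline choice (per-subject default, per-group offered) does not affect
slopes, which are invariant to per-subject centering.

### Reset analysis

The reset hallmark compares failures after a lone reward with failures
before it. Under inference the slope is exactly zero in expectation
(R = 0 after the reward regardless of history). Under the leaky
integrator the textbook argument — later rewards top up a lower port
value, so fewer subsequent failures are tolerated — holds only when the
current site's value is positive on arrival. Closed-loop, the residual
signed value on arrival is typically at or below zero (it is what is left
of the *previous* site's value), which cancels or reverses the effect for
slow decay: simulated slopes are ≈ 0 at γ ≈ 0.3 and reliably negative
only in the fast-decay regime (γ ≈ 0.5) and in the hard schedule, where
pre-reward failure counts actually vary. The package therefore runs this
analysis on hard-schedule cohorts with the γ = 0.5 default — the same
design choice (a lower-reward-probability protocol) made in the original
experiments. This is a known limitation of the leaky-integrator reset
prediction, not of the implementation.

## Model fitting

Fitting is organized statsmodels-style: `StimulusBoundModel` /
`InferenceBasedModel` are built from an event log (one subject; sessions
concatenated with belief/value resets R = 1, V = 0 at session boundaries,
justified by overnight gaps) and `fit()` returns a results object with
estimates, curvature standard errors, NLL/deviance/AIC and a summary
table. The per-decision likelihood is the softmax probability of the
observed next site; the last poke of a session contributes no term.

Free parameters and bounds: SB γ ∈ (0, 1], β ∈ (0, 50], T ∈ [0, 5], v0
pinned at 0; IB default pins (p̂_RWD, p̂_SW) to the environment values
(optimal-agent mode; β, T free), with a free mode over (0.01, 0.99)² as a
stand-in for inference noise. The optimizer is bounded L-BFGS-B with
seeded multi-start (default 10 restarts: mid-bounds plus uniform draws);
the reported fit is the best converged restart and the restart NLL spread
is a diagnostic. Standard errors come from a central-difference Hessian
inverted on the free subspace; estimates within two steps of a bound get
NaN rather than a silently invalid curvature. The SB value trace is
computed with a linear filter; the IB trace is cached per assumed
probability pair, so pinned-mode fits cost a single forward pass.

Validation is generate-then-fit: at 5000 trials, γ recovers within ±0.05
and β within ±15%, and AIC identifies the generating controller
essentially always (margins of hundreds of AIC units). The experiments
this toolbox emulates fit no models to data; the entire fitting procedure
is analysis plumbing validated purely by recovery.

## Problem sizes and numerical choices

The test suite simulates cohorts of 3–20 subjects with 400–10,000 trials
per subject depending on the statistic's variance: 10^5 Monte-Carlo bouts
for occupancy statistics, 10^4 trials per subject for slope hallmarks,
20 × 6 × 400 trials for the schedule/barrier ordering (sign tests need
per-subject consistency, not raw volume), and 16 subjects for the
inactivation contrasts (the per-subject interaction estimate is noisy at
8). Ties and degenerate designs are flagged, not imputed: subjects with a
single reward-number level are excluded from pooled slopes, missing
condition cells are listed, and perfect separation in logistic fits is
reported on the result object.
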