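# patchforage

Simulation and analysis toolbox for a two-site hidden-state foraging task:
the generative task environment, two behavioral controllers (stimulus-bound
and inference-based), the behavioral statistics that discriminate them, and
maximum-likelihood model fitting with parameter-recovery validation.

## The scientific problem

A forager probes one of two reward sites. At any moment exactly one site is
*active*: each poke there is rewarded with probability p_RWD and — after the
poke's outcome — switches the active site with probability p_SW. Pokes at
the inactive site never pay and never move the state, so after a switch the
subject must travel (at a cost) to the other site. The world state is
hidden: the task is a POMDP, and the subject must infer the state from noisy
outcomes. The central asymmetry is that a single reward proves the current
site active, whereas a failure is only partial evidence of a switch.

Two families of strategies make qualitatively different leaving decisions:

- **Stimulus-bound** (leaky integration of outcomes). With site s ∈
  {+1 left, −1 right}, reward r ∈ {0, 1} and signed outcome o = r·s, the
  relative value V = V_LEFT − V_RIGHT evolves as

  V_{t+1} = (1 − γ) V_t + γ o_{t+1}.

  Rewards pile up, so rich bouts delay leaving: the number of consecutive
  failures tolerated before leaving *increases* with the number of rewards.

- **Inference-based** (posterior over the hidden state). The sufficient
  statistic is the likelihood ratio R = P(Inactive)/P(Active) for the
  current site. Per poke, a transition prior is applied
  (R → (R + p_SW)/(1 − p_SW), inverted on a site change), and the outcome
  multiplies in its likelihood: a reward resets R = 0 *exactly*; a failure
  multiplies by 1/(1 − p_RWD). Over t same-site failures after a reward,

  R(t) = p_SW · ρ · (ρ^t − 1)/(ρ − 1),   ρ = 1/((1 − p_SW)(1 − p_RWD)),

  so evidence for leaving grows at rate log ρ per failure — faster in richer
  or more volatile worlds. The value is V = p_RWD · s · (1 − R)/(1 + R).

Both act through a softmax policy with a staying bias T offsetting the
travel cost: P(NextLeft | V, s) = σ(β (V + s·T)).

Because a reward resets the inference, the signature statistics are: the
slope of consecutive failures on reward number (positive for stimulus-bound,
zero under inference), the independence of post-reward failures from
pre-reward failures, and the tuning of failure tolerance to (p_RWD, p_SW)
and to travel cost.

## Worked example

```python
import numpy as np
from patchforage import (EnvParams, IBParams, run_agent, segment_trials,
                         slope_cf_vs_rewards, model_compare, FitSpec)
from patchforage.behavior_analysis import SIM_FILTERS

env = EnvParams.from_protocol("medium")          # p_RWD = 0.9, p_SW = 0.3
log = run_agent("inference_based", IBParams(p_rwd_hat=0.9, p_sw_hat=0.3),
                env, n_trials=2000, rng=np.random.default_rng(0),
                subject_id="demo")

bouts = segment_trials(log, SIM_FILTERS)
slope = slope_cf_vs_rewards(bouts)
print(f"bouts analyzed: {len(bouts)}")
print(f"mean consecutive failures before leaving: "
      f"{bouts['consecutive_failures'].mean():.2f}")
print(f"reward-number slope: {slope.mean:.3f}")

specs = [FitSpec(model="stimulus_bound", restarts=5, seed=0),
         FitSpec(model="inference_based", restarts=5, seed=0)]
table = model_compare(log, specs)
print(table[table.subject_id == "pooled"][["model", "aic", "delta_aic"]]
      .to_string(index=False))
```

prints

```
bouts analyzed: 1654
mean consecutive failures before leaving: 1.15
reward-number slope: -0.004
          model         aic   delta_aic
 stimulus_bound 3772.044795 1321.905678
inference_based 2450.139118    0.000000
```

The simulated inference-based subject tolerates ~1.15 failures before
leaving in the medium schedule, its failure tolerance does not grow with
the number of rewards collected (slope ≈ 0 — the reward-reset hallmark),
and refitting both controllers to its stay/leave choices identifies the
generating model by a wide AIC margin.

A command-line interface wraps the same machinery:

```
patchforage simulate --out-dir cohort --seed 1 --config cohort.yaml
patchforage analyze cohort/events.csv --out-dir analysis
patchforage fit cohort/events.csv --out fits.csv
patchforage recover --out recovery.csv
```

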