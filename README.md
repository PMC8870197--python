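# cgbg — a coarse-grained basal-ganglia model for reinforcement-learning tasks

`cgbg` is a small, fully tested simulator of action selection and dopamine-driven
learning in the basal ganglia (BG), aimed at computational-psychiatry and
cognitive-neuroscience work where the canonical probabilistic learning tasks
(probabilistic selection, probabilistic reversal learning, instructed
probabilistic selection) need a mechanistic, inspectable agent rather than an
abstract Q-learner.  Every anatomical station is one rate unit per stimulus, so
the whole signal flow of a trial can be read off a single state snapshot.

## The model

Stimuli are abstract indices; presenting stimulus *i* sets the binary input
unit `y_in_i = 1`.  The striatum holds one **Go** (D1) and one **NoGo** (D2)
unit per stimulus.  Unit activities are squashed through

```
phi(x) = exp(-a * (1 - x)^2),        a = 8
```

a sigmoid-like bump that is strictly increasing for `x <= 1` with maximum 1 at
`x = 1`.  One phase of a trial is a feed-forward sweep:

```
striatum:  y_k^stria = phi( w_k^snc * y^snc_k  +  sum_i w_ik^stria y_i^in  [+ w^pfc_stria] )
GPe:       y_k^gpe   = 1 - y_k^striaNoGo
GPi:       y_k^gpi   = max(1 - y_k^striaGo/2 - y_k^gpe/2, 0)
thalamus:  y_k^thal  = 1 - y_k^gpi
PMC:       x_k^pmc   = y_k^thal/2 + (sum_i w_ik^pmc y_i^in)/2  [+ w^pfc_pmc]
           x <- x / max(x)   if max(x) > 1;       y_k^pmc = phi(x_k^pmc)
```

and the choice is the presented stimulus with the largest premotor (PMC)
activity.  `w_k^snc` is +1 for Go and −1 for NoGo units, and `y^snc` is the
dopaminergic SNc signal: each trial runs a **minus phase** under tonic
dopamine (the decision) and a **plus phase** in which the chosen stimulus's
Go/NoGo units receive a phasic **burst** after reward or **dip** after
punishment.  By default the SNc unit reports the phasic *deviation* from
baseline (dip/tonic/burst = −0.5/0/+0.5); the absolute coding (0/0.5/1) is
available via `ModelParams.with_absolute_da()` (see `docs/methods.md` for why
the deviation coding is the default).

Learning is contrastive ("plus minus minus"):

```
dy_k   = y_k(plus) - y_k(minus)                     (striatum and PMC)
w_ik  <- max(w_ik + alpha * y_i^in * dy_k, 0)       alpha = 0.1
w     <- beta * w                                   beta  = 0.98  (forgetting)
```

Weights start from a Gaussian N(0.05, 0.01) clipped at zero, so the network
holds 3N² nonnegative learnable weights for N stimuli.  An optional PFC/HC
unit injects an instruction bias (weight 0.3 onto the instructed Go unit,
0.05 onto its PMC unit) for the instructed task.

## Worked example

Run the single-pair demonstration task (stimulus 0 rewarded 90% of the time,
stimulus 1 20%, ten trials) and inspect the behavior:

```bash
$ cgbg run --config configs/pst_demo.yaml --out runs/demo
$ cgbg metrics --trace-dir runs/demo/seed_1
{
  "punishment_count": 5,
  "switch_latencies": null,
  "adherence_duration": null,
  "first_sustained_better_trial": 6,
  "commitment_trial": 6,
  "punishments_before_commitment": 4
}
```

With seed 1 the network starts out preferring the worse stimulus (its random
initial weights favor it), collects four punishments, and from trial 6 on
commits permanently to the better stimulus — `commitment_trial: 6` marks the
start of that terminal run.  `trials.csv` holds the per-trial record
(pair, contingencies, side, choice, reward) and `weights.csv` the full weight
trajectories including the trial-0 initial values.

Replicating the reversal task (0.9/0.2 contingencies swapped every 20 trials
for 100 trials) over 200 seeds:

```bash
$ cgbg replicates --config configs/reversal.yaml --seeds 0:200 --out runs/rev
                       metric  median   q25   q75   n
                     accuracy    0.73  0.69  0.77 200
             punishment_count   27.00 23.00 31.00 200
             switch_latency_1    7.00  5.00 10.00 200
             switch_latency_2    5.00  4.00  8.00 200
             switch_latency_3    4.50  4.00  8.00 200
             switch_latency_4    4.00  3.00  5.00 189
```

The first reversal is the slowest to recover from (median 7 trials before the
newly better stimulus becomes the sustained choice) because the weights
supporting the old preference are at their peak; later reversals switch
faster — the qualitative signature of reversal learning in this circuit.
`cgbg snapshot --trial 1 --phase minus --out state.json` dumps every unit's
activity for a trial as JSON, the machine-readable version of a
network-state diagram.

The same protocols are available programmatically:

```python
from cgbg import ModelParams, make_reversal, run_session, compute_metrics
trace = run_session(make_reversal(), ModelParams(), seed=1)
print(compute_metrics(trace).switch_latencies)
```

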