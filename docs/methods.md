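# Methods

## Model

The simulator is a coarse-grained rate model of the basal ganglia: every
anatomical station (input cortex, striatal D1/Go and D2/NoGo populations,
GPe, GPi, thalamus, premotor cortex, SNc dopamine source, optional PFC/HC
instruction source) is represented by one unit per stimulus, each unit
standing for the mean firing rate of a population.  A trial is two static
feed-forward sweeps — no within-trial temporal dynamics.  The
premotor–thalamus "loop" is resolved as a single pass (thalamus first, then
PMC); no fixed-point iteration is performed, because the layer equations are
defined as a one-shot calculation.  The decision is the argmax of PMC
activity restricted to the stimuli actually on the screen; since the
activation function is strictly increasing below 1 and preactivations are
renormalized to at most 1, the argmax over activities and over
preactivations coincide.  Exact ties (probability zero under Gaussian
initialization) break toward the lowest stimulus index, for reproducibility.

Side-of-screen assignment is sampled and stored per trial but never enters
the dynamics: the input layer codes stimulus identity, not screen position.

## Dopamine coding

The SNc unit takes three values: a dip after punishment, a tonic value
during decisions, a burst after reward, routed in the plus phase only to the
chosen stimulus's Go and NoGo units (all other striatal units keep the tonic
value, so their plus/minus difference — and hence their dopamine-driven
learning — is exactly zero).  The striatal drive is `w_snc * y_snc` with
`w_snc = +1` (Go) / −1 (NoGo).

The default levels are **deviation-coded**: dip/tonic/burst = −0.5/0/+0.5,
i.e. the SNc unit reports the phasic departure from baseline and contributes
nothing at tonic.  The alternative **absolute** coding (0/0.5/1,
`ModelParams.with_absolute_da()`) makes the tonic level itself drive the
striatum (+0.5 to every Go, −0.5 to every NoGo unit).  The deviation coding
is the default because under the absolute coding the NoGo pathway cannot
learn at all: a punishment dip moves a NoGo unit's preactivation from
`s − 0.5` to `s`, and with initial drives `s ≈ 0.1` both activities are of
order `exp(−8·0.8²) ≈ 3·10⁻³`, an increment that multiplicative forgetting
erases.  Simulation confirms the consequences — with absolute coding the
misleadingly instructed network never abandons the instruction and the
ten-trial demonstration task is learned by only ~70% of seeds, whereas
deviation coding yields robust punishment-driven avoidance, reversal
adaptation, and instruction unlearning.  A third reading (NoGo units seeing
the mirrored dopamine level `1 − y_snc`) was evaluated and rejected on the
same behavioral grounds.

## Parameters

| parameter | default | units / range | role |
|---|---|---|---|
| `a` | 8 | dimensionless, > 0 | sharpness of `phi(x) = exp(−a(1−x)²)`; the learnable weights compensate for moderate changes |
| `lr_striatum`, `lr_pmc` | 0.1 | weight per unit activity difference | learning speed; same value for rewards and punishments |
| `beta` | 0.98 | per trial, (0, 1] | forgetting; half-life ln2 / ln(1/β) ≈ 34 trials |
| `w_pfc_stria` | 0.3 | preactivation units | instruction bias on the instructed Go unit |
| `w_pfc_pmc` | 0.05 | preactivation units | instruction bias on the instructed PMC unit |
| `snc_dip/tonic/burst` | −0.5 / 0 / +0.5 | preactivation units | dopamine levels (deviation coding; see above) |
| `init_mean`, `init_var` | 0.05, 0.01 | weight units | Gaussian weight initialization, clipped at 0 |
| `presynaptic_gating` | True | — | delta-rule update gated by the presynaptic input |

Two documented source values conflict for `w_pfc_pmc` (0.05 vs 0.3).  The
default is 0.05: sweeping the parameter shows a bifurcation near ≈ 0.13
above which the misleading instruction becomes permanently inescapable (the
PFC drive on the PMC preactivation exceeds anything the unchosen pathway can
build), and at 0.05 instruction unlearning is robust and stable across
seeds.  Values near the bifurcation (≈ 0.12–0.13) stretch the median
unlearning time toward ~19 trials but leave roughly half the replicates
misled forever, with replicate medians that are unstable from batch to
batch; they are available through the config for exactly that kind of
sensitivity analysis, but make a poor default.

The delta-rule update is gated by the presynaptic input (weights from
stimuli absent on a trial are untouched), so stimulus-specific associations
survive trials on which their pair is not shown except for global
forgetting, which is applied once per trial to all learnable weights.  The
ungated variant (`presynaptic_gating=False`) applies every unit's delta to
all of its incoming weights.  Negative initial draws and negative update
results are clipped to zero — the model assumes nonnegative synaptic
weights throughout.

Trial order within a session: minus phase → decision → feedback → plus
phase → delta-rule update → forgetting.  One RNG stream per session,
consumed in a fixed order (weight init; then per trial: pair, side,
feedback), so adding readouts never changes trajectories.

## Task protocols

* **Probabilistic selection** (`make_pst`): fixed stimulus pairs with reward
  contingencies, uniform i.i.d. pair order by default (a shuffled-block
  scheduler bounding the gap between appearances of a pair is available via
  `pair_sampling="shuffled_blocks"`).  Canonical composition: 80/20, 70/30,
  60/40; the single-pair 0.9/0.2 ten-trial variant serves as the
  demonstration task.
* **Probabilistic reversal learning** (`make_reversal`): one pair whose
  contingencies swap every `block` trials.  "After the first 20 trials" is
  implemented as: trials 1–20 run pre-reversal, the swap takes effect at
  trial 21 (and 41, 61, 81 with the defaults).
* **Instructed probabilistic selection** (`make_instructed`): the single
  pair plus a PFC/HC unit biasing one stimulus (by default the worse one,
  emulating a misleading instruction) on every trial where that stimulus is
  shown, identically in both phases.

Feedback is Bernoulli in the chosen stimulus's current contingency.

## Behavioral readouts

* **Sustained-switch latency** after a reversal effective at trial r+1: the
  smallest t ≥ 1 such that the choice at trial r+t is the newly better
  stimulus *and* that stimulus is the majority choice over the following
  min(5, trials remaining) trials.  The source narrative never defines its
  switch criterion; this operationalization is deliberately strict about
  transient flips.
* **Adherence duration**: length of the initial unbroken run of
  instructed-stimulus choices.
* **Commitment trial / punishments before commitment**: start of the
  terminal unbroken run of better-stimulus choices, and the punishments
  accumulated before it.
* Replicate-level summaries use medians and quartiles (switch latencies
  have a heavy right tail, and censored values — replicates that never
  switch — make means meaningless).  Censoring values are stated where
  used (20 trials for within-block reversal latencies, n_trials + 1 for
  never-recovering instructed sessions).

## Numerical choices

Activities are float64 throughout; the only clamps are the GPi floor at 0
and the weight floor at 0, both part of the model.  CSV/JSON serialization
uses 9 significant digits, enough for exact round-trips of every quantity
the tables carry at this model's dynamic range.  Config validation rejects
unknown keys and out-of-range values by name.

## What the simulations do and do not show

The replicate harness runs 200 seeded sessions per protocol (sizes chosen
so the full suite and the acceptance script run in seconds on one core;
medians are stable to within ±1 trial across independent 200-seed batches
except where noted).  The simulated agent reproduces the qualitative
signatures of the three tasks: reliable acquisition of the better stimulus
within ten trials (>90% of seeds), slower switching after the first
reversal than after later ones, first-trial obedience to a misleading
instruction followed by recovery.

Two quantitative caveats.  First, published single-run values for these
protocols are individual stochastic trajectories; replicate medians need
not and do not match them exactly — in particular the instructed task's
unlearning here is faster (median adherence ≈ 6 trials, recovery from
trial ≈ 7) than the ~19-trial single run reported for this protocol.  Under
every reading of the layer equations we evaluated, escape times are
bimodal: networks either escape within ~6–8 trials or never, so a ~19-trial
sustained adherence is attainable only as a tail event or near the
`w_pfc_pmc` bifurcation, where behavior is degenerate (see above).  Second,
the agent is deterministic given its weights — all behavioral variability
comes from initialization and feedback sampling, not from choice noise, so
human-like exploration variance is outside the model.  The generator also
idealizes real experiments in other ways (no reaction times, no lapses, no
stimulus confusion, side of screen decoupled from learning), so passing
tests validate the mechanism, not fit to any particular human dataset.
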