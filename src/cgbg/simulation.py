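"""The trial loop, replicate harness and behavioral readouts.

``run_session`` ties the pieces together: initialize weights from a seed,
then for each trial run the minus phase (decision under tonic dopamine),
draw feedback, run the plus phase (phasic dopamine on the chosen
stimulus's striatal units), apply the contrastive weight update and the
forgetting decay.  One RNG stream per session, consumed in a fixed order
(weight init, then per trial: pair, side, feedback), so adding readouts
never perturbs trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import NetworkWeights, PhaseState, run_phase
from .params import ModelParams
from .plasticity import apply_forgetting, apply_update, init_weights, phase_difference
from .tasks import Feedback, StimulusPair, TaskSpec, sample_feedback, sample_trial, shuffled_block_schedule

__all__ = [
    "TrialRecord",
    "SessionTrace",
    "BehaviorMetrics",
    "run_trial",
    "run_session",
    "run_replicates",
    "compute_metrics",
    "metrics_from_series",
]

#: Trials a candidate switch must dominate to count as sustained.
SUSTAIN_HORIZON = 5


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    pair: StimulusPair  # contingencies current at this trial
    side: int
    chosen: int
    rewarded: bool
    minus_state: PhaseState
    plus_state: PhaseState
    weights_before: NetworkWeights  # weights in force during both phases
    weights_after: NetworkWeights  # after the delta-rule update and forgetting


@dataclass(frozen=True)
class SessionTrace:
    spec: TaskSpec
    params: ModelParams
    seed: int
    initial_weights: NetworkWeights
    records: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) != self.spec.n_trials:
            raise ValueError("trace length must equal spec.n_trials")

    @property
    def choices(self) -> np.ndarray:
        return np.array([r.chosen for r in self.records])

    @property
    def rewards(self) -> np.ndarray:
        return np.array([r.rewarded for r in self.records])


@dataclass(frozen=True)
class BehaviorMetrics:
    """Per-session behavioral readouts.

    Metrics that need a feature the task lacks (reversals, instruction) are
    ``None``.  ``switch_latencies`` holds, per reversal, the number of
    trials until the newly better stimulus becomes the sustained choice
    (``None`` for a reversal never followed by a sustained switch).
    """

    choices: np.ndarray
    rewarded: np.ndarray
    punishment_count: int
    switch_latencies: Optional[tuple]
    adherence_duration: Optional[int]
    first_sustained_better_trial: Optional[int]
    commitment_trial: Optional[int]
    punishments_before_commitment: Optional[int]


def run_trial(
    weights: NetworkWeights,
    params: ModelParams,
    spec: TaskSpec,
    trial_index: int,
    rng: np.random.Generator,
    schedule: Optional[Sequence[int]] = None,
) -> TrialRecord:
    """One complete trial: minus phase, feedback, plus phase, learning."""
    pair, side = sample_trial(spec, trial_index, rng, schedule)
    y_in = np.zeros(spec.n_stimuli)
    y_in[[pair.first, pair.second]] = 1.0

    pfc_stim = spec.instruction if spec.instruction in pair.members else None
    y_pfc = 1 if pfc_stim is not None else 0

    minus = run_phase(weights, params, y_in, pfc_stimulus=pfc_stim, y_pfc=y_pfc)
    feedback = sample_feedback(pair, minus.chosen, params, rng)
    plus = run_phase(
        weights,
        params,
        y_in,
        phasic_level=feedback.snc_level,
        chosen=minus.chosen,
        pfc_stimulus=pfc_stim,
        y_pfc=y_pfc,
    )
    delta = phase_difference(minus, plus)
    new_weights = apply_forgetting(apply_update(weights, delta, y_in, params), params)
    return TrialRecord(
        trial_index=trial_index,
        pair=pair,
        side=side,
        chosen=minus.chosen,
        rewarded=feedback.rewarded,
        minus_state=minus,
        plus_state=plus,
        weights_before=weights.copy(),
        weights_after=new_weights,
    )


def run_session(spec: TaskSpec, params: ModelParams, seed: int) -> SessionTrace:
    """A full seeded session: weight init followed by ``spec.n_trials`` trials."""
    rng = np.random.default_rng(seed)
    weights = init_weights(spec.n_stimuli, params, rng)
    initial = weights.copy()
    schedule = (
        shuffled_block_schedule(spec, rng)
        if spec.pair_sampling == "shuffled_blocks"
        else None
    )
    records = []
    for t in range(1, spec.n_trials + 1):
        record = run_trial(weights, params, spec, t, rng, schedule)
        records.append(record)
        weights = record.weights_after
    return SessionTrace(
        spec=spec, params=params, seed=int(seed), initial_weights=initial, records=tuple(records)
    )


def run_replicates(
    spec: TaskSpec, params: ModelParams, seeds: Sequence[int]
) -> list[SessionTrace]:
    """Independent sessions, one per seed."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds: replicate sessions will not be independent")
    return [run_session(spec, params, s) for s in seeds]


def _better_series(trace: SessionTrace) -> np.ndarray:
    """Per trial, the member of the shown pair with the higher current contingency."""
    return np.array([r.pair.better() for r in trace.records])


def _first_sustained(
    choices: np.ndarray, better: np.ndarray, start: int, horizon: int = SUSTAIN_HORIZON
) -> Optional[int]:
    """First 0-based index >= start where the currently-better stimulus is
    chosen and remains the majority choice over the following
    ``min(horizon, trials remaining)`` trials (an empty window counts)."""
    n = len(choices)
    for t in range(start, n):
        if choices[t] != better[t]:
            continue
        end = min(n, t + 1 + horizon)
        hits = sum(1 for u in range(t + 1, end) if choices[u] == better[u])
        if end == t + 1 or 2 * hits > (end - t - 1):
            return t
    return None


def metrics_from_series(
    choices: np.ndarray,
    rewarded: np.ndarray,
    better: np.ndarray,
    reversal_trials: Sequence[int] = (),
    instruction: Optional[int] = None,
) -> BehaviorMetrics:
    """Behavioral summary from raw per-trial series.

    * ``switch_latencies`` — for each reversal taking effect at trial r+1,
      the smallest t >= 1 such that the choice at trial r+t is the newly
      better stimulus and stays the majority choice over the next
      ``SUSTAIN_HORIZON`` trials.
    * ``adherence_duration`` — length of the initial run of trials on which
      the instructed stimulus was chosen (0 if the first choice already
      deviates).
    * ``first_sustained_better_trial`` — 1-based trial starting the first
      sustained preference for the better stimulus.
    * ``commitment_trial`` / ``punishments_before_commitment`` — start of
      the terminal unbroken run of better-stimulus choices and the number
      of punishments collected before it.
    """
    choices = np.asarray(choices)
    rewarded = np.asarray(rewarded, dtype=bool)
    better = np.asarray(better)
    n = len(choices)

    switch_latencies: Optional[tuple] = None
    if reversal_trials:
        lats = []
        for r_eff in reversal_trials:
            r = r_eff - 1  # last trial under the old contingencies (1-based)
            t0 = _first_sustained(choices, better, start=r_eff - 1)
            lats.append(None if t0 is None else (t0 + 1) - r)
        switch_latencies = tuple(lats)

    adherence: Optional[int] = None
    if instruction is not None:
        adherence = 0
        for c in choices:
            if c != instruction:
                break
            adherence += 1

    t0 = _first_sustained(choices, better, start=0)
    first_sustained = None if t0 is None else t0 + 1

    commitment: Optional[int] = None
    punish_before: Optional[int] = None
    if choices[n - 1] == better[n - 1]:
        last_bad = -1
        for t in range(n - 1, -1, -1):
            if choices[t] != better[t]:
                last_bad = t
                break
        commitment = last_bad + 2  # 1-based first trial of the terminal run
        punish_before = int(np.sum(~rewarded[: last_bad + 1]))

    return BehaviorMetrics(
        choices=choices,
        rewarded=rewarded,
        punishment_count=int(np.sum(~rewarded)),
        switch_latencies=switch_latencies,
        adherence_duration=adherence,
        first_sustained_better_trial=first_sustained,
        commitment_trial=commitment,
        punishments_before_commitment=punish_before,
    )


def compute_metrics(trace: SessionTrace) -> BehaviorMetrics:
    """Behavioral summary of one session (see ``metrics_from_series``)."""
    return metrics_from_series(
        trace.choices,
        trace.rewards,
        _better_series(trace),
        reversal_trials=trace.spec.reversal_trials,
        instruction=trace.spec.instruction,
    )
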