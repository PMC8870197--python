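"""Task protocols: probabilistic selection, reversal learning, instructed choice.

A task is a set of abstract stimuli grouped into fixed pairs, each stimulus
carrying a reward contingency (probability of positive feedback when
chosen).  On every trial one pair is shown, the agent picks a member, and
binary feedback is drawn from the chosen stimulus's contingency.  Reversal
tasks swap the contingencies within each pair at scheduled trials; the
instructed task adds a PFC/HC bias toward one (misleadingly recommended)
stimulus.  Side-of-screen assignment is recorded as metadata only — the
input layer codes stimulus identity, not position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "StimulusPair",
    "TaskSpec",
    "Feedback",
    "DEFAULT_PST_CONTINGENCIES",
    "make_pst",
    "make_reversal",
    "make_instructed",
    "active_pair",
    "sample_trial",
    "sample_feedback",
    "shuffled_block_schedule",
]

#: The canonical three-pair probabilistic selection composition:
#: AB 80/20, CD 70/30, EF 60/40.
DEFAULT_PST_CONTINGENCIES: tuple = ((0.8, 0.2), (0.7, 0.3), (0.6, 0.4))


@dataclass(frozen=True)
class StimulusPair:
    first: int
    second: int
    p_first: float
    p_second: float

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("pair members must be distinct stimuli")
        if self.first < 0 or self.second < 0:
            raise ValueError("stimulus indices must be nonnegative")
        for p in (self.p_first, self.p_second):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"reward probability {p} outside [0, 1]")

    @property
    def members(self) -> tuple:
        return (self.first, self.second)

    def contingency_of(self, stimulus: int) -> float:
        if stimulus == self.first:
            return self.p_first
        if stimulus == self.second:
            return self.p_second
        raise ValueError(f"stimulus {stimulus} is not a member of pair {self.members}")

    def swapped(self) -> "StimulusPair":
        """The pair with its contingencies exchanged (one reversal)."""
        return replace(self, p_first=self.p_second, p_second=self.p_first)

    def better(self) -> int:
        """Member with the higher contingency (lower index on a tie)."""
        return self.first if self.p_first >= self.p_second else self.second


@dataclass(frozen=True)
class TaskSpec:
    n_stimuli: int
    pairs: tuple
    n_trials: int
    reversal_trials: tuple = ()
    instruction: Optional[int] = None
    pair_sampling: str = "uniform"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        object.__setattr__(self, "reversal_trials", tuple(self.reversal_trials))
        if not self.pairs:
            raise ValueError("a task needs at least one stimulus pair")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for pair in self.pairs:
            for s in pair.members:
                if s >= self.n_stimuli:
                    raise ValueError(
                        f"stimulus {s} out of range for n_stimuli={self.n_stimuli}"
                    )
        rev = self.reversal_trials
        if any(b <= a for a, b in zip(rev, rev[1:])):
            raise ValueError("reversal_trials must be strictly increasing")
        if rev and not (1 <= rev[0] and rev[-1] <= self.n_trials):
            raise ValueError("reversal_trials must lie within 1..n_trials")
        if self.instruction is not None:
            if not any(self.instruction in p.members for p in self.pairs):
                raise ValueError(
                    f"instructed stimulus {self.instruction} occurs in no pair"
                )
        if self.pair_sampling not in ("uniform", "shuffled_blocks"):
            raise ValueError(f"unknown pair_sampling mode {self.pair_sampling!r}")


@dataclass(frozen=True)
class Feedback:
    rewarded: bool
    snc_level: float


def make_pst(
    contingencies: Optional[Sequence] = None,
    n_trials: int = 60,
    pair_sampling: str = "uniform",
) -> TaskSpec:
    """Probabilistic selection task: fixed pairs, no reversals, no instruction.

    ``contingencies`` is a list of (p_first, p_second) tuples, one per pair;
    pair j uses stimuli 2j and 2j+1.  Defaults to the three-pair AB/CD/EF
    composition.  The single-pair 0.9/0.2 demonstration is
    ``make_pst([(0.9, 0.2)], n_trials=10)``.
    """
    if contingencies is None:
        contingencies = DEFAULT_PST_CONTINGENCIES
    contingencies = list(contingencies)
    if not contingencies:
        raise ValueError("need at least one pair of contingencies")
    pairs = tuple(
        StimulusPair(2 * j, 2 * j + 1, float(p1), float(p2))
        for j, (p1, p2) in enumerate(contingencies)
    )
    return TaskSpec(
        n_stimuli=2 * len(pairs),
        pairs=pairs,
        n_trials=n_trials,
        pair_sampling=pair_sampling,
    )


def make_reversal(
    p_first: float = 0.9,
    p_second: float = 0.2,
    block: int = 20,
    n_trials: int = 100,
) -> TaskSpec:
    """Reversal learning: one pair whose contingencies swap every ``block`` trials.

    With the defaults (0.9/0.2, block 20, 100 trials) the swapped
    contingencies take effect on trials 21, 41, 61 and 81.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    if block > n_trials:
        raise ValueError(f"block ({block}) cannot exceed n_trials ({n_trials})")
    reversal_trials = tuple(range(block + 1, n_trials + 1, block))
    return TaskSpec(
        n_stimuli=2,
        pairs=(StimulusPair(0, 1, p_first, p_second),),
        n_trials=n_trials,
        reversal_trials=reversal_trials,
    )


def make_instructed(
    p_first: float = 0.9,
    p_second: float = 0.2,
    instructed: int = 1,
    n_trials: int = 30,
) -> TaskSpec:
    """Instructed selection: single pair plus a PFC/HC bias toward one stimulus.

    By default the instruction (mis)recommends the worse, 20%-rewarded
    stimulus, as in the misleading-instruction condition.
    """
    if instructed not in (0, 1):
        raise ValueError("instructed stimulus must be a member of the pair (0 or 1)")
    return TaskSpec(
        n_stimuli=2,
        pairs=(StimulusPair(0, 1, p_first, p_second),),
        n_trials=n_trials,
        instruction=instructed,
    )


def active_pair(spec: TaskSpec, pair: StimulusPair, trial_index: int) -> StimulusPair:
    """The pair with the contingencies in force at ``trial_index`` (1-based).

    Each scheduled reversal at or before the trial swaps the contingencies;
    an even number of swaps restores the original assignment.
    """
    n_rev = sum(1 for r in spec.reversal_trials if r <= trial_index)
    return pair.swapped() if n_rev % 2 else pair


def sample_trial(
    spec: TaskSpec,
    trial_index: int,
    rng: np.random.Generator,
    schedule: Optional[Sequence[int]] = None,
) -> tuple[StimulusPair, int]:
    """Draw the pair and screen side for one trial.

    Returns ``(pair, side)`` where the pair carries the contingencies
    current at ``trial_index`` and ``side`` is 0 if the first member is on
    the left, 1 otherwise (metadata only; it never enters the dynamics).
    With a precomputed ``schedule`` (bounded-gap sampling) the pair comes
    from the schedule and only the side is drawn; otherwise the pair is
    uniform i.i.d. over the task's pairs.
    """
    if not (1 <= trial_index <= spec.n_trials):
        raise ValueError(f"trial_index {trial_index} outside 1..{spec.n_trials}")
    if schedule is not None:
        pair_idx = int(schedule[trial_index - 1])
    else:
        pair_idx = int(rng.integers(len(spec.pairs)))
    side = int(rng.integers(2))
    return active_pair(spec, spec.pairs[pair_idx], trial_index), side


def shuffled_block_schedule(spec: TaskSpec, rng: np.random.Generator) -> np.ndarray:
    """Pair indices for all trials, shuffled within consecutive blocks.

    Every block of ``len(pairs)`` trials contains each pair exactly once, so
    the gap between two appearances of a pair is at most ``2*len(pairs) - 1``
    trials.
    """
    k = len(spec.pairs)
    n_blocks = -(-spec.n_trials // k)
    seq = np.concatenate([rng.permutation(k) for _ in range(n_blocks)])
    return seq[: spec.n_trials]


def sample_feedback(
    pair: StimulusPair,
    chosen: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> Feedback:
    """Bernoulli feedback from the chosen stimulus's contingency.

    Reward triggers an SNc burst in the upcoming plus phase; punishment a dip.
    """
    p = pair.contingency_of(chosen)
    rewarded = bool(rng.random() < p)
    return Feedback(
        rewarded=rewarded,
        snc_level=params.snc_burst if rewarded else params.snc_dip,
    )
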