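"""Forward dynamics of the coarse-grained basal-ganglia network.

One "phase" is a single deterministic feed-forward sweep
input -> striatum -> GPe -> GPi -> thalamus -> PMC -> output.  Each layer
unit summarizes the mean firing rate of a population; activities live in
[0, 1].  The striatum is split into N Go (D1) units followed by N NoGo (D2)
units; the SNc dopamine unit drives Go units with weight +1 and NoGo units
with weight -1.  A trial consists of two phases: a *minus* phase (tonic
dopamine, the network decides) and a *plus* phase (phasic dopamine —
burst after reward, dip after punishment — delivered only to the chosen
stimulus's Go/NoGo units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "NetworkWeights",
    "PhaseState",
    "phi",
    "striatum_activity",
    "gpe_activity",
    "gpi_activity",
    "thalamus_activity",
    "pmc_activity",
    "decide",
    "snc_vector",
    "run_phase",
]


def phi(x, a: float):
    """Activation function ``phi(x) = exp(-a * (1 - x)**2)``.

    A bump-shaped squashing function with maximum 1 at ``x = 1``; strictly
    increasing for ``x <= 1`` and symmetric about 1.  Maps any real
    preactivation into (0, 1].
    """
    if a <= 0:
        raise ValueError(f"activation shape a must be positive, got {a}")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite preactivation passed to phi")
    out = np.exp(-a * (1.0 - arr) ** 2)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class NetworkWeights:
    """Learnable input->striatum and input->PMC weights plus fixed SNc signs.

    ``w_in_stria`` has shape (N, 2N): column k < N feeds the Go unit of
    stimulus k, column N + k the NoGo unit.  ``w_in_pmc`` has shape (N, N).
    ``w_snc_stria`` is the fixed +1/-1 sign vector of length 2N.
    """

    n_stimuli: int
    w_in_stria: np.ndarray
    w_in_pmc: np.ndarray
    w_snc_stria: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_stimuli
        if n < 1:
            raise ValueError("n_stimuli must be >= 1")
        if self.w_snc_stria is None:
            object.__setattr__(self, "w_snc_stria", default_snc_signs(n))
        object.__setattr__(self, "w_in_stria", np.asarray(self.w_in_stria, dtype=float))
        object.__setattr__(self, "w_in_pmc", np.asarray(self.w_in_pmc, dtype=float))
        object.__setattr__(self, "w_snc_stria", np.asarray(self.w_snc_stria, dtype=float))
        if self.w_in_stria.shape != (n, 2 * n):
            raise ValueError(
                f"w_in_stria must have shape {(n, 2 * n)}, got {self.w_in_stria.shape}"
            )
        if self.w_in_pmc.shape != (n, n):
            raise ValueError(
                f"w_in_pmc must have shape {(n, n)}, got {self.w_in_pmc.shape}"
            )
        if np.any(self.w_in_stria < 0) or np.any(self.w_in_pmc < 0):
            raise ValueError("learnable weights must be nonnegative")
        if self.w_snc_stria.shape != (2 * n,):
            raise ValueError(f"w_snc_stria must have shape {(2 * n,)}")
        if not (
            np.all(self.w_snc_stria[:n] == 1.0) and np.all(self.w_snc_stria[n:] == -1.0)
        ):
            raise ValueError("w_snc_stria must be +1 for Go units, -1 for NoGo units")

    @property
    def n_learnable(self) -> int:
        """Number of learnable weights: 2N^2 + N^2 = 3N^2."""
        return self.w_in_stria.size + self.w_in_pmc.size

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.n_stimuli,
            self.w_in_stria.copy(),
            self.w_in_pmc.copy(),
            self.w_snc_stria.copy(),
        )


def default_snc_signs(n_stimuli: int) -> np.ndarray:
    return np.concatenate([np.ones(n_stimuli), -np.ones(n_stimuli)])


@dataclass(frozen=True)
class PhaseState:
    """All layer activities from one feed-forward sweep."""

    phase: str  # "minus" or "plus"
    y_in: np.ndarray
    y_pfc: int
    instructed_index: Optional[int]
    y_snc_per_unit: np.ndarray
    y_stria: np.ndarray
    y_gpe: np.ndarray
    y_gpi: np.ndarray
    y_thal: np.ndarray
    x_pmc: np.ndarray
    y_pmc: np.ndarray
    y_out: np.ndarray
    chosen: int

    @property
    def presented(self) -> tuple:
        return tuple(int(i) for i in np.flatnonzero(self.y_in))

    @property
    def y_stria_go(self) -> np.ndarray:
        n = len(self.y_in)
        return self.y_stria[:n]

    @property
    def y_stria_nogo(self) -> np.ndarray:
        n = len(self.y_in)
        return self.y_stria[n:]


def _check_vector(name: str, v: np.ndarray, length: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (length,):
        raise ValueError(f"{name} must have shape {(length,)}, got {v.shape}")
    return v


def striatum_activity(
    weights: NetworkWeights,
    params: ModelParams,
    y_in: np.ndarray,
    y_snc_per_unit: np.ndarray,
    pfc_go_index: Optional[int] = None,
    y_pfc: int = 0,
) -> np.ndarray:
    """Activity of the 2N striatal units.

    Each unit k sees its SNc drive ``w_snc[k] * snc[k]``, the sum of input
    weights from the active stimuli, and — for the single instructed Go
    unit when the PFC/HC is active — the fixed instruction weight.
    """
    n = weights.n_stimuli
    y_in = _check_vector("y_in", y_in, n)
    snc = _check_vector("y_snc_per_unit", y_snc_per_unit, 2 * n)
    pre = weights.w_snc_stria * snc + y_in @ weights.w_in_stria
    if pfc_go_index is not None and y_pfc:
        if not (0 <= pfc_go_index < n):
            raise ValueError(f"instructed Go index {pfc_go_index} out of range")
        pre[pfc_go_index] += params.w_pfc_stria
    return phi(pre, params.a)


def gpe_activity(y_stria_nogo: np.ndarray) -> np.ndarray:
    """GPe units are tonically active and inhibited one-to-one by NoGo units."""
    v = np.asarray(y_stria_nogo, dtype=float)
    return 1.0 - v


def gpi_activity(y_stria_go: np.ndarray, y_gpe: np.ndarray) -> np.ndarray:
    """GPi units: tonic, inhibited by Go (direct) and GPe (indirect), floored at 0."""
    go = np.asarray(y_stria_go, dtype=float)
    gpe = np.asarray(y_gpe, dtype=float)
    return np.maximum(1.0 - 0.5 * go - 0.5 * gpe, 0.0)


def thalamus_activity(y_gpi: np.ndarray) -> np.ndarray:
    """Thalamic units are disinhibited as their GPi counterparts shut down."""
    return 1.0 - np.asarray(y_gpi, dtype=float)


def pmc_activity(
    weights: NetworkWeights,
    params: ModelParams,
    y_thal: np.ndarray,
    y_in: np.ndarray,
    pfc_pmc_index: Optional[int] = None,
    y_pfc: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Premotor-cortex preactivation and activity.

    ``x_k = 0.5 * thal_k + 0.5 * sum_i w_pmc[i, k] * y_in[i] (+ pfc bias)``,
    renormalized by its maximum if that maximum exceeds 1, then squashed
    through phi.  Returns ``(x, y)`` with the post-normalization x.
    """
    n = weights.n_stimuli
    y_thal = _check_vector("y_thal", y_thal, n)
    y_in = _check_vector("y_in", y_in, n)
    x = 0.5 * y_thal + 0.5 * (y_in @ weights.w_in_pmc)
    if pfc_pmc_index is not None and y_pfc:
        if not (0 <= pfc_pmc_index < n):
            raise ValueError(f"instructed PMC index {pfc_pmc_index} out of range")
        x[pfc_pmc_index] += params.w_pfc_pmc
    m = x.max()
    if m > 1.0:
        x = x / m
    return x, phi(x, params.a)


def decide(y_pmc: np.ndarray, presented: Iterable[int]) -> tuple[int, np.ndarray]:
    """Pick the presented stimulus with the highest PMC activity.

    Units for stimuli absent from the screen are masked out.  Exact ties are
    broken toward the lowest stimulus index, for reproducibility.
    """
    y_pmc = np.asarray(y_pmc, dtype=float)
    idx = sorted(int(i) for i in presented)
    if not idx:
        raise ValueError("presented stimulus set must be nonempty")
    if idx[0] < 0 or idx[-1] >= len(y_pmc):
        raise ValueError(f"presented indices {idx} out of range for N={len(y_pmc)}")
    masked = np.full_like(y_pmc, -np.inf)
    masked[idx] = y_pmc[idx]
    chosen = int(np.argmax(masked))
    y_out = np.zeros(len(y_pmc))
    y_out[chosen] = 1.0
    return chosen, y_out


def snc_vector(
    weights: NetworkWeights,
    params: ModelParams,
    phasic_level: Optional[float] = None,
    chosen: Optional[int] = None,
) -> np.ndarray:
    """Per-striatal-unit SNc level.

    Tonic everywhere in the minus phase.  In the plus phase the phasic level
    (burst or dip) is routed only to the chosen stimulus's Go and NoGo
    units; all other units keep seeing the tonic level, so their plus/minus
    activity difference — and hence their dopamine-driven learning — is nil.
    """
    n = weights.n_stimuli
    snc = np.full(2 * n, params.snc_tonic)
    if phasic_level is not None:
        if chosen is None:
            raise ValueError("phasic SNc signal requires a chosen stimulus")
        if not (0 <= chosen < n):
            raise ValueError(f"chosen index {chosen} out of range")
        snc[chosen] = phasic_level
        snc[n + chosen] = phasic_level
    return snc


def run_phase(
    weights: NetworkWeights,
    params: ModelParams,
    y_in: np.ndarray,
    *,
    phasic_level: Optional[float] = None,
    chosen: Optional[int] = None,
    pfc_stimulus: Optional[int] = None,
    y_pfc: int = 0,
) -> PhaseState:
    """One full feed-forward sweep of the network.

    Minus phase (default): tonic SNc everywhere; the decision is taken by
    ``decide`` over the presented stimuli.  Plus phase: pass the feedback's
    ``phasic_level`` and the minus-phase ``chosen`` index; the decision is
    clamped to that choice and the phasic dopamine is routed to its
    striatal units only.
    """
    n = weights.n_stimuli
    y_in = _check_vector("y_in", y_in, n)
    if not np.all(np.isin(y_in, (0.0, 1.0))):
        raise ValueError("y_in must be binary")
    if phasic_level is not None and chosen is None:
        raise ValueError("plus phase requires the minus-phase choice (chosen=...)")

    snc = snc_vector(weights, params, phasic_level, chosen)
    y_stria = striatum_activity(weights, params, y_in, snc, pfc_stimulus, y_pfc)
    y_gpe = gpe_activity(y_stria[n:])
    y_gpi = gpi_activity(y_stria[:n], y_gpe)
    y_thal = thalamus_activity(y_gpi)
    x_pmc, y_pmc = pmc_activity(weights, params, y_thal, y_in, pfc_stimulus, y_pfc)

    presented = [int(i) for i in np.flatnonzero(y_in)]
    if phasic_level is None:
        chosen_idx, y_out = decide(y_pmc, presented)
        phase = "minus"
    else:
        assert chosen is not None
        if chosen not in presented:
            raise ValueError(f"chosen stimulus {chosen} was not presented")
        chosen_idx = int(chosen)
        y_out = np.zeros(n)
        y_out[chosen_idx] = 1.0
        phase = "plus"

    return PhaseState(
        phase=phase,
        y_in=y_in.copy(),
        y_pfc=int(bool(y_pfc)),
        instructed_index=pfc_stimulus if y_pfc else None,
        y_snc_per_unit=snc,
        y_stria=y_stria,
        y_gpe=y_gpe,
        y_gpi=y_gpi,
        y_thal=y_thal,
        x_pmc=x_pmc,
        y_pmc=y_pmc,
        y_out=y_out,
        chosen=chosen_idx,
    )
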