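"""Weight initialization, the plus/minus learning rule and forgetting.

Learning is contrastive: after each trial the plus-phase and minus-phase
activities of the striatal and PMC units are subtracted, and the learnable
weights move along that difference with a delta-rule step gated by the
presynaptic input.  Weights are clipped to stay nonnegative and decay by a
multiplicative forgetting factor once per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NetworkWeights, PhaseState, default_snc_signs
from .params import ModelParams

__all__ = [
    "WeightDelta",
    "init_weights",
    "phase_difference",
    "apply_update",
    "apply_forgetting",
]


@dataclass(frozen=True)
class WeightDelta:
    """Plus-minus activity differences for the striatum (2N) and PMC (N)."""

    d_stria: np.ndarray
    d_pmc: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "d_stria", np.asarray(self.d_stria, dtype=float))
        object.__setattr__(self, "d_pmc", np.asarray(self.d_pmc, dtype=float))
        if self.d_stria.ndim != 1 or self.d_pmc.ndim != 1:
            raise ValueError("activity differences must be vectors")
        if self.d_stria.shape[0] != 2 * self.d_pmc.shape[0]:
            raise ValueError(
                "striatal delta must be twice as long as the PMC delta, got "
                f"{self.d_stria.shape[0]} and {self.d_pmc.shape[0]}"
            )


def init_weights(
    n_stimuli: int, params: ModelParams, rng: np.random.Generator
) -> NetworkWeights:
    """Draw initial learnable weights i.i.d. Gaussian, clipped at zero.

    The striatal matrix (N x 2N) is drawn first, then the PMC matrix
    (N x N); the same seed therefore always yields the same weights.
    Negative draws are replaced by 0 so the global nonnegativity assumption
    holds from trial one.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    sd = params.init_sd
    w_stria = rng.normal(params.init_mean, sd, size=(n_stimuli, 2 * n_stimuli))
    w_pmc = rng.normal(params.init_mean, sd, size=(n_stimuli, n_stimuli))
    return NetworkWeights(
        n_stimuli=n_stimuli,
        w_in_stria=np.clip(w_stria, 0.0, None),
        w_in_pmc=np.clip(w_pmc, 0.0, None),
        w_snc_stria=default_snc_signs(n_stimuli),
    )


def phase_difference(minus: PhaseState, plus: PhaseState) -> WeightDelta:
    """Elementwise plus-minus activity difference for both learnable layers."""
    if minus.y_stria.shape != plus.y_stria.shape or minus.y_pmc.shape != plus.y_pmc.shape:
        raise ValueError("minus and plus phases have mismatched dimensions")
    return WeightDelta(
        d_stria=plus.y_stria - minus.y_stria,
        d_pmc=plus.y_pmc - minus.y_pmc,
    )


def apply_update(
    weights: NetworkWeights,
    delta: WeightDelta,
    y_in: np.ndarray,
    params: ModelParams,
) -> NetworkWeights:
    """Delta-rule step: ``w[i,k] <- max(w[i,k] + lr * gate_i * delta_k, 0)``.

    ``gate_i`` is the binary presynaptic input when gating is on (default),
    so associations of stimuli absent from the screen stay put; with gating
    off every weight onto unit k moves by the same amount.
    """
    n = weights.n_stimuli
    y_in = np.asarray(y_in, dtype=float)
    if y_in.shape != (n,):
        raise ValueError(f"y_in must have shape {(n,)}, got {y_in.shape}")
    if delta.d_stria.shape != (2 * n,) or delta.d_pmc.shape != (n,):
        raise ValueError("delta dimensions do not match the weights")
    gate = y_in if params.presynaptic_gating else np.ones(n)
    w_stria = weights.w_in_stria + params.lr_striatum * np.outer(gate, delta.d_stria)
    w_pmc = weights.w_in_pmc + params.lr_pmc * np.outer(gate, delta.d_pmc)
    return NetworkWeights(
        n_stimuli=n,
        w_in_stria=np.clip(w_stria, 0.0, None),
        w_in_pmc=np.clip(w_pmc, 0.0, None),
        w_snc_stria=weights.w_snc_stria.copy(),
    )


def apply_forgetting(weights: NetworkWeights, params: ModelParams) -> NetworkWeights:
    """Multiply every learnable weight by the forgetting factor beta.

    The fixed SNc->striatum signs are untouched.  At beta = 0.98 the memory
    trace has a half-life of ln 2 / ln(1/beta) ~ 34 trials.
    """
    return NetworkWeights(
        n_stimuli=weights.n_stimuli,
        w_in_stria=params.beta * weights.w_in_stria,
        w_in_pmc=params.beta * weights.w_in_pmc,
        w_snc_stria=weights.w_snc_stria.copy(),
    )
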