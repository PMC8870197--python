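"""Model parameters for the coarse-grained basal-ganglia network.

The network has a small, fixed set of design parameters: the shape of the
activation function, two learning rates, a forgetting factor, the strength
of the prefrontal/hippocampal (PFC/HC) instruction bias, the three output
levels of the dopaminergic SNc unit, and the Gaussian used to initialize
the learnable weights.  Everything else in the model is either a convention
(binary stimulus coding, +1/-1 SNc->striatum signs) or a learnable weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Fixed and design parameters of the network.

    Parameters
    ----------
    a : float
        Shape coefficient of the activation function
        ``phi(x) = exp(-a * (1 - x)**2)``.  Must be positive.
    lr_striatum, lr_pmc : float
        Learning rates for the input->striatum and input->premotor-cortex
        weights (weight change per unit of plus/minus activity difference).
    beta : float
        Per-trial multiplicative forgetting factor in ``(0, 1]``.
    w_pfc_stria : float
        Strength of the PFC/HC drive onto the instructed stimulus's Go unit.
    w_pfc_pmc : float
        Strength of the PFC/HC drive onto the instructed stimulus's PMC unit.
    snc_dip, snc_tonic, snc_burst : float
        SNc output on punishment, at baseline, and on reward.  The striatal
        drive is ``w_snc * y_snc`` with ``w_snc = +1`` (Go) or ``-1`` (NoGo).
        The defaults code dopamine as the phasic *deviation* from baseline
        (dip = -0.5, tonic = 0, burst = +0.5): at baseline the SNc
        contributes nothing, a burst pushes Go units toward threshold and a
        dip pushes NoGo units toward threshold symmetrically.  The absolute
        coding (0 / 0.5 / 1) can be selected via these fields; see
        docs/methods.md for why the deviation coding is the default.
    init_mean, init_var : float
        Mean and variance of the Gaussian used to initialize learnable
        weights.  Negative draws are clipped to zero.
    presynaptic_gating : bool
        If True (default), the delta-rule update of ``w[i, k]`` is gated by
        the presynaptic input ``y_in[i]``, so weights from stimuli absent
        from the screen are untouched.  If False, every weight to unit *k*
        moves by ``lr * delta_k`` regardless of the input (the ungated
        variant, available for sensitivity analysis).
    """

    a: float = 8.0
    lr_striatum: float = 0.1
    lr_pmc: float = 0.1
    beta: float = 0.98
    w_pfc_stria: float = 0.3
    w_pfc_pmc: float = 0.05
    snc_dip: float = -0.5
    snc_tonic: float = 0.0
    snc_burst: float = 0.5
    init_mean: float = 0.05
    init_var: float = 0.01
    presynaptic_gating: bool = True

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"activation shape a must be positive, got {self.a}")
        if self.lr_striatum < 0 or self.lr_pmc < 0:
            raise ValueError("learning rates must be nonnegative")
        if not (0 < self.beta <= 1):
            raise ValueError(f"forgetting factor beta must lie in (0, 1], got {self.beta}")
        if self.w_pfc_stria < 0 or self.w_pfc_pmc < 0:
            raise ValueError("PFC/HC weights must be nonnegative")
        if not (self.snc_dip < self.snc_tonic < self.snc_burst):
            raise ValueError(
                "SNc levels must satisfy dip < tonic < burst, got "
                f"{self.snc_dip}, {self.snc_tonic}, {self.snc_burst}"
            )
        if self.init_var < 0:
            raise ValueError("init_var must be nonnegative")

    @property
    def init_sd(self) -> float:
        """Standard deviation of the weight-initialization Gaussian."""
        return math.sqrt(self.init_var)

    def with_absolute_da(self) -> "ModelParams":
        """Return a copy using the absolute dopamine coding (0 / 0.5 / 1).

        Under this coding the tonic SNc level itself enters the striatal
        preactivation (+0.5 for Go units, -0.5 for NoGo units at baseline).
        """
        return replace(self, snc_dip=0.0, snc_tonic=0.5, snc_burst=1.0)
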