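"""Multi-spike firing gates: Linear mode and spike-frequency adaptation.

A multi-spike neuron replaces the binary threshold crossing with a pair
of functions: the firing gate ``s = g(v)`` mapping membrane potential to
an integer spike count for the window, and the membrane cost
``u = h(s)`` giving the potential consumed to emit those spikes.  The
window update is then ``v[t] = decay * (v[t-dt] - u[t-dt]) + I_norm[t]``.

Two gates are provided:

* **Linear mode** — ``s = floor(v / v_th)`` capped at ``s_max``; each
  spike costs the same base threshold, so ``u = s * v_th``.  With
  ``s_max = 1`` this reduces exactly to the soft-reset binary neuron.
* **SFA mode** — spike-frequency adaptation: each successive spike in a
  window raises the effective threshold geometrically by the inhibition
  coefficient ``q > 1``, so the cost of ``s`` spikes is the geometric sum
  ``u = (q**s - 1)/(q - 1) * v_th`` and the continuous spike intensity is
  ``n* = log_q(v/v_th * (q-1) + 1)`` with ``s = floor(n*)``.  Counts grow
  logarithmically in the drive, suppressing dense firing.

For gradient-based training the floor is non-differentiable; its
pseudo-derivative is the constant ``ds/dn* = 1`` (straight-through), so
gradients flow through the smooth intensity ``n*`` unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

# Slack inside floor() so intensities that are integers up to fp error
# (e.g. log_q of an exact power of q) are not rounded down a whole spike.
_FLOOR_EPS = 1e-9


@dataclass(frozen=True)
class GateResult:
    """Outcome of applying a firing gate to one membrane potential."""

    s: int          # spike count emitted this window
    n_star: float   # continuous spike intensity (pre-floor)
    u: float        # consumed membrane potential (mV)


@dataclass(frozen=True)
class LinearGate:
    """Linear-mode gate: constant per-spike cost ``v_th``, optional cap."""

    v_th: float
    s_max: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.v_th > 0:
            raise ValueError(f"v_th must be positive, got {self.v_th}")
        if self.s_max is not None and self.s_max < 1:
            raise ValueError(f"s_max must be >= 1 or None, got {self.s_max}")

    def __call__(self, v: float) -> GateResult:
        n_star = v / self.v_th
        s = int(math.floor(n_star + _FLOOR_EPS))
        s = max(s, 0)
        if self.s_max is not None:
            s = min(s, self.s_max)
        return GateResult(s=s, n_star=n_star, u=self.v_th * s)

    def cost(self, s: int) -> float:
        """Membrane cost ``h(s)`` of emitting ``s`` spikes."""
        return self.v_th * s


@dataclass(frozen=True)
class SFAGate:
    """Spike-frequency-adaptation gate with geometric threshold growth.

    The k-th spike in a window costs ``v_th * q**(k-1)``; ``s_max`` is a
    numerical guard on the geometric term, not part of the model.
    """

    v_th: float
    q: float
    s_max: Optional[int] = 64

    def __post_init__(self) -> None:
        if not self.v_th > 0:
            raise ValueError(f"v_th must be positive, got {self.v_th}")
        if not self.q > 1:
            raise ValueError(f"inhibition coefficient q must exceed 1, got {self.q}")

    def intensity(self, v: float) -> float:
        """Continuous spike intensity ``n* = log_q(v/v_th*(q-1)+1)``."""
        arg = v / self.v_th * (self.q - 1.0) + 1.0
        if arg <= 0.0:
            return -math.inf
        return math.log(arg) / math.log(self.q)

    def __call__(self, v: float) -> GateResult:
        if v < 0:
            return GateResult(s=0, n_star=self.intensity(v), u=0.0)
        n_star = self.intensity(v)
        s = max(int(math.floor(n_star + _FLOOR_EPS)), 0)
        if self.s_max is not None:
            s = min(s, self.s_max)
        return GateResult(s=s, n_star=n_star, u=self.cost(s))

    def cost(self, s: int) -> float:
        """Geometric-sum cost ``(q**s - 1)/(q - 1) * v_th`` of ``s`` spikes."""
        return (self.q ** s - 1.0) / (self.q - 1.0) * self.v_th


Gate = Union[LinearGate, SFAGate]


def sfa_surrogate_grad(n_star) -> np.ndarray:
    """Pseudo-derivative of the spike count w.r.t. the intensity: unit.

    The floor in ``s = floor(n*)`` has zero derivative almost everywhere;
    for backpropagation it is replaced by the constant 1, so the gradient
    of the smooth intensity passes through unchanged.
    """
    return np.ones_like(np.asarray(n_star, dtype=float))


def sfa_intensity_grad(v, gate: SFAGate) -> np.ndarray:
    """Analytic ``dn*/dv = (q-1) / (ln q * (v/v_th*(q-1)+1) * v_th)``.

    Combined with the unit surrogate this is the full ``ds/dv`` used in
    training.  Only defined where the log argument is positive.
    """
    v = np.asarray(v, dtype=float)
    arg = v / gate.v_th * (gate.q - 1.0) + 1.0
    return (gate.q - 1.0) / (math.log(gate.q) * arg * gate.v_th)


def msp_step(
    v_prev: float, u_prev: float, I_norm: float, gate: Gate, decay: float
) -> Tuple[float, GateResult]:
    """One multi-spike window update.

    The previous window's consumed potential ``u_prev`` is subtracted
    before the leak, mirroring the soft reset (which is the
    ``LinearGate(s_max=1)`` special case).
    """
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay factor must lie in (0, 1), got {decay}")
    v = decay * (v_prev - u_prev) + I_norm
    return v, gate(v)
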