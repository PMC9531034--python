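"""Shared parameter and result containers for the discrete LIF model family.

Units follow the electrophysiology convention used throughout the package:
milliseconds (time), millivolts (potential), milliamperes (current), ohms
(resistance), so that R*I is in mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class NeuronParams:
    """Physical constants of a leaky integrate-and-fire neuron.

    Parameters
    ----------
    tau : float
        Membrane time constant in ms. Must be positive.
    R : float
        Membrane resistance in ohms. Must be positive.
    v_th : float
        Firing threshold in mV (measured from rest). Must be positive.
    v_rest : float
        Resting potential in mV. Fixed at 0 by convention; the discrete
        update equations are derived with this origin.
    s_max : int or None
        Optional cap on spikes emitted within one iterative window.
        ``None`` means unbounded (multi-spike neurons) — single-spike
        neurons use ``s_max=1``.
    """

    tau: float
    R: float
    v_th: float
    v_rest: float = 0.0
    s_max: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.R > 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if not self.v_th > 0:
            raise ValueError(f"v_th must be positive, got {self.v_th}")
        if self.v_rest != 0.0:
            raise ValueError("v_rest is fixed at 0 in this model family")
        if self.s_max is not None and self.s_max < 1:
            raise ValueError(f"s_max must be >= 1 or None, got {self.s_max}")


@dataclass(frozen=True)
class SimulationConfig:
    """Constant-current simulation protocol.

    ``total_time`` must be an integer multiple of ``dt`` (within floating
    point slack); configs with a partial final window are rejected so that
    window-partition invariance checks are exact.
    """

    current: float       # constant input current I_c (mA)
    total_time: float    # T (ms)
    dt: float            # iterative step length (ms)
    initial_v: float = 0.0

    def __post_init__(self) -> None:
        if not self.total_time > 0:
            raise ValueError("total_time must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        n = self.total_time / self.dt
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(
                f"total_time={self.total_time} is not an integer multiple of "
                f"dt={self.dt}; partial final windows are not supported"
            )

    @property
    def n_windows(self) -> int:
        return int(round(self.total_time / self.dt))


@dataclass(frozen=True)
class StepOutcome:
    """Result of one closed-form window update of the LIF neuron.

    ``t_alpha`` is the time from window start to the first spike,
    ``t_omega`` the inter-spike interval under the window's constant
    current, and ``t_r`` the time from the last spike to the window end.
    ``v_estimate`` is the potential the membrane would reach at the window
    end had no reset occurred; when no spike fires it coincides with
    ``v_residual``.
    """

    n_spikes: int
    v_residual: float
    v_estimate: float
    t_alpha: Optional[float] = None
    t_omega: Optional[float] = None
    t_r: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be non-negative")
        if self.n_spikes == 0 and not math.isclose(
            self.v_residual, self.v_estimate, rel_tol=0, abs_tol=1e-12
        ):
            raise ValueError("with no spikes, v_residual must equal v_estimate")
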