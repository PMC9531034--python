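"""Discrete leaky integrate-and-fire neuron model family.

The continuous LIF membrane obeys ``tau dv/dt = -(v - v_rest) + R I(t)``
with a spike and reset once ``v`` reaches ``v_th``.  Discretising with
step ``dt`` and current held constant over each window gives a family of
per-window update rules of increasing fidelity:

* ``hard_reset`` / ``soft_reset`` — the binary single-spike-pattern
  updates used by most BPTT-trained spiking networks.  At most one spike
  per window; hard reset discards any suprathreshold excess, soft reset
  carries it over (scaled by the decay factor).
* ``standard`` — the exact per-window solution: first-spike latency
  ``t_alpha``, inter-spike interval ``t_omega`` and residual time ``t_r``
  are solved in closed form, so the emitted spike count per window is
  exact for any ``dt``.
* ``simplified`` — first-order approximation of the standard model,
  accurate when ``v_th / (R I)`` is small.

An event-driven simulator (`event_driven_oracle`) produces the exact
continuous-time spike train for a constant-current run, independent of
any ``dt``; it is the reference the discrete models are judged against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .grids import SpikeGrid
from .params import NeuronParams, SimulationConfig, StepOutcome

# Absolute tolerance for threshold comparisons: the closed forms round-trip
# through ln/exp, so V_e can land within fp noise of v_th.
V_TH_ATOL = 1e-12
# Slack added inside floor() when counting whole inter-spike intervals, so a
# spike landing exactly on the window edge is attributed to this window.
_FLOOR_EPS = 1e-9

MODEL_IDS = ("hard_reset", "soft_reset", "standard", "simplified",
             "linear_msp", "sfa_msp")


def decay_factor(dt: float, tau: float) -> float:
    """Per-step membrane retention factor ``exp(-dt/tau)``."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return math.exp(-dt / tau)


def normalize_input(I: float, dt: float, params: NeuronParams) -> float:
    """Normalised drive ``(1 - exp(-dt/tau)) * R * I`` in mV.

    This is the steady-state-scaled charge a constant current ``I`` adds
    to the membrane over one window; as ``dt -> inf`` it approaches the
    asymptote ``R*I``.
    """
    return (1.0 - decay_factor(dt, params.tau)) * params.R * I


def hard_reset_step(
    v_prev: float, s_prev: int, I_norm: float, params: NeuronParams, dt: float
) -> Tuple[float, int]:
    """One binary window update with hard reset.

    A spike in the previous window zeroes the carried potential entirely,
    discarding any excess above threshold.
    """
    if s_prev not in (0, 1):
        raise ValueError("hard_reset_step is a binary (single-spike) update")
    d = decay_factor(dt, params.tau)
    v = d * v_prev * (1 - s_prev) + I_norm
    s = 1 if v >= params.v_th - V_TH_ATOL else 0
    return v, s


def soft_reset_step(
    v_prev: float, s_prev: int, I_norm: float, params: NeuronParams, dt: float
) -> Tuple[float, int]:
    """One binary window update with soft reset (threshold subtraction).

    The portion of potential above threshold is retained and decays like
    any other charge; with zero excess this coincides with the hard reset.
    """
    if s_prev not in (0, 1):
        raise ValueError("soft_reset_step is a binary (single-spike) update")
    d = decay_factor(dt, params.tau)
    v = d * (v_prev - s_prev * params.v_th) + I_norm
    s = 1 if v >= params.v_th - V_TH_ATOL else 0
    return v, s


def _estimate_potential(v0: float, Ic: float, dt: float, p: NeuronParams) -> float:
    d = decay_factor(dt, p.tau)
    return d * v0 + (1.0 - d) * p.R * Ic


def standard_numerical_step(
    v0: float, Ic: float, dt: float, params: NeuronParams
) -> StepOutcome:
    """Exact per-window LIF solution under constant current.

    With the unreset end-of-window estimate ``V_e`` below threshold, no
    spike fires and the residual is ``V_e`` itself.  Otherwise the
    first-spike latency and inter-spike interval

        t_alpha = -tau ln(1 - (v_th - v0)/(R Ic - v0))
        t_omega = -tau ln(1 - v_th/(R Ic))

    give ``n = floor((dt - t_alpha)/t_omega) + 1`` spikes and a residual
    built from the time ``t_r`` left after the last spike.
    """
    p = params
    if v0 >= p.v_th:
        raise ValueError(f"window must start below threshold, got v0={v0}")
    v_e = _estimate_potential(v0, Ic, dt, p)
    if v_e < p.v_th - V_TH_ATOL:
        return StepOutcome(n_spikes=0, v_residual=v_e, v_estimate=v_e)
    drive = p.R * Ic
    if drive <= p.v_th:
        # V_e >= v_th from below-threshold start requires suprathreshold
        # drive; anything else indicates corrupted inputs.
        raise ArithmeticError(
            f"V_e={v_e} reached threshold with subthreshold drive R*Ic={drive}"
        )
    t_alpha = -p.tau * math.log1p(-(p.v_th - v0) / (drive - v0))
    t_omega = -p.tau * math.log1p(-p.v_th / drive)
    n = int(math.floor((dt - t_alpha) / t_omega + _FLOOR_EPS)) + 1
    if p.s_max is not None:
        n = min(n, p.s_max)
    t_r = dt - t_alpha - (n - 1) * t_omega
    t_r = min(max(t_r, 0.0), dt)
    v_r = (1.0 - math.exp(-t_r / p.tau)) * drive
    v_r = min(v_r, p.v_th * (1.0 - 1e-15))  # fp guard: residual stays below v_th
    return StepOutcome(
        n_spikes=n, v_residual=v_r, v_estimate=v_e,
        t_alpha=t_alpha, t_omega=t_omega, t_r=t_r,
    )


def simplified_numerical_step(
    v0: float, Ic: float, dt: float, params: NeuronParams
) -> StepOutcome:
    """First-order approximation of `standard_numerical_step`.

    Valid when ``v_th/(R Ic)`` is small: the logs in the exact latencies
    are linearised, collapsing the spike count to

        n = floor((dt/tau) * R Ic / v_th + v0 / v_th)

    The subthreshold branch is identical to the standard model.  Near the
    firing boundary the linearised count can disagree with the threshold
    test (including n <= 0); such windows are treated as silent, and the
    residual is clamped into [0, v_th) — an artefact of the approximation,
    not of the exact model.
    """
    p = params
    if v0 >= p.v_th:
        raise ValueError(f"window must start below threshold, got v0={v0}")
    v_e = _estimate_potential(v0, Ic, dt, p)
    if v_e < p.v_th - V_TH_ATOL:
        return StepOutcome(n_spikes=0, v_residual=v_e, v_estimate=v_e)
    drive = p.R * Ic
    if drive <= p.v_th:
        raise ArithmeticError(
            f"V_e={v_e} reached threshold with subthreshold drive R*Ic={drive}"
        )
    n = int(math.floor((dt / p.tau) * drive / p.v_th + v0 / p.v_th + _FLOOR_EPS))
    if n <= 0:
        return StepOutcome(n_spikes=0, v_residual=v_e, v_estimate=v_e)
    if p.s_max is not None:
        n = min(n, p.s_max)
    t_alpha = p.tau * (p.v_th - v0) / (drive - v0)
    t_omega = p.tau * p.v_th / drive
    t_r = dt - t_alpha - (n - 1) * t_omega
    t_r = min(max(t_r, 0.0), dt)
    v_r = (1.0 - math.exp(-t_r / p.tau)) * drive
    v_r = min(max(v_r, 0.0), p.v_th * (1.0 - 1e-15))
    return StepOutcome(
        n_spikes=n, v_residual=v_r, v_estimate=v_e,
        t_alpha=t_alpha, t_omega=t_omega, t_r=t_r,
    )


def event_driven_oracle(
    cfg: SimulationConfig, params: NeuronParams
) -> np.ndarray:
    """Exact continuous-time spike times on [0, T] under constant current.

    Uses the closed-form latencies directly on the whole run, so the
    result is independent of any discretisation.  Returns an empty array
    when the drive cannot reach threshold (``R*Ic <= v_th``).
    """
    p = params
    drive = p.R * cfg.current
    if drive <= p.v_th:
        return np.empty(0)
    v0 = cfg.initial_v
    if v0 >= p.v_th:
        raise ValueError("initial potential must be below threshold")
    t_alpha = -p.tau * math.log1p(-(p.v_th - v0) / (drive - v0))
    if t_alpha > cfg.total_time:
        return np.empty(0)
    t_omega = -p.tau * math.log1p(-p.v_th / drive)
    k_max = int(math.floor((cfg.total_time - t_alpha) / t_omega + _FLOOR_EPS))
    return t_alpha + t_omega * np.arange(k_max + 1)


@dataclass
class DiscreteRun:
    """Per-window spike counts plus the end-of-window potential trace."""

    model_id: str
    grid: SpikeGrid
    v_trace: np.ndarray  # post-reset / residual potential at each window end

    @property
    def counts(self) -> np.ndarray:
        return self.grid.counts[0]

    def total_spikes(self) -> int:
        return self.grid.total_spikes()

    @property
    def final_v(self) -> float:
        return float(self.v_trace[-1])


def run_discrete_model(
    model_id: str,
    cfg: SimulationConfig,
    params: NeuronParams,
    *,
    q: float = 1.2,
    sfa_s_max: int = 64,
) -> DiscreteRun:
    """Iterate one of the discrete neuron models over a constant-current run.

    ``model_id`` selects among ``hard_reset``, ``soft_reset``, ``standard``,
    ``simplified``, ``linear_msp`` (floor gate, cap from ``params.s_max``)
    and ``sfa_msp`` (spike-frequency-adaptation gate with inhibition
    coefficient ``q``).
    """
    from .gates import LinearGate, SFAGate, msp_step  # local: avoid cycle at import

    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    n_win = cfg.n_windows
    counts = np.zeros(n_win, dtype=np.int64)
    v_trace = np.zeros(n_win, dtype=float)
    v = cfg.initial_v

    if model_id in ("standard", "simplified"):
        step = standard_numerical_step if model_id == "standard" else simplified_numerical_step
        for k in range(n_win):
            out = step(v, cfg.current, cfg.dt, params)
            counts[k] = out.n_spikes
            v = out.v_residual
            v_trace[k] = v
    elif model_id in ("hard_reset", "soft_reset"):
        step = hard_reset_step if model_id == "hard_reset" else soft_reset_step
        I_norm = normalize_input(cfg.current, cfg.dt, params)
        s = 0
        for k in range(n_win):
            v, s = step(v, s, I_norm, params, cfg.dt)
            counts[k] = s
            v_trace[k] = v  # raw membrane value; the reset applies on the next step
    else:
        if model_id == "linear_msp":
            gate = LinearGate(v_th=params.v_th, s_max=params.s_max)
        else:
            gate = SFAGate(v_th=params.v_th, q=q, s_max=sfa_s_max)
        d = decay_factor(cfg.dt, params.tau)
        I_norm = normalize_input(cfg.current, cfg.dt, params)
        u = 0.0
        for k in range(n_win):
            v, res = msp_step(v, u, I_norm, gate, d)
            counts[k] = res.s
            u = res.u
            v_trace[k] = v  # raw membrane value; consumption applies next step
    grid = SpikeGrid(counts=counts[None, :], dt=cfg.dt)
    return DiscreteRun(model_id=model_id, grid=grid, v_trace=v_trace)
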