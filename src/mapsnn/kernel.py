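"""State-free synaptic response: delayed 2-exponential kernel as causal convolution.

A presynaptic spike train is converted to a postsynaptic current by
convolving with a spike-response kernel.  Instead of integrating a
synaptic state variable step by step, the kernel is truncated to a
finite window of ``kernel_size`` taps and the response is computed as a
causal 1-D convolution — no recursion over time, hence "state-free".

The kernel shape is the difference of two exponentials with a rise onset
shifted by ``delay``:

    K*(t) = exp(-a t) - exp(-b t)
    K(t)  = K*(t - delay)  for t >= delay,  else 0

sampled at the simulation step: ``taps[i] = K(i * dt)``.  ``a``, ``b``
and ``delay`` are trainable per neuron; amplitude normalisation is left
to the synaptic weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import SpikeGrid

# Rates and delay are clamped away from zero at kernel build; negative
# rates would make the kernel grow without bound.
PARAM_FLOOR = 1e-3
# When a == b the two exponentials cancel identically; perturb b.
_DEGENERACY_EPS = 1e-6


@dataclass(frozen=True)
class SpikeKernel:
    """A sampled, delayed 2-exponential spike-response kernel."""

    a: float
    b: float
    delay: float
    kernel_size: int
    dt: float
    taps: np.ndarray

    @property
    def t_k(self) -> float:
        """Length of the response window covered by the taps (ms)."""
        return (self.kernel_size - 1) * self.dt


def kernel_shape(t, a: float, b: float):
    """The un-delayed 2-exponential ``K*(t) = exp(-a t) - exp(-b t)``."""
    t = np.asarray(t, dtype=float)
    return np.exp(-a * t) - np.exp(-b * t)


def build_kernel(
    a: float, b: float, delay: float, kernel_size: int, dt: float
) -> SpikeKernel:
    """Sample the delayed 2-exponential into ``kernel_size`` taps.

    Taps before the onset delay are exactly zero.  ``a``, ``b`` and
    ``delay`` are clamped to at least ``PARAM_FLOOR`` and coincident
    rates are split apart by a tiny perturbation, since ``a == b``
    cancels the kernel identically.
    """
    if kernel_size < 1:
        raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    a = max(float(a), PARAM_FLOOR)
    b = max(float(b), PARAM_FLOOR)
    delay = max(float(delay), PARAM_FLOOR)
    if abs(a - b) < _DEGENERACY_EPS:
        b = b + _DEGENERACY_EPS
    t = np.arange(kernel_size) * dt
    taps = np.where(t >= delay, kernel_shape(t - delay, a, b), 0.0)
    return SpikeKernel(a=a, b=b, delay=delay, kernel_size=kernel_size,
                       dt=dt, taps=taps)


def _as_sequence(spikes, kernel: SpikeKernel) -> np.ndarray:
    if isinstance(spikes, SpikeGrid):
        if abs(spikes.dt - kernel.dt) > 1e-12 * max(1.0, kernel.dt):
            raise ValueError(
                f"spike grid dt={spikes.dt} does not match kernel dt={kernel.dt}"
            )
        if spikes.n_channels != 1:
            raise ValueError("apply_response expects a single-channel sequence")
        return spikes.counts[0].astype(float)
    return np.asarray(spikes, dtype=float)


def apply_response(spikes, kernel: SpikeKernel) -> np.ndarray:
    """Causal convolution of a spike-count sequence with the kernel taps.

    ``o[t] = sum_i spikes[t - i] * taps[i]`` with zero padding before
    t=0; output length equals input length, and spikes more than
    ``kernel_size - 1`` steps in the past have no effect.
    """
    s = _as_sequence(spikes, kernel)
    return np.convolve(s, kernel.taps)[: len(s)]


def direct_sum_oracle(spikes, kernel: SpikeKernel) -> np.ndarray:
    """Term-by-term evaluation of the response sum (reference path).

    Deliberately naive — a double loop over output time and tap index —
    and kept independent of `apply_response` so the two can be compared.
    """
    s = _as_sequence(spikes, kernel)
    out = np.zeros(len(s))
    for t in range(len(s)):
        acc = 0.0
        for i in range(kernel.kernel_size):
            if t - i >= 0:
                acc += s[t - i] * kernel.taps[i]
        out[t] = acc
    return out
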