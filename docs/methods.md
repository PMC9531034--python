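# Methods

This note documents the models the package implements, the numerical
choices behind them, and what the bundled synthetic benchmark does and
does not demonstrate.

## The discrete LIF model family

The membrane of a leaky integrate-and-fire (LIF) neuron obeys

    tau dv/dt = -(v - v_rest) + R I(t),        v_rest = 0,

with a spike and reset when `v` reaches the threshold `v_th`.  All
discrete models in `mapsnn.lif` hold the input current constant over
each iterative window `(t - dt, t]` (the current value at the window's
right edge), which is the only quantisation the family shares; windows
are half-open on the left and spike counts are attributed to the right
edge.  Units are ms, mV, mA and ohms throughout, so `R*I` is in mV.
Configurations whose total time is not an integer multiple of `dt` are
rejected rather than truncated, which keeps window-partition invariance
checks exact.

Four per-window updates are provided:

* **hard reset** — binary spike, carried potential zeroed after a
  spike; the excess above threshold is discarded.
* **soft reset** — binary spike, threshold subtracted instead; the
  excess survives (scaled by the decay factor `exp(-dt/tau)`).  With
  zero excess the two coincide.
* **standard numerical** — the exact solution: with window-start
  potential `V0` and drive `R*Ic > v_th`, the first-spike latency and
  inter-spike interval are

      t_alpha = -tau ln(1 - (v_th - V0)/(R Ic - V0))
      t_omega = -tau ln(1 - v_th/(R Ic))

  giving `n = floor((dt - t_alpha)/t_omega) + 1` spikes and residual
  `V_r = (1 - exp(-t_r/tau)) R Ic` with `t_r = dt - t_alpha -
  (n-1) t_omega`.  Because each window reproduces the continuous-time
  trajectory exactly, the total spike count over a run is independent
  of `dt`.
* **simplified numerical** — the same structure with the logarithms
  linearised (`t_omega ~ tau v_th / (R C)`), collapsing the count to
  `n = floor((dt/tau) R Ic / v_th + V0/v_th)`; a good approximation
  exactly when `v_th/(R Ic)` is small.

Numerical conventions: threshold comparisons use an absolute tolerance
of 1e-12 mV (ln/exp round-trips); the floor over whole inter-spike
intervals gets 1e-9 of slack so a spike landing on a window edge counts
in that window; the membrane is never clamped at zero — transiently
negative potentials are part of the model.  The simplified model's
linearised count can disagree with the exact threshold test near the
firing boundary (including predicting zero spikes in a window whose
estimated potential crosses threshold); such windows are treated as
silent and residuals are clamped into `[0, v_th)`.  This is a property
of the approximation, which its definition leaves unaddressed.

An event-driven simulator evaluates the same closed forms once over the
whole run, yielding the exact continuous-time spike train; it is the
oracle for every dt-robustness test.

## Multi-spike gates and spike-frequency adaptation

Binary ("single-spike pattern") neurons transmit at most one spike per
window, so their counts saturate at `T/dt` once `dt` exceeds the
inter-spike interval.  Multi-spike neurons replace the threshold test
with a firing gate `s = g(v)` (an integer count) and a membrane cost
`u = h(s)`; the update `v[t] = decay (v[t-dt] - u[t-dt]) + I_norm[t]`
generalises the soft reset, which is the `s_max = 1` special case.

* **Linear mode**: `s = floor(v/v_th)` (capped at `s_max`), cost
  `u = s v_th`.  Spike intensity is linear in the drive.
* **SFA mode** (spike-frequency adaptation): each successive spike in a
  window raises the effective threshold geometrically by the inhibition
  coefficient `q > 1`, so `s` spikes cost the geometric sum
  `u = (q^s - 1)/(q - 1) v_th` and the continuous intensity is
  `n* = log_q(v/v_th (q - 1) + 1)`, `s = floor(n*)`.  Counts grow
  logarithmically in the drive; under identical constant drive SFA
  emits strictly fewer spikes than Linear mode whenever any window
  fires, and counts are non-increasing in `q`.  As `q -> 1+` the SFA
  gate recovers the Linear gate.

Negative membrane values yield `s = 0, u = 0` (spike counts are
non-negative by definition); the geometric cost term is guarded by a
numerical cap (`s_max = 64` by default) since `q^s` grows without
bound.  The per-spike threshold elevation does not persist across
windows: each window recomputes the gate from the base threshold, which
is what the network dataflow equations imply.  `v_th` and `q` are fixed
scalars shared across neurons by default (per-neuron storage is
supported; trainability is off — no gradient rule is defined for them).

For training, the floor is assigned the pseudo-derivative
`ds/dn* = 1`: gradients pass through the smooth intensity unchanged
(straight-through).  The same rule is used for Linear mode with
`n* = v/v_th`.  Inside the network, the SFA intensity is extended below
`v = 0` by its C1 linear continuation (the slope at `v = 0`,
`(q-1)/(v_th ln q)`): the forward count is still 0, but a neuron whose
membrane goes negative keeps a gradient path instead of dying — without
the extension an output neuron that starts with a negative drive can
never learn to fire and its class is permanently unreachable.  A rectangular pseudo-derivative (gradient only within a
window around threshold, the convention of binary-spike baselines) is
available as a per-layer configuration.

## State-free synaptic response

A presynaptic spike train becomes a postsynaptic current by convolution
with a response kernel.  Instead of integrating a synaptic state
variable, the kernel is truncated to `kernel_size` taps and applied as
a causal 1-D convolution — no recursion over time.  The kernel is a
delayed difference of exponentials,

    K*(t) = exp(-a t) - exp(-b t),    K(t) = K*(t - delay) for t >= delay else 0,

with trainable per-neuron `a`, `b`, `delay`; each neuron filters its
own outgoing spike train with its own kernel.  No normalisation is
applied — amplitude is absorbed by the synaptic weights.

Numerical choices: `a`, `b`, `delay` are clamped to at least 1e-3 at
kernel build (negative rates make the kernel explosive); coincident
rates (`|a - b| < 1e-6`) are split by a 1e-6 perturbation since the
difference cancels identically; the onset branch `K = 0` for
`t < delay` is a hard gate, so `delay`'s gradient flows only through
the smooth shifted argument of the active taps (taps in the zero branch
contribute zero gradient) — the map is differentiable except exactly at
tap boundaries.  Defaults: `kernel_size = 7`, `delay = 0.8`, `a, b`
drawn uniformly from [0.5, 1.0].

**Kernel time unit.**  Inside the network the taps are sampled at the
tap index (`t = i`), i.e. kernel time is measured in timestep units.
The default shape rates (~0.5–1/step) then describe a response bump a
few steps wide at any physical bin width; sampled against a 16–20 ms
bin in physical ms they would decay to nothing within one tap, making
the synapse inert.  The standalone `build_kernel` API keeps an explicit
tap spacing for users who want physical-time kernels.

## Network, decoding and training

Layers are fully connected.  Per timestep: weighted sum of the previous
layer's response currents plus a constant per-neuron bias; membrane
update with fixed decay factor 0.2; firing gate; and, on layers with a
kernel, the causal convolution producing the output current.  Membrane
and cost states start at 0 and convolution history is zero-padded —
an unbiased start consistent with a zero resting potential.

Classification is rate decoding: total output spike counts `Z_i` pass
through a softmax (applied to raw counts, no temperature) and training
minimises the cross-entropy `-sum_i y_i log p_i`, averaged over the
batch, with Adam at learning rate 1e-3.  The trainable set is the
weights, biases and the kernel parameters `a, b, delay`.  Gradients are
computed by backpropagation-through-time on a small reverse-mode tape
(`mapsnn.autodiff`) written for this package; the gate's floor uses the
straight-through surrogate above, and the reset path `u[t-dt]`
participates in the backward pass (no detaching).

Gradient verification: finite differences cannot probe the surrogate
directly (the spiking loss is piecewise constant in places), so the
network offers a relaxed forward in which the floor is replaced by the
identity — exactly the function whose derivative the surrogate defines.
Finite differences agree with the tape there to better than 1e-4
relative at generic parameter points; a separate unit test pins that
the straight-through node passes gradients unchanged.  Checks are run
at generic (jittered) parameter points because the zero-initialised
state can sit exactly on a relu kink, where two-sided differences
average the one-sided slopes.

## Synthetic benchmark task

The generator emulates event-camera / silicon-cochlea recordings:
integer event counts per channel per bin, Poisson noise, several events
possible per bin.  The default task has 3 classes, 100 channels, 800 ms
at 16 ms bins.  A fixed block of 20 signal channels fires at an
elevated rate from a class-specific onset time (0, 200, 400 ms) on top
of uniform background noise on all channels; rates are 1.0 events/bin
(signal) and 0.05 events/bin (background), chosen once as
event-sensor-like sparsity.  Because every class drives the *same*
channels and differs in onset, the label is carried jointly by the
total drive (rate feature) and by its temporal placement — both rate
decoding and temporal feature extraction matter, which is the regime
the synaptic kernel exists for.

What passing on this task shows: the full pipeline (multi-spike gates,
trainable kernels, BPTT) can learn a separable spatio-temporal code at
desk scale, deterministically under a fixed seed.  What it does not
show: performance on real event datasets (no sensor noise correlations,
no jitter in onset, orders of magnitude fewer channels and samples), or
any benchmark-scale error rate.  Readers for the two common
neuromorphic formats (ATIS event files, spiking-cochlea HDF5) are
included for users who want to go further; tests exercise them on
synthetic fixtures only.

Default training setup used by the examples, tests and acceptance
script: 120 training samples, two layers (100 -> 64 -> 3), batch 32,
up to 50 epochs — sized so a full ablation (four configurations) runs
in a couple of minutes on one CPU.  The four configurations mirror the
ablation structure of the model family: `ssp` (binary gate, cap 1),
`ssp+sfsrm`, `msp` (SFA gate), `msp+sfsrm`.  The binary baselines
default to the same straight-through surrogate as the multi-spike
gates: the rectangular window (width 1 mV around a 2 mV threshold)
never overlaps the membrane range reachable from a silent start on
this task, so its gradient support is empty and training cannot leave
the initial plateau; the rectangular rule remains available as a
configuration for users who want the convention, with the width under
their control.

## Known limitations

* Constant-current closed forms only; time-varying analytic inputs are
  out of scope (inputs are piecewise-constant by quantisation).
* The autodiff tape is eager and unoptimised; it is sized for the
  desk-scale networks here, not for benchmark-scale training.
* The SFA threshold resets every window; refractory periods,
  stochastic firing and decaying adaptive thresholds are not modelled.
* Softmax over raw spike counts can saturate for very long runs with
  high output rates; decoding follows the definition as printed.
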