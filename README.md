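# mapsnn

Multi-spike leaky integrate-and-fire neuron models, trainable state-free
synaptic response kernels, and BPTT-trained spiking networks with rate
decoding — with an exact event-driven oracle for validating every
discretisation.

## The problem

Gradient-trained spiking neural networks discretise the LIF membrane
equation `tau dv/dt = -(v - v_rest) + R I(t)` into per-window updates and
transmit a binary spike per timestep.  That binary ("single-spike")
convention silently assumes the step length `dt` is small: once `dt`
exceeds the neuron's inter-spike interval, binary neurons saturate at one
spike per window and undercount, so accuracy depends on an arbitrary
simulation constant.  This package implements the model family that fixes
this at the algorithmic level:

* **Exact discretisation.**  The *standard numerical model* solves each
  window in closed form (first-spike latency
  `t_alpha = -tau ln(1 - (v_th - V0)/(R I - V0))`, inter-spike interval
  `t_omega = -tau ln(1 - v_th/(R I))`), so its spike count is independent
  of `dt`.  A *simplified* first-order variant is accurate when
  `v_th/(R I)` is small.
* **Multi-spike gates.**  Neurons transmit an integer count per window,
  `s = g(v)`, paying a membrane cost `u = h(s)`.  The *Linear* gate is
  `s = floor(v/v_th)`; the *SFA* gate models spike-frequency adaptation
  with a geometrically growing per-spike threshold (`q > 1`), giving
  `s = floor(log_q(v/v_th (q-1) + 1))` — logarithmic counts, fewer spikes.
* **State-free synapses.**  Postsynaptic currents come from a causal
  convolution with a trainable delayed 2-exponential kernel
  `K(t) = exp(-a(t-delay)) - exp(-b(t-delay))` truncated to a few taps —
  temporal features without recursive synapse state.
* **Training.**  Fully connected networks of these neurons are trained by
  backpropagation-through-time with rate decoding (softmax over total
  output spike counts, cross-entropy loss); the floor's pseudo-derivative
  is the constant 1 (straight-through).  Gradients run on a small
  reverse-mode tape over numpy that ships with the package.

A synthetic event-stream generator (event-camera-like integer counts per
channel per bin, Poisson noise, class-specific temporal onsets) makes the
whole method exercisable at desk scale, and readers for the common
neuromorphic formats (ATIS event files, spiking-cochlea HDF5) are
included.

## Worked example

```python
from mapsnn import NeuronParams, SimulationConfig, event_driven_oracle, run_discrete_model

p = NeuronParams(tau=4.0, R=2.0, v_th=1.0)        # ms, ohm, mV
cfg = SimulationConfig(current=1.0, total_time=1000.0, dt=10.0)

print(len(event_driven_oracle(cfg, p)))                          # 360
print(run_discrete_model("standard", cfg, p).total_spikes())     # 360
print(run_discrete_model("soft_reset", cfg, p).total_spikes())   # 100
print(run_discrete_model("sfa_msp", cfg, p, q=1.2).total_spikes())  # 100
```

The exact event-driven simulation of this neuron fires 360 spikes in a
second (one every `4 ln 2 ≈ 2.77` ms).  The standard numerical model
reproduces exactly that count even with a coarse 10 ms step, while the
binary soft-reset neuron is capped at one spike per window — 100 — which
is the discretisation failure the multi-spike gates remove.

Longer narrative scripts live in `examples/`, one per capability:
closed-form window updates (`neuron_closed_forms.py`), the dt sweep with
claim checks (`timescale_sweep.py`), firing gates (`spike_gates.py`), the
synaptic kernel (`synaptic_kernel.py`), event binning and file formats
(`event_data_io.py`), and end-to-end training (`train_synthetic.py`).
`train_synthetic.py` trains the 100→64→3 network on the 3-class synthetic
task and prints the loss/accuracy table; it crosses 95% training
accuracy at epoch 22 (seed 1) and reaches 100% shortly after on one
CPU, with the characteristic flat "silent-start" epochs before the
first output spikes appear.

A thin CLI mirrors the library for shell use:

```bash
mapsnn sweep --out sweep.csv --plot panels.png
mapsnn simulate --model standard --dt-grid 0.5,1,2,5,10 --tau 4 --r 2 --out run.csv
mapsnn kernels --a 0.5 --b 1.0 --delay 0.8 --dump taps.csv
mapsnn synth --n-samples 30 --out events.csv
mapsnn train --gate msp+sfsrm --epochs 50 --log train.jsonl
```

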