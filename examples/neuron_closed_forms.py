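"""Closed-form LIF window updates and the event-driven oracle.

For a neuron with tau = 4 ms, R = 2 ohm, v_th = 1 mV driven by 1 mA,
the exact per-window solution gives the first-spike latency t_alpha,
the inter-spike interval t_omega and the spike count per window; the
event-driven simulator applies the same closed forms over a whole run.
"""

from mapsnn import (
    NeuronParams, SimulationConfig, event_driven_oracle,
    simplified_numerical_step, standard_numerical_step,
)

p = NeuronParams(tau=4.0, R=2.0, v_th=1.0)

out = standard_numerical_step(v0=0.0, Ic=1.0, dt=10.0, params=p)
print("Standard model, one 10 ms window from rest:")
print(f"  t_alpha = {out.t_alpha:.4f} ms   (first spike; = 4 ln 2)")
print(f"  t_omega = {out.t_omega:.4f} ms   (inter-spike interval)")
print(f"  n       = {out.n_spikes}          (spikes in the window)")
print(f"  V_r     = {out.v_residual:.4f} mV (residual potential)")

sim = simplified_numerical_step(v0=0.0, Ic=1.0, dt=10.0, params=p)
print(f"\nSimplified model on the same window: n = {sim.n_spikes} "
      "(first-order in v_th/(R I), crude at R=2)")

cfg = SimulationConfig(current=1.0, total_time=1000.0, dt=1.0)
times = event_driven_oracle(cfg, p)
print(f"\nEvent-driven run over 1000 ms: {len(times)} spikes, "
      f"first at {times[0]:.4f} ms, all {times[1]-times[0]:.4f} ms apart.")
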