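"""Multi-spike firing gates: Linear mode vs spike-frequency adaptation.

The Linear gate emits floor(v / v_th) spikes at constant cost per
spike; the SFA gate raises the per-spike threshold geometrically
(coefficient q), so counts grow logarithmically in the drive and dense
firing is suppressed.
"""

from mapsnn import LinearGate, SFAGate

lin = LinearGate(v_th=1.0)
sfa = SFAGate(v_th=1.0, q=1.5)

print(f"{'v (mV)':>8} | {'linear s':>8} {'cost u':>7} | "
      f"{'SFA n*':>7} {'SFA s':>5} {'cost u':>7}")
for v in (0.5, 1.0, 2.5, 5.0, 10.0, 20.0):
    a, b = lin(v), sfa(v)
    print(f"{v:8.1f} | {a.s:8d} {a.u:7.2f} | {b.n_star:7.3f} {b.s:5d} {b.u:7.2f}")

print("\nAt v = 2.5 the SFA neuron affords exactly 2 spikes "
      "(1.0 + 1.5 mV) while the linear one would fire 2 at 2.0 mV; "
      "by v = 20 the gap is wide (SFA fires "
      f"{sfa(20.0).s} vs linear {lin(20.0).s}).")
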