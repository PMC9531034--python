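"""Timescale robustness of the discrete LIF model family.

Runs every discrete neuron model under the constant-current protocol
(I = 1 mA, v_th = 1 mV, T = 1000 ms; tau in {4, 40} ms, R in {2, 20} ohm)
over a grid of step lengths, prints the spike-count table for one panel,
and checks the study's claims.  The key number: the standard numerical
model records the same total count at every dt — the event-driven exact
count — while binary neurons saturate at one spike per window.
"""

from mapsnn import SweepSpec, check_claims, run_sweep

spec = SweepSpec()
df = run_sweep(spec)

panel = df[(df.tau == 4.0) & (df.R == 2.0)]
print("Spike counts, tau=4 ms, R=2 ohm (event-driven count: "
      f"{int(panel.oracle_spikes.iloc[0])}):\n")
print(panel.pivot(index="dt", columns="model", values="total_spikes"))

print("\nClaim checks across all four (tau, R) panels:")
print(check_claims(df, spec).summary())
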