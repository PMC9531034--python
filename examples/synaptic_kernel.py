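"""The state-free synaptic response: a delayed 2-exponential kernel.

A spike train is converted into a postsynaptic current by a causal
convolution with K(t) = exp(-a(t-delay)) - exp(-b(t-delay)) (zero
before the onset delay), truncated to a finite number of taps — no
recursive synapse state.
"""

import numpy as np

from mapsnn import apply_response, build_kernel

k = build_kernel(a=0.5, b=1.0, delay=0.8, kernel_size=7, dt=1.0)
print("Sampled kernel taps (a=0.5, b=1.0, delay=0.8, 7 taps at 1 ms):")
print(" ", np.array_str(k.taps, precision=4))
print(f"  response window t_k = {k.t_k:.0f} ms")

spikes = np.array([2, 0, 0, 1, 0, 0, 0, 3, 0, 0, 0, 0])
trace = apply_response(spikes, k)
print("\nInteger spike counts :", spikes)
print("Response current     :", np.array_str(trace, precision=3))
print("\nEach spike launches a scaled copy of the kernel (the count 2 at"
      "\nt=0 doubles it); contributions older than 6 steps are dropped.")
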