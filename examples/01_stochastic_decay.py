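"""Dithered fixed-point decay: unbiased rounding and the time-constant ceiling.

The neuron stores its currents and membrane voltage as 4-bit codes and decays
them by multiplying with an 8-bit leak factor L (retention L/256), replacing
the truncated low bits with a 5-bit random dither.  This demo shows that the
rounding is exactly unbiased, and measures the largest effective time
constant the 1/32 dither resolution allows (~31 steps, i.e. ~30 ms at 1 ms
steps).
"""

import numpy as np

from cortexsim import decay_step, stochastic_round, tau_to_leak
from cortexsim.fixedpoint import measure_decay_tau

# Unbiasedness: averaging floor((q+r)/32) over all 32 dithers returns q/32.
q = 48
vals = [stochastic_round(q, r) for r in range(32)]
print(f"stochastic_round({q}, r) over all dithers: mean={sum(vals)/32} (exact {q/32})")

# One decay step of code 7 at half leak (L=128): mean is 3.5 = 7 * 128/256.
vals = [decay_step(7, 128, r) for r in range(32)]
print(f"decay_step(7, L=128): values {{3,4}}, mean={sum(vals)/32}")

# Leak factors for the published time constants.
for tau in (5.8, 3.0, 10.0):
    print(f"tau={tau:5.1f} ms -> L={tau_to_leak(tau)} (retention {tau_to_leak(tau)/256:.4f})")

# The 5-bit dither caps the slowest decay at retention 31/32 (L=248):
# fitting the ensemble-mean trajectory of 10^4 trajectories gives tau ~ 31.5
# steps, i.e. the advertised ~30 ms ceiling.
tau = measure_decay_tau(248, n=10_000, steps=100, seed=1)
print(f"effective tau at L=248: {tau:.2f} steps (ceiling -1/ln(31/32) = "
      f"{-1/np.log(31/32):.2f})")
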