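"""Axonal delay storage: exact release and the stochastic multi-rate readout.

Events fan out into 16 FIFO queues (delays 1-16 ms).  The functional mode
releases a copy exactly `delay` steps after enqueue.  The faithful mode
mirrors the hardware: each access slot picks a queue with probability
P_i proportional to 1/i (encoded as 20-bit cumulative thresholds against an
LFSR draw), so draining equal loads takes time proportional to the delay
value — the mechanism that turns a readout *rate* into an expected *delay*.
"""

import numpy as np

from cortexsim import DelayStore, SpikeCountEvent, build_delay_distribution, enqueue_event, exact_read_step
from cortexsim.axon import ReadoutRng, stochastic_read_step
from cortexsim.lut import PostConnection, PostTarget

# exact mode: enqueue at t=5 with delay 3 -> released at t=8
store = DelayStore()
post = PostConnection((PostTarget(hc_offset=0, delay_ms=3, conn_id=0),))
enqueue_event(store, SpikeCountEvent(0, np.zeros(8)), post, t=5)
for t in (6, 7, 8):
    out = exact_read_step(store, t)
    print(f"t={t}: released {len(out)} copies")

# stochastic mode: the drain-time ratio experiment
dist = build_delay_distribution(f=0)
print(f"P_1={dist.P[0]:.4f} (=1/H16), P_1/P_16={dist.P[0]/dist.P[15]:.1f}, "
      f"sum(R_i)={int(dist.R.sum())} (~2^20={1 << 20})")

N = 1000
store = DelayStore()
for d in range(1, 17):
    p = PostConnection((PostTarget(0, d, 0),))
    for _ in range(N):
        enqueue_event(store, SpikeCountEvent(0, np.zeros(8)), p, t=0)
rng = ReadoutRng.from_seed(3)
drain_at = np.zeros(16, np.int64)
access = 0
while store.occupancy().sum():
    access += 1
    stochastic_read_step(store, dist, rng)
    done = (store.occupancy() == 0) & (drain_at == 0)
    drain_at[done] = access
print(f"loaded {N} copies per queue; drained after {access} access slots")
print("drain-time ratios vs delay 1:",
      np.round(drain_at / drain_at[0], 2))
print("  (ideal 1:2:...:16 — the readout rates realize the delay ratios)")
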