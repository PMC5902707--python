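"""Event propagation with programmable axonal delays.

At transmit time an event is expanded into one copy per fan-out target
(up to 16), each appended to the FIFO queue of its delay value (1–16 ms).
Odd delays live in one storage bank and even delays in the other, mirroring
the alternating access pattern of the two single-port memories the design
time-shares.

Two readout modes exist:

* *exact* — the functional default: a copy enqueued at ``t`` with delay
  ``d`` is released at exactly ``t + d``, FIFO within each queue.
* *stochastic* — the faithful model of the hardware readout: each access
  slot draws a delay queue with probability ``P_i ∝ 1/i`` (so draining N
  events from the delay-``i`` queue takes ~``i`` times longer than from the
  delay-1 queue), gated by a global probability knob ``f`` that scales all
  delays together.  The probabilities are normalized to 20-bit integers
  ``R_i`` forming cumulative thresholds ``T_i`` compared against a 20-bit
  LFSR draw, exactly as the hardware does.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .fixedpoint import Lfsr, seed_lfsr_state
from .lut import DELAY_MAX, DELAY_MIN, PostConnection
from .minicolumn import SpikeCountEvent

__all__ = [
    "DelayedEvent",
    "DelayStore",
    "DelayDistribution",
    "build_delay_distribution",
    "ReadoutRng",
    "enqueue_event",
    "exact_read_step",
    "stochastic_read_step",
]

N_DELAYS = DELAY_MAX  # 16 queues
THRESHOLD_BITS = 20
GATE_BITS = 10


@dataclass(frozen=True)
class DelayedEvent:
    """One fan-out copy in flight: the event, which of the source's (up to 16)
    connections it used, and when it was enqueued."""

    event: SpikeCountEvent
    conn_id: int
    enqueue_time: int
    delay_ms: int


@dataclass
class DelayStore:
    """16 FIFO queues (delay 1..16 ms) with conservation counters."""

    queues: list[deque] = field(default_factory=lambda: [deque() for _ in range(N_DELAYS)])
    enqueued: np.ndarray = field(default_factory=lambda: np.zeros(N_DELAYS, np.int64))
    released: np.ndarray = field(default_factory=lambda: np.zeros(N_DELAYS, np.int64))

    def queue(self, delay_ms: int) -> deque:
        if not DELAY_MIN <= delay_ms <= DELAY_MAX:
            raise ValueError("delay must be 1..16 ms")
        return self.queues[delay_ms - 1]

    def occupancy(self) -> np.ndarray:
        return np.array([len(q) for q in self.queues], dtype=np.int64)

    def bank(self, delay_ms: int) -> str:
        """Odd delays -> bank 'A', even delays -> bank 'B'."""
        return "A" if delay_ms % 2 == 1 else "B"

    def conserved(self) -> bool:
        """Per-queue conservation: enqueued == released + still queued."""
        return bool(np.all(self.enqueued == self.released + self.occupancy()))


def enqueue_event(
    store: DelayStore, ev: SpikeCountEvent, post: PostConnection, t: int
) -> None:
    """Fan out ``ev`` at time ``t``: one delayed copy per post target."""
    for target in post.targets:
        store.queue(target.delay_ms).append(
            DelayedEvent(ev, target.conn_id, t, target.delay_ms)
        )
        store.enqueued[target.delay_ms - 1] += 1


def exact_read_step(store: DelayStore, t: int) -> list[DelayedEvent]:
    """Release every copy due at ``t`` (enqueue_time + delay == t), FIFO order.

    Valid because enqueue times are nondecreasing within a queue, so all due
    copies sit at the head.
    """
    out: list[DelayedEvent] = []
    for d in range(DELAY_MIN, DELAY_MAX + 1):
        q = store.queues[d - 1]
        while q and q[0].enqueue_time + d <= t:
            ev = q.popleft()
            if ev.enqueue_time + d < t:
                raise RuntimeError("missed a due release; steps must be contiguous")
            out.append(ev)
            store.released[d - 1] += 1
    return out


# -- stochastic (faithful) readout ------------------------------------------

@dataclass(frozen=True)
class DelayDistribution:
    """Per-delay readout probabilities and their 20-bit threshold encoding.

    ``P_i = P_1 / i`` with ``sum P_i = 1`` (so ``P_1 = 1/H_16``, the
    reciprocal 16th harmonic number); ``R_i = round(P_i * 2^20)``;
    ``T`` holds the 17 cumulative thresholds with ``T_0 = 0``.  ``f`` is the
    10-bit global probability: a readout slot is enabled iff
    ``f <= draw10``, i.e. with probability ``(1024 - f)/1024``.
    """

    P: np.ndarray
    R: np.ndarray
    T: np.ndarray
    f: int


def build_delay_distribution(f: int = 0) -> DelayDistribution:
    if not 0 <= f <= (1 << GATE_BITS) - 1:
        raise ValueError("f must be a 10-bit value")
    i = np.arange(1, N_DELAYS + 1, dtype=np.float64)
    P = (1.0 / i) / np.sum(1.0 / i)
    R = np.round(P * (1 << THRESHOLD_BITS)).astype(np.int64)
    T = np.concatenate(([0], np.cumsum(R)))
    return DelayDistribution(P=P, R=R, T=T, f=f)


@dataclass
class ReadoutRng:
    """The two LFSRs driving the stochastic readout: a 10-bit gate stream and
    a 20-bit delay-selection stream."""

    gate: Lfsr
    select: Lfsr

    @classmethod
    def from_seed(cls, global_seed: int) -> "ReadoutRng":
        return cls(
            gate=Lfsr(GATE_BITS, seed_lfsr_state(global_seed, 0xA10, GATE_BITS)),
            select=Lfsr(THRESHOLD_BITS, seed_lfsr_state(global_seed, 0xA20, THRESHOLD_BITS)),
        )


def stochastic_read_step(
    store: DelayStore, dist: DelayDistribution, rng: ReadoutRng
) -> DelayedEvent | None:
    """One readout access slot; returns a released copy or ``None``.

    The gate draw may disable the slot entirely (global probability ``f``);
    otherwise the 20-bit draw selects a delay queue through the cumulative
    thresholds, and the head of that queue is popped if it has one.  An empty
    selected queue simply wastes the slot ("wait for the next clock cycle").
    """
    draw10 = rng.gate.draw_bits(GATE_BITS)
    if dist.f > draw10:
        return None
    draw20 = rng.select.draw_bits(THRESHOLD_BITS)
    i = int(np.searchsorted(dist.T, draw20, side="right")) - 1
    if not 0 <= i < N_DELAYS:
        return None  # draw beyond T_16 (rounding slack): wasted slot
    q = store.queues[i]
    if not q:
        return None
    ev = q.popleft()
    store.released[i] += 1
    return ev
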