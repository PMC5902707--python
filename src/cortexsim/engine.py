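"""The master scheduler: the 1 ms simulation loop and the hardware timing model.

Each step runs the fixed phase order

1. **compute** — every bound slot reads-and-clears its accumulated synaptic
   input W, updates its 100 neurons, and emits a spike-count event if any
   type spiked;
2. **expand** — events fan out through their source's post-connection
   targets into the axonal delay queues;
3. **deliver** — copies due this step (plus external stimulus input) are
   weight-modulated, mapped to destination minicolumns, and accumulated into
   the arbiters, binding fresh slots for previously silent addresses;
4. **release** — slots whose minicolumn is fully quiescent (all PSC and
   membrane codes zero, no pending W) are unbound;
5. **record**.

Inputs delivered in step ``t`` are integrated by the neurons in step
``t + 1`` (W is read at the start of the next compute phase).  The loop is a
pure function of (network, seed): slot iteration is by slot index and all
groupings are in sorted order, so reruns are bit-identical.

The neuron arithmetic here is a vectorized twin of the scalar reference in
:mod:`cortexsim.neuron`; a property test pins the two to each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .axon import (
    DelayDistribution,
    DelayedEvent,
    DelayStore,
    ReadoutRng,
    build_delay_distribution,
    enqueue_event,
    exact_read_step,
    stochastic_read_step,
)
from .fixedpoint import splitmix64, splitmix64_array
from .lut import MC_BITS, ParameterLut
from .minicolumn import COUNT_MAX, MinicolumnSpec, N_LANES, N_TYPES, SpikeCountEvent
from .neuron import Q4_MAX, Q4_MIN
from .synapse import (
    Arbiter,
    N_ARBITERS,
    _ARBITER_SHIFT,
    map_destination_batch,
)

__all__ = [
    "TimingModel",
    "estimate_update_period",
    "real_time_capacity",
    "addressable_capacity",
    "CompiledSpec",
    "CompiledNetwork",
    "SimRecorders",
    "Simulator",
]

_LFSR20_TAPS = (19, 2)
_LFSR20_WIDTH = 20


# -- timing model ------------------------------------------------------------

@dataclass(frozen=True)
class TimingModel:
    """Cycle accounting of the time-multiplexed update loop.

    The minicolumn pool is processed in segments of ``segment_size`` slots
    (one clock cycle each, matching the memory burst length); between two
    segment bursts the event store gets an access window of up to
    ``slot_cycles`` cycles.
    """

    n_tm: int
    clock_period_ns: float = 5.0
    segment_size: int = 1024
    slot_cycles: int = 200

    def __post_init__(self) -> None:
        if min(self.n_tm, self.segment_size) <= 0 or self.clock_period_ns <= 0:
            raise ValueError("timing parameters must be positive")
        if self.slot_cycles < 0:
            raise ValueError("slot_cycles must be nonnegative")


def estimate_update_period(tm: TimingModel) -> float:
    """Wall-clock milliseconds per 1 ms update of all ``n_tm`` slots:
    ``ceil(n_tm / segment) * (segment + slot) * clock``."""
    segments = math.ceil(tm.n_tm / tm.segment_size)
    return segments * (tm.segment_size + tm.slot_cycles) * tm.clock_period_ns * 1e-6


def real_time_capacity(
    clock_period_ns: float = 5.0,
    budget_ms: float = 1.0,
    segment_size: int = 1024,
    slot_cycles: int = 0,
) -> int:
    """Largest slot count updatable within ``budget_ms`` of wall clock.

    Each slot costs one cycle plus its share ``slot_cycles / segment_size``
    of the inter-segment access window.
    """
    budget_cycles = int(budget_ms * 1e6 / clock_period_ns)
    return budget_cycles * segment_size // (segment_size + slot_cycles)


def addressable_capacity(n_tm: int, assignment_ratio: int) -> int:
    """Addressable dynamically-assigned minicolumns: pool size x ratio."""
    return n_tm * assignment_ratio


# -- compiled network --------------------------------------------------------

@dataclass(frozen=True)
class CompiledSpec:
    """Per-lane parameter arrays of one minicolumn spec (shape (100,))."""

    L_epsc: np.ndarray
    L_ipsc: np.ndarray
    L_mem: np.ndarray
    L_rfc: np.ndarray
    g_syn: np.ndarray
    g_psc: np.ndarray
    u_reset: np.ndarray
    lane_types: np.ndarray
    onehot: np.ndarray  # (100, 8) lane -> type indicator, for count sums

    @classmethod
    def from_spec(cls, spec: MinicolumnSpec) -> "CompiledSpec":
        lt = spec.lane_types().astype(np.int64)
        def per_lane(attr):
            vals = np.array([getattr(p, attr) for p in spec.params], dtype=np.int32)
            return vals[lt]
        onehot = np.zeros((N_LANES, N_TYPES), dtype=np.int32)
        onehot[np.arange(N_LANES), lt] = 1
        return cls(
            L_epsc=per_lane("L_epsc"),
            L_ipsc=per_lane("L_ipsc"),
            L_mem=per_lane("L_mem"),
            L_rfc=per_lane("L_rfc"),
            g_syn=per_lane("g_syn_code"),
            g_psc=per_lane("g_psc_code"),
            u_reset=per_lane("u_reset"),
            lane_types=lt,
            onehot=onehot,
        )


def _gain_mul(code: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized gain product, rounded to nearest (ties away from zero)."""
    num = (code + 1) * x
    return np.where(num >= 0, (num + 8) >> 4, -((-num + 8) >> 4))


def neuron_kernel(
    psc: np.ndarray,
    u: np.ndarray,
    W_lane: np.ndarray,
    cs: CompiledSpec,
    r1: np.ndarray,
    r2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized neuron update over an (n_slots, 100) block.

    Mirrors :func:`cortexsim.neuron.neuron_step` exactly, elementwise.
    Returns ``(psc_new, u_new, spikes)`` as int32/bool arrays.
    """
    psc = psc.astype(np.int32)
    u = u.astype(np.int32)
    # PSC generator
    L = np.where(psc >= 0, cs.L_epsc, cs.L_ipsc)
    m = np.abs(psc)
    dec = ((m * L >> 3) + r1) >> 5
    dec = np.sign(psc) * dec
    drive = np.clip(_gain_mul(cs.g_syn, W_lane), Q4_MIN, Q4_MAX)
    psc_new = np.clip(dec + drive, Q4_MIN, Q4_MAX)
    # soma
    active = u >= 0
    dec_u = ((np.abs(u) * cs.L_mem >> 3) + r2) >> 5  # active branch magnitude
    total = dec_u + _gain_mul(cs.g_psc, psc_new)
    spikes = active & (total > Q4_MAX) & (psc_new > 0)
    u_act = np.where(
        total > Q4_MAX,
        np.where(psc_new > 0, cs.u_reset, Q4_MAX),
        np.where(total < Q4_MIN, cs.u_reset, total),
    )
    u_ref = -((((-u).clip(min=0) * cs.L_rfc >> 3) + r2) >> 5)
    u_new = np.where(active, u_act, u_ref)
    return psc_new, u_new, spikes


class CompiledNetwork:
    """Vector tables compiled from a :class:`ParameterLut` for the engine."""

    def __init__(self, lut: ParameterLut) -> None:
        if len(lut) == 0:
            raise ValueError("cannot compile an empty network")
        self.lut = lut
        # dedupe specs by identity
        spec_ids: dict[int, int] = {}
        self.specs: list[CompiledSpec] = []
        self.range_spec: np.ndarray = np.zeros(len(lut), dtype=np.int64)
        for ri, entry in enumerate(lut.entries):
            key = id(entry.spec)
            if key not in spec_ids:
                spec_ids[key] = len(self.specs)
                self.specs.append(CompiledSpec.from_spec(entry.spec))
            self.range_spec[ri] = spec_ids[key]
        # pre-connection rules: (range, conn_id) -> rule id with dense arrays
        self.rule_index: dict[tuple[int, int], int] = {}
        self.rule_pre = []
        self.rule_conn: list[int] = []
        self.rule_M: list[np.ndarray] = []  # (8, 8) masked weights, int32
        for ri, entry in enumerate(lut.entries):
            for cid, (pre, mask) in sorted(entry.pre.items()):
                self.rule_index[(ri, cid)] = len(self.rule_pre)
                self.rule_pre.append(pre)
                self.rule_conn.append(cid)
                self.rule_M.append(
                    mask.mask.astype(np.int32) * pre.weights.astype(np.int32)
                )
        # post targets per range: list of (delay, conn_id, rule_id)
        self.range_post: list[list[tuple[int, int, int]]] = []
        for ri, entry in enumerate(lut.entries):
            targets = []
            for tgt in entry.post.targets:
                rule_id = self.rule_index.get((ri, tgt.conn_id))
                if rule_id is None:
                    raise ValueError(
                        f"range {ri}: post target conn_id {tgt.conn_id} has no "
                        f"pre-connection rule"
                    )
                targets.append((tgt.delay_ms, tgt.conn_id, rule_id))
            self.range_post.append(targets)


# -- recorders ---------------------------------------------------------------

@dataclass
class SimRecorders:
    """Run outputs: events, occupancy trace, lane-level spikes, statistics."""

    record_spikes: bool = False
    # (t, addr, 8 counts) per emitted event, chunked per step
    event_chunks: list = field(default_factory=list)
    occupancy: list = field(default_factory=list)  # (t, active_count)
    spike_chunks: list = field(default_factory=list)  # (t, addrs, lanes)
    enqueued_total: int = 0
    delivered_total: int = 0
    bypass_hits: int = 0
    overflow_count: int = 0

    def events(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All events as (t array, addr array, counts (n, 8) array)."""
        if not self.event_chunks:
            z = np.zeros(0, np.int64)
            return z, z, np.zeros((0, N_TYPES), np.int64)
        ts = np.concatenate([np.full(len(a), t) for t, a, _ in self.event_chunks])
        addrs = np.concatenate([a for _, a, _ in self.event_chunks])
        counts = np.concatenate([c for _, _, c in self.event_chunks])
        return ts, addrs, counts

    def occupancy_trace(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.occupancy:
            return np.zeros(0, np.int64), np.zeros(0, np.int64)
        arr = np.asarray(self.occupancy, dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def spikes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Lane-level spikes as (t, addr, lane) arrays (if recorded)."""
        if not self.spike_chunks:
            z = np.zeros(0, np.int64)
            return z, z, z
        ts = np.concatenate([np.full(len(a), t) for t, a, _ in self.spike_chunks])
        addrs = np.concatenate([a for _, a, _ in self.spike_chunks])
        lanes = np.concatenate([l for _, _, l in self.spike_chunks])
        return ts, addrs, lanes


# -- the simulator -----------------------------------------------------------

class Simulator:
    """Event-driven simulation of a compiled network.

    Parameters
    ----------
    network:
        A :class:`CompiledNetwork` (or a :class:`ParameterLut`, compiled on
        the fly).
    seed:
        Global seed; every random stream (dither, destination selection,
        stochastic readout) derives from it.
    mode:
        ``"exact"`` (integer-ms delays, the functional default) or
        ``"stochastic"`` (the faithful multi-rate readout with
        ``accesses_per_ms`` readout slots per step).
    capacity:
        Slots per arbiter (default 2^16).
    shift:
        Right-shift applied in weight modulation (default 0).
    strict_overflow:
        If True, an arbiter running out of slots raises; otherwise the
        delivery is dropped and counted.
    """

    def __init__(
        self,
        network: CompiledNetwork | ParameterLut,
        seed: int,
        mode: str = "exact",
        capacity: int = 1 << 16,
        shift: int = 0,
        accesses_per_ms: int = 200,
        f: int = 0,
        record_spikes: bool = False,
        strict_overflow: bool = False,
    ) -> None:
        if isinstance(network, ParameterLut):
            network = CompiledNetwork(network)
        if mode not in ("exact", "stochastic"):
            raise ValueError("mode must be 'exact' or 'stochastic'")
        self.net = network
        self.seed = int(seed)
        self.mode = mode
        self.capacity = capacity
        self.shift = shift
        self.strict_overflow = strict_overflow
        self.t = 0
        self.arbiters = [Arbiter(capacity) for _ in range(N_ARBITERS)]
        # per-arbiter neuron state and dither-stream arrays, allocated lazily
        self._psc: list = [None] * N_ARBITERS
        self._u: list = [None] * N_ARBITERS
        self._dither: list = [None] * N_ARBITERS  # (capacity, 100, 2) uint32
        self._spec_of: list = [None] * N_ARBITERS
        self._seed_mix = np.uint64(splitmix64(self.seed) & ((1 << 63) - 1))
        # exact-mode schedule: release time -> list of (addrs, counts, rule_id)
        self._schedule: dict[int, list] = {}
        self._pending = 0
        # stochastic-mode structures
        self.delay_store = DelayStore()
        self.delay_dist: DelayDistribution = build_delay_distribution(f)
        self.readout_rng = ReadoutRng.from_seed(self.seed)
        self.accesses_per_ms = accesses_per_ms
        self.rec = SimRecorders(record_spikes=record_spikes)
        self.dropped = 0
        self.released_total = 0
        self.enqueued_total = 0

    # -- slot plumbing ------------------------------------------------------

    def _ensure_arrays(self, a: int) -> None:
        if self._psc[a] is None:
            self._psc[a] = np.zeros((self.capacity, N_LANES), np.int8)
            self._u[a] = np.zeros((self.capacity, N_LANES), np.int8)
            self._dither[a] = np.zeros((self.capacity, N_LANES, 2), np.uint32)
            self._spec_of[a] = np.zeros(self.capacity, np.int16)

    def _bind(self, a: int, addr: int, range_idx: int) -> int | None:
        """Bind ``addr`` in arbiter ``a``; seed its dither streams."""
        from .synapse import ArbiterOverflowError

        self._ensure_arrays(a)
        try:
            slot = self.arbiters[a]._allocate(addr)
        except ArbiterOverflowError:
            if self.strict_overflow:
                raise
            self.dropped += 1
            return None
        self._psc[a][slot] = 0
        self._u[a][slot] = 0
        self._spec_of[a][slot] = self.net.range_spec[range_idx]
        # one 20-bit LFSR per (address, lane, stage): binding-order independent
        lane_keys = (
            (np.uint64(addr) << np.uint64(9))
            | (np.arange(N_LANES, dtype=np.uint64) << np.uint64(2))
        )
        for stage in (0, 1):
            s = splitmix64_array((lane_keys ^ np.uint64(stage)) ^ self._seed_mix)
            s &= np.uint64((1 << _LFSR20_WIDTH) - 1)
            s[s == 0] = 1
            self._dither[a][slot, :, stage] = s.astype(np.uint32)
        return slot

    def active_minicolumn_count(self) -> int:
        """Bound dynamically-assigned minicolumns (after the release phase
        this equals the number of columns failing the quiescence test)."""
        return sum(arb.occupancy for arb in self.arbiters)

    # -- phases --------------------------------------------------------------

    def _draw_dithers(self, a: int, slots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Advance the slots' 20-bit LFSRs 5 steps; low 5 bits are the dither."""
        states = self._dither[a][slots]  # copy (fancy indexing)
        for _ in range(5):
            fb = ((states >> _LFSR20_TAPS[0]) ^ (states >> _LFSR20_TAPS[1])) & 1
            states = ((states << 1) | fb) & ((1 << _LFSR20_WIDTH) - 1)
        self._dither[a][slots] = states
        r = (states & 31).astype(np.int32)
        return r[..., 0], r[..., 1]

    def _compute_phase(self) -> tuple[np.ndarray, np.ndarray]:
        """Update every bound slot; return (event addrs, event counts)."""
        ev_addrs, ev_counts = [], []
        for a in range(N_ARBITERS):
            arb = self.arbiters[a]
            if arb.occupancy == 0:
                continue
            slots = arb.bound_slots()
            spec_ids = self._spec_of[a][slots]
            r1, r2 = self._draw_dithers(a, slots)
            W_all = arb.W[slots].astype(np.int32)
            arb.W[slots] = 0  # read-and-clear
            for sid in np.unique(spec_ids):
                sel = spec_ids == sid
                sl = slots[sel]
                cs = self.net.specs[sid]
                W_lane = W_all[sel][:, cs.lane_types]
                psc_new, u_new, spikes = neuron_kernel(
                    self._psc[a][sl], self._u[a][sl], W_lane, cs, r1[sel], r2[sel]
                )
                self._psc[a][sl] = psc_new.astype(np.int8)
                self._u[a][sl] = u_new.astype(np.int8)
                counts = np.minimum(spikes.astype(np.int32) @ cs.onehot, COUNT_MAX)
                fired = counts.sum(axis=1) > 0
                if np.any(fired):
                    addrs = arb.addr_of[sl[fired]]
                    ev_addrs.append(addrs)
                    ev_counts.append(counts[fired].astype(np.uint8))
                if self.rec.record_spikes and np.any(spikes):
                    rows, lanes = np.nonzero(spikes)
                    self.rec.spike_chunks.append(
                        (self.t, arb.addr_of[sl[rows]], lanes)
                    )
        if not ev_addrs:
            return np.zeros(0, np.int64), np.zeros((0, N_TYPES), np.uint8)
        return np.concatenate(ev_addrs), np.concatenate(ev_counts)

    def _expand_phase(self, addrs: np.ndarray, counts: np.ndarray) -> None:
        """Fan events out into the delay storage."""
        if len(addrs) == 0:
            return
        ranges = self.net.lut.lookup_range_array(addrs)
        for ri in np.unique(ranges):
            sel = ranges == ri
            a_sel, c_sel = addrs[sel], counts[sel]
            for delay, conn_id, rule_id in self.net.range_post[ri]:
                if self.mode == "exact":
                    self._schedule.setdefault(self.t + delay, []).append(
                        (a_sel, c_sel, rule_id)
                    )
                    self._pending += len(a_sel)
                else:
                    for addr, cnt in zip(a_sel, c_sel):
                        ev = SpikeCountEvent(int(addr), cnt)
                        self.delay_store.queue(delay).append(
                            DelayedEvent(ev, conn_id, self.t, delay)
                        )
                        self.delay_store.enqueued[delay - 1] += 1
                self.rec.enqueued_total += len(a_sel)
                self.enqueued_total += len(a_sel)

    def _released_chunks(self) -> list:
        """Delayed-event chunks due this step: (addrs, counts, rule_id)."""
        if self.mode == "exact":
            chunks = self._schedule.pop(self.t, [])
            n = sum(len(a) for a, _, _ in chunks)
            self._pending -= n
            self.released_total += n
            return chunks
        released: dict[tuple[int, int], list] = {}
        for _ in range(self.accesses_per_ms):
            dev = stochastic_read_step(self.delay_store, self.delay_dist, self.readout_rng)
            if dev is None:
                continue
            ri = self.net.lut.lookup_range(dev.event.address)
            rule_id = self.net.rule_index[(ri, dev.conn_id)]
            released.setdefault((ri, rule_id), []).append(dev)
            self.released_total += 1
        chunks = []
        for (_, rule_id), devs in sorted(released.items()):
            chunks.append(
                (
                    np.array([d.event.address for d in devs], np.int64),
                    np.stack([d.event.counts for d in devs]),
                    rule_id,
                )
            )
        return chunks

    def _deliver_phase(self, chunks: list, stim_addrs, stim_W) -> None:
        """Weight-modulate, map destinations, and accumulate into arbiters."""
        dest_list, W_list = [], []
        for addrs, counts, rule_id in chunks:
            pre = self.net.rule_pre[rule_id]
            M = self.net.rule_M[rule_id]
            W_ev = counts.astype(np.int32) @ M.T  # (e, 8) per-dest-type sums
            W_ev = np.clip(W_ev >> self.shift, Q4_MIN, Q4_MAX)
            conn_id = self.net.rule_conn[rule_id]
            dests = map_destination_batch(addrs, conn_id, pre, self.seed)
            e, csize = dests.shape
            dest_list.append(dests.reshape(-1))
            W_list.append(np.repeat(W_ev, csize, axis=0))
        if stim_addrs is not None and len(stim_addrs):
            dest_list.append(np.asarray(stim_addrs, np.int64))
            W_list.append(np.asarray(stim_W, np.int32).reshape(len(stim_addrs), N_TYPES))
        if not dest_list:
            return
        dests = np.concatenate(dest_list)
        W_all = np.concatenate(W_list)
        self.rec.delivered_total += len(dests)
        arb_ids = dests >> _ARBITER_SHIFT
        for a in np.unique(arb_ids):
            sel = arb_ids == a
            uniq, inverse = np.unique(dests[sel], return_inverse=True)
            sums = np.zeros((len(uniq), N_TYPES), np.int32)
            np.add.at(sums, inverse, W_all[sel])
            arb = self.arbiters[int(a)]
            slots = np.empty(len(uniq), np.int64)
            missing = np.array([addr not in arb.slot_of for addr in uniq])
            if np.any(missing):
                new_ranges = self.net.lut.lookup_range_array(uniq[missing])
            mi = 0
            keep = np.ones(len(uniq), bool)
            for k, addr in enumerate(uniq):
                addr = int(addr)
                slot = arb.slot_of.get(addr)
                if slot is None:
                    slot = self._bind(int(a), addr, int(new_ranges[mi]))
                    mi += 1
                    if slot is None:  # overflow drop (non-strict)
                        keep[k] = False
                        continue
                slots[k] = slot
            arb.accumulate_batch(slots[keep], sums[keep])

    def _release_phase(self) -> None:
        for a in range(N_ARBITERS):
            arb = self.arbiters[a]
            if arb.occupancy == 0:
                continue
            slots = arb.bound_slots()
            quiet = (
                ~np.any(self._psc[a][slots], axis=1)
                & ~np.any(self._u[a][slots], axis=1)
                & ~np.any(arb.W[slots], axis=1)
            )
            if np.any(quiet):
                arb.free_slots(slots[quiet])

    # -- public loop ---------------------------------------------------------

    def step(self, stim_addrs=None, stim_W=None) -> None:
        """Advance one 1 ms step, optionally injecting external stimulus
        deliveries (pre-weighted (address, 8xW) pairs for this step)."""
        addrs, counts = self._compute_phase()
        if len(addrs):
            self.rec.event_chunks.append((self.t, addrs, counts.astype(np.int64)))
        self._expand_phase(addrs, counts)
        chunks = self._released_chunks()
        self._deliver_phase(chunks, stim_addrs, stim_W)
        self._release_phase()
        self.rec.occupancy.append((self.t, self.active_minicolumn_count()))
        self.rec.bypass_hits = sum(arb.bypass_hits for arb in self.arbiters)
        self.rec.overflow_count = sum(arb.overflow_count for arb in self.arbiters)
        self.t += 1

    def run(self, duration_ms: int, stimulus=None) -> SimRecorders:
        """Run ``duration_ms`` steps.  ``stimulus`` maps step -> (addrs, W)."""
        for _ in range(duration_ms):
            if stimulus is not None:
                sa, sw = stimulus.get(self.t, (None, None))
            else:
                sa, sw = None, None
            self.step(sa, sw)
        return self.rec

    def pending_events(self) -> int:
        """Copies still sitting in delay storage."""
        if self.mode == "exact":
            return self._pending
        return int(self.delay_store.occupancy().sum())
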