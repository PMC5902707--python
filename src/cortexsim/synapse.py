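"""Receive-side event processing: destination mapping, weight modulation,
and dynamic assignment of active minicolumns to time-multiplexed slots.

A delayed event copy names its source minicolumn and which of the source's
connections it travelled.  The receive side:

1. adds the connection's 20-bit hypercolumn offset to the source hypercolumn
   (wrapping modulo 2^20) and draws ``conn_size`` *fixed* pseudo-random
   destination minicolumns inside the destination hypercolumn — fixed in the
   sense that the same (source address, connection, global seed) always maps
   to the same destination set;
2. multiplies the eight per-type spike counts by the eight per-source-type
   weights and sums them into eight per-destination-type accumulators under
   the 8x8 type mask, saturating into the signed 4-bit range;
3. hands each (destination address, W) pair to one of 16 arbiters (selected
   by the top 4 address bits), which binds the address to a free
   time-multiplexed slot if it does not already hold one, and accumulates W
   into the slot otherwise.

Slot binding is the dynamic-assignment mechanism that lets a bounded pool of
physical update slots serve a vastly larger address space of mostly-silent
minicolumns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixedpoint import splitmix64, splitmix64_array
from .lut import HC_BITS, MC_BITS, PreConnection, TypeMask
from .minicolumn import N_TYPES
from .neuron import Q4_MAX, Q4_MIN

__all__ = [
    "N_ARBITERS",
    "map_destination",
    "map_destination_batch",
    "modulate_weights",
    "Arbiter",
    "ArbiterOverflowError",
    "SynapseArray",
    "arbiter_index",
]

N_ARBITERS = 16
_ARBITER_SHIFT = 23  # top 4 bits of the 27-bit address


def arbiter_index(addr: int) -> int:
    return addr >> _ARBITER_SHIFT


def _dest_keys(src_addr, conn_id, global_seed: int, n: int) -> np.ndarray:
    """Keyed-hash ranking keys for destination selection.

    Row ``j`` gets ``splitmix64(mix(src, conn, seed) ^ (j+1))``; the
    ``conn_size`` smallest keys select the destination minicolumn indices.
    Vectorized over a batch of sources.
    """
    base = splitmix64_array(
        (np.asarray(src_addr, dtype=np.uint64) << np.uint64(8))
        ^ np.asarray(conn_id, dtype=np.uint64)
        ^ np.uint64(splitmix64(global_seed) & 0xFFFFFFFFFFFF)
    )
    j = np.arange(1, n + 1, dtype=np.uint64)
    return splitmix64_array(base[..., None] ^ j)


def map_destination(
    src_addr: int, conn_id: int, pre: PreConnection, global_seed: int
) -> np.ndarray:
    """Destination addresses for one event copy (sorted ascending).

    ``conn_size`` distinct minicolumn indices in ``[0, dest_hc_size)`` are
    selected by ranking keyed hashes — a deterministic function of
    (source address, conn_id, global seed) only, so repeated events from the
    same source always land on the same destination set.
    """
    src_hc = src_addr >> MC_BITS
    dest_hc = (src_hc + pre.offset) % (1 << HC_BITS)
    keys = _dest_keys(src_addr, conn_id, global_seed, pre.dest_hc_size)
    mc_idx = np.sort(np.argsort(keys, kind="stable")[: pre.conn_size])
    return (dest_hc << MC_BITS) | mc_idx.astype(np.int64)


def map_destination_batch(
    src_addrs: np.ndarray, conn_id: int, pre: PreConnection, global_seed: int
) -> np.ndarray:
    """Vectorized :func:`map_destination`: ``(n, conn_size)`` addresses."""
    src_addrs = np.asarray(src_addrs, dtype=np.int64)
    dest_hc = (
        (src_addrs >> MC_BITS) + pre.offset
    ) % (1 << HC_BITS)
    keys = _dest_keys(src_addrs, conn_id, global_seed, pre.dest_hc_size)
    order = np.argsort(keys, axis=-1, kind="stable")[:, : pre.conn_size]
    mc_idx = np.sort(order, axis=-1)
    return (dest_hc[:, None] << MC_BITS) | mc_idx.astype(np.int64)


def modulate_weights(
    counts: np.ndarray,
    weights: np.ndarray,
    mask: TypeMask,
    shift: int = 0,
) -> np.ndarray:
    """Per-destination-type synaptic input codes for one event.

    ``acc[d] = sum_s mask[d, s] * weights[s] * counts[s]``, arithmetic-shifted
    right by ``shift`` and saturated to the Q4 range.  With the default
    ``shift = 0`` a single presynaptic spike of weight code ``w`` contributes
    exactly ``w`` — weight codes and W codes share the 1/8 normalization.
    """
    counts = np.asarray(counts, dtype=np.int32)
    weights = np.asarray(weights, dtype=np.int32)
    acc = mask.mask.astype(np.int32) @ (weights * counts)
    return np.clip(acc >> shift, Q4_MIN, Q4_MAX).astype(np.int8)


class ArbiterOverflowError(RuntimeError):
    """All slots of an arbiter are bound; the hardware would stall here."""


@dataclass
class Arbiter:
    """One of the 16 dynamic-assignment units.

    Maintains the associative address->slot map, per-slot 8x4-bit saturating
    weight accumulators, the round-robin index generator used to pick fresh
    slots, and the consecutive-address bypass register (a fast path the
    hardware uses to skip the CAM search; functionally it only shows up in
    the hit statistics here).
    """

    capacity: int = 1 << 16
    slot_of: dict[int, int] = field(default_factory=dict)
    rr_index: int = 0
    last_addr: int = -1
    bypass_hits: int = 0
    overflow_count: int = 0

    def __post_init__(self) -> None:
        self.bound = np.zeros(self.capacity, dtype=bool)
        self.addr_of = np.full(self.capacity, -1, dtype=np.int64)
        self.W = np.zeros((self.capacity, N_TYPES), dtype=np.int8)

    @property
    def occupancy(self) -> int:
        return len(self.slot_of)

    def _allocate(self, addr: int) -> int:
        """Bind ``addr`` to the next free slot at/after the round-robin index."""
        if self.occupancy >= self.capacity:
            self.overflow_count += 1
            raise ArbiterOverflowError(
                f"arbiter full ({self.capacity} slots); address {addr} dropped"
            )
        while self.bound[self.rr_index]:
            self.rr_index = (self.rr_index + 1) % self.capacity
        slot = self.rr_index
        self.bound[slot] = True
        self.addr_of[slot] = addr
        self.slot_of[addr] = slot
        self.rr_index = (self.rr_index + 1) % self.capacity
        return slot

    def lookup(self, addr: int) -> int | None:
        return self.slot_of.get(addr)

    def process(self, addr: int, W: np.ndarray) -> int:
        """Route one weighted input; returns the slot used.

        A hit accumulates (saturating on commit); a miss binds a fresh slot.
        """
        if addr == self.last_addr and addr in self.slot_of:
            self.bypass_hits += 1
        self.last_addr = addr
        slot = self.slot_of.get(addr)
        if slot is None:
            slot = self._allocate(addr)
        acc = self.W[slot].astype(np.int32) + np.asarray(W, dtype=np.int32)
        self.W[slot] = np.clip(acc, Q4_MIN, Q4_MAX)
        return slot

    def accumulate_batch(self, slots: np.ndarray, W_sums: np.ndarray) -> None:
        """Commit per-slot summed contributions with one saturation.

        ``W_sums`` holds the full-precision within-step sums; saturation is
        applied once per commit (see the package methods note on accumulation
        granularity).
        """
        acc = self.W[slots].astype(np.int32) + W_sums
        self.W[slots] = np.clip(acc, Q4_MIN, Q4_MAX)

    def read_and_clear(self, slot: int) -> np.ndarray:
        """Return the slot's W codes and zero the accumulators (binding kept)."""
        if not self.bound[slot]:
            raise LookupError(f"slot {slot} is not bound")
        out = self.W[slot].copy()
        self.W[slot] = 0
        return out

    def free_slots(self, slots) -> None:
        """Unbind the given slots; they become reusable."""
        for slot in np.atleast_1d(np.asarray(slots, dtype=np.int64)):
            s = int(slot)
            if not self.bound[s]:
                continue
            addr = int(self.addr_of[s])
            self.bound[s] = False
            self.addr_of[s] = -1
            self.W[s] = 0
            del self.slot_of[addr]
            if addr == self.last_addr:
                self.last_addr = -1

    def free_inactive(self, inactive_addresses) -> None:
        """Release the slots of the given quiescent minicolumn addresses."""
        slots = [self.slot_of[a] for a in inactive_addresses if a in self.slot_of]
        if slots:
            self.free_slots(np.asarray(slots))

    def bound_slots(self) -> np.ndarray:
        """Bound slot indices in ascending slot order (the iteration order)."""
        return np.flatnonzero(self.bound)


@dataclass
class SynapseArray:
    """The 16 arbiters plus routing by the top 4 address bits."""

    capacity: int = 1 << 16

    def __post_init__(self) -> None:
        self.arbiters = [Arbiter(self.capacity) for _ in range(N_ARBITERS)]

    def process(self, addr: int, W: np.ndarray) -> tuple[int, int]:
        a = arbiter_index(addr)
        return a, self.arbiters[a].process(addr, W)

    @property
    def occupancy(self) -> int:
        return sum(a.occupancy for a in self.arbiters)
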