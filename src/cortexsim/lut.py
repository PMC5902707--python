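"""Address-range parameter lookup (the behavioral model of the threshold CAM).

All per-minicolumn configuration — neuron parameters, outgoing (post)
connection targets with axonal delays, and incoming (pre) connection rules
with weights and type masks — is resolved hierarchically through a compact
range table rather than stored per column.  The table holds up to 512
sorted 27-bit thresholds ``A_i``; an address belongs to the half-open range
``[A_i, A_{i+1})`` and inherits that range's entries.  This is what lets a
network of 10^8 neurons be described in kilobytes.

Address layout: 27 bits total, hypercolumn = ``addr >> 7`` (20 bits),
minicolumn-within-hypercolumn = ``addr & 127`` (7 bits), both 0-based.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .minicolumn import ADDRESS_BITS, MinicolumnSpec, N_TYPES

__all__ = [
    "MAX_RANGES",
    "MAX_CONN_SIZE",
    "MAX_POST_TARGETS",
    "HC_BITS",
    "MC_BITS",
    "split_address",
    "make_address",
    "TypeMask",
    "PreConnection",
    "PostTarget",
    "PostConnection",
    "RangeEntry",
    "ParameterLut",
]

MAX_RANGES = 512
MAX_CONN_SIZE = 128
MAX_POST_TARGETS = 16
DELAY_MIN, DELAY_MAX = 1, 16
HC_BITS, MC_BITS = 20, 7
ADDRESS_SPACE = 1 << ADDRESS_BITS


def split_address(addr: int) -> tuple[int, int]:
    """27-bit address -> (hypercolumn, minicolumn-index)."""
    return addr >> MC_BITS, addr & (MAX_CONN_SIZE - 1)


def make_address(hc: int, mc: int) -> int:
    if not 0 <= hc < (1 << HC_BITS):
        raise ValueError("hypercolumn index must fit in 20 bits")
    if not 0 <= mc < MAX_CONN_SIZE:
        raise ValueError("minicolumn index must fit in 7 bits")
    return (hc << MC_BITS) | mc


@dataclass(frozen=True)
class TypeMask:
    """8x8 connection mask; ``mask[dest_type, src_type]`` gates one synapse.

    64 bits describe every possible type-to-type connection between a source
    and destination minicolumn pair.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=np.uint8)
        if m.shape != (N_TYPES, N_TYPES) or np.any(m > 1):
            raise ValueError("mask must be an 8x8 0/1 array")
        object.__setattr__(self, "mask", m)

    @classmethod
    def none(cls) -> "TypeMask":
        return cls(np.zeros((N_TYPES, N_TYPES), np.uint8))

    @classmethod
    def from_pairs(cls, pairs) -> "TypeMask":
        """Build from ``(dest_type, src_type)`` index pairs."""
        m = np.zeros((N_TYPES, N_TYPES), np.uint8)
        for d, s in pairs:
            m[d, s] = 1
        return cls(m)


@dataclass(frozen=True)
class PreConnection:
    """Receive-side rule: how one incoming connection lands in a hypercolumn.

    ``conn_size`` destination minicolumns are drawn (deterministically per
    source address) from the ``dest_hc_size`` columns of the destination
    hypercolumn; ``weights`` are per-source-type signed 4-bit codes
    (value = code/8); ``offset`` is the 20-bit hypercolumn offset added to
    the source hypercolumn (0 = recurrent).
    """

    conn_size: int
    offset: int
    weights: np.ndarray
    dest_hc_size: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int8)
        if w.shape != (N_TYPES,) or np.any(w < -8) or np.any(w > 7):
            raise ValueError("weights must be 8 signed 4-bit codes")
        object.__setattr__(self, "weights", w)
        if not 1 <= self.dest_hc_size <= MAX_CONN_SIZE:
            raise ValueError(f"dest_hc_size must be in [1, {MAX_CONN_SIZE}]")
        if not 1 <= self.conn_size <= self.dest_hc_size:
            raise ValueError(
                f"conn_size {self.conn_size} must be in [1, dest_hc_size="
                f"{self.dest_hc_size}]"
            )
        if not 0 <= self.offset < (1 << HC_BITS):
            raise ValueError("offset must fit in 20 bits")


@dataclass(frozen=True)
class PostTarget:
    """One transmit-side fan-out copy: hypercolumn offset + axonal delay."""

    hc_offset: int
    delay_ms: int
    conn_id: int

    def __post_init__(self) -> None:
        if not 0 <= self.hc_offset < (1 << HC_BITS):
            raise ValueError("hc_offset must fit in 20 bits")
        if not DELAY_MIN <= self.delay_ms <= DELAY_MAX:
            raise ValueError(
                f"axonal delay must be in [{DELAY_MIN}, {DELAY_MAX}] ms, "
                f"got {self.delay_ms}"
            )
        if not 0 <= self.conn_id < MAX_POST_TARGETS:
            raise ValueError("conn_id must index one of up to 16 connections")


@dataclass(frozen=True)
class PostConnection:
    """Up to 16 fan-out targets of a source range; empty list = event sink."""

    targets: tuple[PostTarget, ...] = ()

    def __post_init__(self) -> None:
        if len(self.targets) > MAX_POST_TARGETS:
            raise ValueError(
                f"at most {MAX_POST_TARGETS} post-connection targets allowed"
            )
        ids = [t.conn_id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError("conn_ids within one post connection must be unique")


@dataclass
class RangeEntry:
    """Everything one address range resolves to."""

    spec: MinicolumnSpec
    post: PostConnection = field(default_factory=PostConnection)
    # conn_id -> (PreConnection, TypeMask), keyed by the *source* address:
    # the receive side looks up the rule with the incoming event's address,
    # so keys must cover every conn_id this range's own post connection uses.
    pre: dict[int, tuple[PreConnection, TypeMask]] = field(default_factory=dict)


class NoRangeError(LookupError):
    """Address below the first threshold: no configured range."""


class ParameterLut:
    """The network description: sorted thresholds plus per-range entries."""

    def __init__(self) -> None:
        self.thresholds: list[int] = []
        self.entries: list[RangeEntry] = []

    def add_range(self, threshold: int, entry: RangeEntry) -> int:
        """Append a range starting at ``threshold``; thresholds must arrive
        strictly increasing.  Returns the new range index."""
        if not 0 <= threshold < ADDRESS_SPACE:
            raise ValueError("threshold must be a 27-bit address")
        if self.thresholds and threshold <= self.thresholds[-1]:
            raise ValueError(
                f"thresholds must be strictly increasing "
                f"({threshold} after {self.thresholds[-1]})"
            )
        if len(self.thresholds) >= MAX_RANGES:
            raise ValueError(f"range table limited to {MAX_RANGES} thresholds")
        self.thresholds.append(threshold)
        self.entries.append(entry)
        return len(self.entries) - 1

    def __len__(self) -> int:
        return len(self.entries)

    def lookup_range(self, addr: int) -> int:
        """Largest ``i`` with ``A_i <= addr`` (half-open range convention)."""
        if not 0 <= addr < ADDRESS_SPACE:
            raise ValueError("address must fit in 27 bits")
        if not self.thresholds:
            raise NoRangeError("empty range table")
        i = bisect_right(self.thresholds, addr) - 1
        if i < 0:
            raise NoRangeError(f"address {addr} below first threshold")
        return i

    def lookup_range_array(self, addrs: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`lookup_range` (no below-range addresses allowed)."""
        th = np.asarray(self.thresholds, dtype=np.int64)
        idx = np.searchsorted(th, addrs, side="right") - 1
        if np.any(idx < 0):
            raise NoRangeError("address below first threshold")
        return idx

    def get_neuron_params(self, addr: int) -> MinicolumnSpec:
        return self.entries[self.lookup_range(addr)].spec

    def get_post_connection(self, addr: int) -> PostConnection:
        return self.entries[self.lookup_range(addr)].post

    def get_pre_connection(self, addr: int, conn_id: int) -> tuple[PreConnection, TypeMask]:
        entry = self.entries[self.lookup_range(addr)]
        try:
            return entry.pre[conn_id]
        except KeyError:
            raise LookupError(
                f"address {addr} has no pre-connection for conn_id {conn_id}"
            ) from None
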