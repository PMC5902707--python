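"""The 100-neuron physical minicolumn and its spike-count events.

A minicolumn hosts up to eight neuron types in contiguous lane blocks of
four (the hardware multiplexes parameters at a granularity of 100/4 = 25
blocks).  All neurons of one type receive the same accumulated synaptic
input ``W`` for the step.  The per-type spike totals of a step are clipped
to 4 bits and form the minicolumn's outgoing event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neuron import NeuronState, NeuronTypeParams, neuron_step

__all__ = [
    "N_LANES",
    "N_TYPES",
    "LANE_BLOCK",
    "COUNT_MAX",
    "MinicolumnSpec",
    "SpikeCountEvent",
    "assign_type_lanes",
    "minicolumn_step",
]

N_LANES = 100
N_TYPES = 8
LANE_BLOCK = 4
COUNT_MAX = 15  # 4-bit saturating spike counts
ADDRESS_BITS = 27


@dataclass(frozen=True)
class MinicolumnSpec:
    """Neuron-type composition and parameters of one minicolumn class.

    ``type_counts`` holds eight nonnegative multiples of four summing to 100;
    ``params`` gives one parameter set per type (entries for empty types may
    be shared placeholders).
    """

    type_counts: tuple[int, ...]
    params: tuple[NeuronTypeParams, ...]

    def __post_init__(self) -> None:
        if len(self.type_counts) != N_TYPES or len(self.params) != N_TYPES:
            raise ValueError("exactly 8 type counts and 8 parameter sets required")
        if any(c < 0 or c % LANE_BLOCK for c in self.type_counts):
            raise ValueError(
                f"type counts must be nonnegative multiples of {LANE_BLOCK}: "
                f"{self.type_counts}"
            )
        if sum(self.type_counts) != N_LANES:
            raise ValueError(
                f"type counts must sum to {N_LANES}, got {sum(self.type_counts)}"
            )

    def lane_types(self) -> np.ndarray:
        return assign_type_lanes(self)

    def type_offsets(self) -> np.ndarray:
        """Start lane of each type block (for segmented reductions)."""
        return np.concatenate(([0], np.cumsum(self.type_counts)[:-1])).astype(np.int64)


@dataclass
class SpikeCountEvent:
    """The unit of inter-column communication: source address + 8 counts."""

    address: int
    counts: np.ndarray = field(default_factory=lambda: np.zeros(N_TYPES, np.uint8))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.uint8)
        if self.counts.shape != (N_TYPES,):
            raise ValueError("counts must be 8 values")
        if np.any(self.counts > COUNT_MAX):
            raise ValueError("spike counts are 4-bit (<= 15)")
        if not 0 <= self.address < (1 << ADDRESS_BITS):
            raise ValueError("address must fit in 27 bits")


def assign_type_lanes(spec: MinicolumnSpec) -> np.ndarray:
    """Lane -> type table: contiguous blocks in type-index order."""
    return np.repeat(np.arange(N_TYPES), spec.type_counts).astype(np.int8)


def minicolumn_step(
    states: list[NeuronState],
    W: np.ndarray,
    spec: MinicolumnSpec,
    dithers: np.ndarray,
) -> tuple[list[NeuronState], np.ndarray]:
    """Reference per-lane update of one minicolumn for one 1 ms step.

    Parameters
    ----------
    states:
        100 neuron states.
    W:
        8 per-type accumulated synaptic inputs (Q4 codes).
    dithers:
        ``(100, 2)`` array of 5-bit dithers (PSC stage, soma stage).

    Returns the new states and the 8 saturated per-type spike counts.  This
    loopy implementation is the semantic oracle; the engine's vectorized
    kernel must agree with it lane for lane.
    """
    if len(states) != N_LANES:
        raise ValueError("a minicolumn has exactly 100 neurons")
    lane_types = assign_type_lanes(spec)
    counts = np.zeros(N_TYPES, dtype=np.int64)
    out: list[NeuronState] = []
    for lane in range(N_LANES):
        t = int(lane_types[lane])
        new_state, spiked = neuron_step(
            states[lane],
            int(W[t]),
            spec.params[t],
            int(dithers[lane, 0]),
            int(dithers[lane, 1]),
        )
        out.append(new_state)
        counts[t] += spiked
    return out, np.minimum(counts, COUNT_MAX).astype(np.uint8)
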