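"""The simplified auditory-cortex experiment: network builder, tonotopic
Poisson sweep stimulus, and the analysis reductions.

The model is a tonotopic array of ``n_channels`` independent channels.  Each
channel owns ``hc_per_channel`` hypercolumns of ``mc_per_hc`` minicolumns of
100 neurons (at the published scale: 100 channels x 100 x 100 x 100 = 10^8
neurons).  Every minicolumn hosts three cortical-layer groups, each split
into an excitatory and an inhibitory type (4:1 ratio overall):

====  ======  =====
type  group   count
====  ======  =====
0     L2/3 e  32
1     L2/3 i  8
2     L4   e  16
3     L4   i  4
4     L5/6 e  32
5     L5/6 i  8
====  ======  =====

Each minicolumn projects to 24 others — 8 random minicolumns in its own
hypercolumn and 8 each in the two tonotopic neighbours (boundary
hypercolumns drop the missing neighbour; channels are never connected).
Excitatory weights are +0.4 (code 3) and inhibitory −1.0 (code −8), a
balanced-network setting.

The stimulus emulates a cochlear pure-tone sweep: 10 Poisson neurons per
channel, each wired to 8 random minicolumns of one of 10 random
hypercolumns of that channel, firing at ~10 Hz during the channel's 10 ms
window of each sweep; spikes drive only the excitatory L4 type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import CompiledNetwork, SimRecorders, Simulator
from .fixedpoint import splitmix64
from .lut import (
    HC_BITS,
    ParameterLut,
    PostConnection,
    PostTarget,
    PreConnection,
    RangeEntry,
    TypeMask,
    make_address,
)
from .minicolumn import MinicolumnSpec, N_LANES, N_TYPES
from .neuron import NeuronTypeParams

__all__ = [
    "AuditoryConfig",
    "StimulusEvent",
    "default_intra_mask",
    "default_inter_mask",
    "build_auditory_network",
    "NetworkReport",
    "poisson_sweep_stimulus",
    "compile_stimulus",
    "estimate_poisson_rate",
    "channel_rate_map",
    "active_fraction_trace",
    "run_auditory_demo",
    "write_events",
    "read_events",
]

# type indices
L23E, L23I, L4E, L4I, L56E, L56I = range(6)
EXC_TYPES = (L23E, L4E, L56E)
INH_TYPES = (L23I, L4I, L56I)


def default_intra_mask() -> TypeMask:
    """Within-hypercolumn group motif (mask[dest, src]).

    The canonical cortical relay — L4e drives L2/3, L2/3e drives L5/6, L5/6e
    feeds back to L2/3 — plus inhibition arranged so the network has a
    balanced operating point: interneurons are driven by excitation only
    (inhibition stays recruited at high activity), pyramidal targets receive
    enough inhibitory weight that a saturated event's masked sum is negative
    (activity self-limits) while a low-rate event's expected sum is positive
    (activity self-sustains).  With the published weights (+0.4/−1.0) and
    type counts this makes each channel hover in a noise-driven
    asynchronous-irregular regime instead of locking up or dying instantly.
    """
    return TypeMask.from_pairs(
        [
            # excitatory relay onto L2/3, with L2/3i + L4i inhibition
            (L23E, L4E), (L23E, L56E), (L23E, L23I), (L23E, L4I),
            # interneuron drive (excitatory sources only)
            (L23I, L4E), (L23I, L56E),
            # L2/3e -> L5/6, gated by L5/6i
            (L56E, L23E), (L56E, L56I),
            (L56I, L23E),
            # L4 relay: stimulus-driven, locally gated
            (L4E, L4I),
            (L4I, L4E),
        ]
    )


def default_inter_mask() -> TypeMask:
    """Between-hypercolumn (tonotopic neighbour) motif: excitatory types
    recruit the neighbouring hypercolumn's same-group interneurons — lateral
    (surround) inhibition that keeps activity spatially confined."""
    return TypeMask.from_pairs(
        [
            (L23I, L23E),
            (L4I, L4E),
            (L56I, L56E),
        ]
    )


def _weight_code(w: float) -> int:
    code = int(round(w * 8.0))
    if not -8 <= code <= 7:
        raise ValueError(f"weight {w} outside representable [-1, 0.875]")
    return code


@dataclass(frozen=True)
class AuditoryConfig:
    """All knobs of the experiment, defaulting to the published conditions."""

    n_channels: int = 100
    hc_per_channel: int = 100
    mc_per_hc: int = 100
    type_counts: tuple[int, ...] = (32, 8, 16, 4, 32, 8, 0, 0)
    tau_epsc: float = 5.8
    tau_ipsc: float = 5.8
    tau_mem: float = 5.8
    tau_rfc: float = 3.0
    g_syn: float = 1.0
    g_psc: float = 1.0
    w_exc: float = 0.4
    w_inh: float = -1.0
    conn_size: int = 8
    delay_ms: int = 1
    poisson_per_channel: int = 10
    poisson_rate_hz: float = 10.0
    poisson_targets: int = 8
    stim_hypercolumns: int = 10
    sweep_window_ms: int = 10
    n_sweeps: int = 10

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.hc_per_channel < 1:
            raise ValueError("need at least one channel and one hypercolumn")
        if not 1 <= self.mc_per_hc <= 128:
            raise ValueError("mc_per_hc must be in [1, 128]")
        if self.stim_hypercolumns > self.hc_per_channel:
            # scaled-down configs: stimulate every hypercolumn that exists
            object.__setattr__(self, "stim_hypercolumns", self.hc_per_channel)
        if self.conn_size > self.mc_per_hc or self.poisson_targets > self.mc_per_hc:
            raise ValueError("connection size exceeds destination hypercolumn size")

    # -- structural bookkeeping ------------------------------------------

    @property
    def n_hypercolumns(self) -> int:
        return self.n_channels * self.hc_per_channel

    @property
    def n_minicolumns(self) -> int:
        return self.n_hypercolumns * self.mc_per_hc

    @property
    def n_neurons(self) -> int:
        return self.n_minicolumns * N_LANES

    @property
    def sweep_period_ms(self) -> int:
        return self.n_channels * self.sweep_window_ms

    @property
    def duration_ms(self) -> int:
        return self.sweep_period_ms * self.n_sweeps

    def hc_index(self, channel: int, h: int) -> int:
        return channel * self.hc_per_channel + h

    def address(self, channel: int, h: int, mc: int) -> int:
        return make_address(self.hc_index(channel, h), mc)

    def channel_of_address(self, addr: int) -> int:
        return (addr >> 7) // self.hc_per_channel

    def params(self) -> NeuronTypeParams:
        return NeuronTypeParams.from_time_constants(
            self.tau_epsc, self.tau_ipsc, self.tau_mem, self.tau_rfc,
            self.g_syn, self.g_psc,
        )

    def minicolumn_spec(self) -> MinicolumnSpec:
        p = self.params()
        return MinicolumnSpec(tuple(self.type_counts), (p,) * N_TYPES)

    def source_weights(self) -> np.ndarray:
        """Per-source-type weight codes: w_exc for e-types, w_inh for i-types."""
        w = np.zeros(N_TYPES, np.int8)
        for t in EXC_TYPES:
            w[t] = _weight_code(self.w_exc)
        for t in INH_TYPES:
            w[t] = _weight_code(self.w_inh)
        return w


@dataclass(frozen=True)
class NetworkReport:
    """Structural totals the builder reports."""

    n_neurons: int
    n_minicolumns: int
    n_hypercolumns: int
    n_ranges: int
    out_degree_interior: int


def build_auditory_network(cfg: AuditoryConfig) -> tuple[ParameterLut, NetworkReport]:
    """Construct the range table for the tonotopic network.

    Each channel contributes up to three address ranges (first hypercolumn,
    interior, last) differing only in which tonotopic neighbours exist; all
    share one minicolumn spec.  conn_id 0 is the recurrent (offset 0)
    connection, 1 the +1 neighbour, 2 the −1 neighbour (20-bit wrap-around
    encoding for the negative offset).
    """
    spec = cfg.minicolumn_spec()
    weights = cfg.source_weights()
    intra, inter = default_intra_mask(), default_inter_mask()
    wrap_minus1 = (1 << HC_BITS) - 1

    def pre(offset: int, mask: TypeMask) -> tuple[PreConnection, TypeMask]:
        return (
            PreConnection(
                conn_size=cfg.conn_size,
                offset=offset,
                weights=weights,
                dest_hc_size=cfg.mc_per_hc,
            ),
            mask,
        )

    conn_defs = {
        0: pre(0, intra),
        1: pre(1, inter),
        2: pre(wrap_minus1, inter),
    }

    lut = ParameterLut()
    HC = cfg.hc_per_channel
    for c in range(cfg.n_channels):
        # hypercolumn spans within the channel sharing the same neighbour set
        if HC == 1:
            spans = [(0, 1, (0,))]
        elif HC == 2:
            spans = [(0, 1, (0, 1)), (1, 2, (0, 2))]
        else:
            spans = [
                (0, 1, (0, 1)),
                (1, HC - 1, (0, 1, 2)),
                (HC - 1, HC, (0, 2)),
            ]
        for h_lo, h_hi, conn_ids in spans:
            entry = RangeEntry(
                spec=spec,
                post=PostConnection(
                    tuple(
                        PostTarget(
                            hc_offset=conn_defs[cid][0].offset,
                            delay_ms=cfg.delay_ms,
                            conn_id=cid,
                        )
                        for cid in conn_ids
                    )
                ),
                pre={cid: conn_defs[cid] for cid in conn_ids},
            )
            lut.add_range(make_address(cfg.hc_index(c, h_lo), 0), entry)

    report = NetworkReport(
        n_neurons=cfg.n_neurons,
        n_minicolumns=cfg.n_minicolumns,
        n_hypercolumns=cfg.n_hypercolumns,
        n_ranges=len(lut),
        out_degree_interior=3 * cfg.conn_size,
    )
    return lut, report


# -- stimulus ----------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEvent:
    """One Poisson-neuron spike and the minicolumns it lands on."""

    t_ms: int
    channel: int
    neuron_id: int
    targets: tuple[int, ...]  # 8 minicolumn addresses inside the channel


def _derived_seed(seed: int, tag: int) -> int:
    return splitmix64(splitmix64(seed) ^ tag) % (1 << 31)


def poisson_sweep_stimulus(cfg: AuditoryConfig, seed: int) -> list[StimulusEvent]:
    """Generate the full sweep stimulus spike stream.

    Channel ``c``'s 10 Poisson neurons fire as ~10 Hz processes (independent
    1 ms Bernoulli bins) during the window
    ``[(s * n_channels + c) * 10 ms, +10 ms)`` of every sweep ``s``.  Each
    neuron's targets — one of 10 random hypercolumns of the channel, 8 random
    minicolumns inside it — are fixed for the whole run.
    """
    wiring_rng = np.random.default_rng(_derived_seed(seed, 0x57121))
    spike_rng = np.random.default_rng(_derived_seed(seed, 0x57122))
    p = cfg.poisson_rate_hz / 1000.0  # per-ms spike probability
    W = cfg.sweep_window_ms

    targets: list[list[tuple[int, ...]]] = []
    for c in range(cfg.n_channels):
        hcs = wiring_rng.choice(
            cfg.hc_per_channel, size=cfg.stim_hypercolumns, replace=False
        )
        per_neuron = []
        for j in range(cfg.poisson_per_channel):
            h = int(hcs[j % cfg.stim_hypercolumns])
            mcs = wiring_rng.choice(cfg.mc_per_hc, size=cfg.poisson_targets, replace=False)
            per_neuron.append(tuple(cfg.address(c, h, int(m)) for m in sorted(mcs)))
        targets.append(per_neuron)

    events: list[StimulusEvent] = []
    for s in range(cfg.n_sweeps):
        for c in range(cfg.n_channels):
            t0 = (s * cfg.n_channels + c) * W
            fires = spike_rng.random((cfg.poisson_per_channel, W)) < p
            for j, dt in zip(*np.nonzero(fires)):
                events.append(
                    StimulusEvent(
                        t_ms=t0 + int(dt),
                        channel=c,
                        neuron_id=int(j),
                        targets=targets[c][int(j)],
                    )
                )
    events.sort(key=lambda e: e.t_ms)
    return events


def compile_stimulus(
    events: list[StimulusEvent], cfg: AuditoryConfig
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Convert stimulus spikes to per-step pre-weighted deliveries.

    Each spike contributes the excitatory weight code to the L4e accumulator
    of each of its 8 target minicolumns ("only sent to the excitatory
    neurons of the L4 group").
    """
    w = _weight_code(cfg.w_exc)
    by_t: dict[int, list[int]] = {}
    for ev in events:
        by_t.setdefault(ev.t_ms, []).extend(ev.targets)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for t, addrs in by_t.items():
        a = np.asarray(addrs, np.int64)
        Wd = np.zeros((len(a), N_TYPES), np.int32)
        Wd[:, L4E] = w
        out[t] = (a, Wd)
    return out


def estimate_poisson_rate(events: list[StimulusEvent], cfg: AuditoryConfig) -> float:
    """Mean within-window firing rate (Hz) across all neuron-windows."""
    n_neurons = cfg.n_channels * cfg.poisson_per_channel
    active_s = cfg.n_sweeps * cfg.sweep_window_ms / 1000.0  # per neuron
    return len(events) / (n_neurons * active_s)


# -- analysis ----------------------------------------------------------------

def channel_rate_map(
    ts: np.ndarray,
    addrs: np.ndarray,
    counts: np.ndarray,
    cfg: AuditoryConfig,
    bin_ms: int = 10,
    duration_ms: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel population firing-rate maps from event records.

    Returns ``(exc, inh)`` matrices of shape (channels, bins) in Hz per
    neuron: per-channel spike counts of the excitatory / inhibitory types,
    divided by the type population of the channel and the bin width.
    """
    if duration_ms is None:
        duration_ms = cfg.duration_ms
    nbins = max(1, int(np.ceil(duration_ms / bin_ms)))
    exc = np.zeros((cfg.n_channels, nbins))
    inh = np.zeros((cfg.n_channels, nbins))
    if len(ts):
        ch = (np.asarray(addrs) >> 7) // cfg.hc_per_channel
        b = np.minimum(np.asarray(ts) // bin_ms, nbins - 1)
        counts = np.asarray(counts)
        np.add.at(exc, (ch, b), counts[:, list(EXC_TYPES)].sum(axis=1))
        np.add.at(inh, (ch, b), counts[:, list(INH_TYPES)].sum(axis=1))
    tc = np.asarray(cfg.type_counts)
    pop = cfg.hc_per_channel * cfg.mc_per_hc
    exc_pop = tc[list(EXC_TYPES)].sum() * pop
    inh_pop = tc[list(INH_TYPES)].sum() * pop
    bin_s = bin_ms / 1000.0
    return exc / (exc_pop * bin_s), inh / (inh_pop * bin_s)


def active_fraction_trace(
    occ_t: np.ndarray,
    occ_counts: np.ndarray,
    cfg: AuditoryConfig,
    warmup_ms: int | None = None,
) -> tuple[np.ndarray, float]:
    """Active-minicolumn percentage trace and its steady-state mean.

    Percentage of all dynamically-assigned minicolumn addresses bound at each
    step; the mean excludes a warm-up (default: the first sweep period).
    """
    if warmup_ms is None:
        warmup_ms = cfg.sweep_period_ms
    pct = 100.0 * np.asarray(occ_counts, float) / cfg.n_minicolumns
    steady = pct[np.asarray(occ_t) >= warmup_ms]
    return pct, float(steady.mean()) if len(steady) else float("nan")


def run_auditory_demo(
    cfg: AuditoryConfig,
    seed: int,
    duration_ms: int | None = None,
    mode: str = "exact",
    record_spikes: bool = False,
) -> tuple[Simulator, SimRecorders]:
    """Build the network, generate the sweep stimulus, and run it."""
    lut, _ = build_auditory_network(cfg)
    stim = compile_stimulus(poisson_sweep_stimulus(cfg, seed), cfg)
    sim = Simulator(CompiledNetwork(lut), seed=seed, mode=mode, record_spikes=record_spikes)
    rec = sim.run(cfg.duration_ms if duration_ms is None else duration_ms, stimulus=stim)
    return sim, rec


def steady_state_active_percentage(
    cfg: AuditoryConfig, seeds, warmup_ms: int | None = None
) -> tuple[float, list[float]]:
    """Mean steady-state active-minicolumn percentage over independent seeds.

    Runs the demo once per seed, records the bound-slot count every ms,
    discards the warm-up (default: the first sweep period), and averages the
    active percentage across time and seeds.  Returns (mean, per-seed list).
    """
    vals = []
    for seed in seeds:
        _, rec = run_auditory_demo(cfg, seed=int(seed))
        occ_t, occ_n = rec.occupancy_trace()
        _, steady = active_fraction_trace(occ_t, occ_n, cfg, warmup_ms=warmup_ms)
        vals.append(steady)
    return float(np.mean(vals)), vals


# -- columnar text event I/O ---------------------------------------------------

_EVENTS_HEADER = "t_ms\taddress\t" + "\t".join(f"c{i}" for i in range(N_TYPES))


def write_events(path, ts, addrs, counts) -> None:
    """Write event records as tab-separated text with a named-column header."""
    ts = np.asarray(ts)
    addrs = np.asarray(addrs)
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(_EVENTS_HEADER + "\n")
        for i in range(len(ts)):
            row = "\t".join(str(int(c)) for c in counts[i])
            fh.write(f"{int(ts[i])}\t{int(addrs[i])}\t{row}\n")


def read_events(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read records written by :func:`write_events`; malformed rows raise
    with their line number."""
    ts, addrs, counts = [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _EVENTS_HEADER:
            raise ValueError(f"{path}:1: unrecognized event-file header")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 + N_TYPES:
                raise ValueError(f"{path}:{ln}: expected {2 + N_TYPES} columns")
            try:
                vals = [int(p) for p in parts]
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer field") from None
            ts.append(vals[0])
            addrs.append(vals[1])
            counts.append(vals[2:])
    return (
        np.asarray(ts, np.int64),
        np.asarray(addrs, np.int64),
        np.asarray(counts, np.int64).reshape(len(ts), N_TYPES),
    )
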