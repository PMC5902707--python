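# Methods

This note documents the model cortexsim implements, the numerical
conventions it fixes where the architecture leaves them open, what the
built-in synthetic experiment does and does not emulate, and the known
limitations. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Fixed-point arithmetic and randomness

All neuron state is fixed point: signed 4-bit codes (`Q4`, value = code/8,
range [−1, 0.875]) for the post-synaptic current (PSC) and the membrane
offset, 8-bit leak factors `L` (per-step retention `L/256 ≈ τ/(τ+1)`), and
8-bit gain codes (gain = (code+1)/16, covering [0.0625, 16] so both
endpoints of the nominal [0.06, 16] range are representable).

**Stochastic decay.** One decay step computes `q = floor(|x|·L/8)` (the
product truncated to 1/32 units) and returns
`sign(x) · floor((q + r)/32)` with a 5-bit dither `r`. Averaged over the 32
dithers this equals `q/32` exactly; the only systematic error is the 3-bit
product truncation, which biases the retention downward by at most 7/8 of
1/32 per step and grows in relative terms as codes approach the
quantization floor (the test suite pins the ensemble mean to the exact
16-state Markov chain of the update, and to the continuous exponential
within 1.5 % in the high-code regime). The dither resolution caps the
slowest *cleanly representable* retention at 31/32 (`L = 248`), i.e. an
effective time constant of `−1/ln(31/32) ≈ 31.5` steps — the design's
"about 30 ms" ceiling, which the acceptance script measures by exponential
fit. Leak factors above 248 produce code-dependent quantized retentions and
are not used by the default parameter mapping.

**Dither interpretation.** The additive random term in the update equations
is implemented as stochastic-rounding dither of the truncated product, not
as additive noise on the state: additive uniform noise in (0,1) would not
converge and contradicts the stated purpose of generating discarded low
bits on the fly.

**Random streams.** All randomness in the simulation core comes from
Fibonacci LFSRs (left shift, feedback into the LSB; after `n` steps the low
`n` state bits are the last `n` output bits). Default primitive
polynomials: width 4 `x⁴+x³+1`, 8 `x⁸+x⁶+x⁵+x⁴+1`, 10 `x¹⁰+x⁷+1`, 20
`x²⁰+x³+1`, 32 `x³²+x²²+x²+x+1`. The stochastic delay readout uses a
10-bit gate stream and a 20-bit selection stream. Neuron dithers use one
20-bit stream per (minicolumn address, lane, pipeline stage), seeded by a
splitmix64 hash of (global seed, address, lane, stage). Seeding per
*address* rather than per physical lane is a deliberate design choice: a
minicolumn's trajectory is then a pure function of the configuration and
the seed, independent of slot-binding history and of how many other columns
are active, which is what makes bit-identical reruns and
iteration-order-independent trajectories possible. The hardware-oriented
alternative (one free-running generator per physical lane, shared across
time-multiplexed columns in processing order) produces statistically
equivalent dithers but binds the noise to the scheduling history. The
generator-measurement helpers (Poisson stimulus, decay-constant fits) use
numpy PCG64 generators seeded from the same global seed.

## 2. Neuron model

The PSC generator selects the excitatory or inhibitory leak by the current
sign of the PSC and adds the gained drive `round(g_syn · W)` (round to
nearest, ties away from zero — the rounding of the gain product is not
specified by the architecture and is fixed here), saturating into Q4. A
single accumulator can carry mixed excitatory/inhibitory drive.

The membrane is stored as a signed offset `u` from the configurable initial
voltage; `u ≥ 0` is the active state (the rest state integrates), `u < 0`
the refractory state. In the active state the soma decays `u` and adds
`round(g_psc · PSC(t+1))`. If the un-clamped sum exceeds +7 while the PSC
is excitatory the neuron spikes and `u` resets to `u_reset = −8`; a sum
below −8 (strong inhibition) resets likewise but without a spike. A sum in
[−8, −1] is stored as-is, i.e. strong-but-not-underflowing inhibition can
push the neuron into the refractory branch; it decays back to rest either
way. In the refractory state the PSC is discarded by the soma (the PSC
generator keeps running) and |u| decays with τ_rfc — the refractory period
is therefore stochastic with mean set by `L_rfc`, not a hard interval; no
spike can occur while `u < 0`.

Default parameters (the built-in experiment): τ_EPSC = τ_IPSC = τ_mem =
5.8 ms (L = 218), τ_rfc = 3 ms (L = 192), g_syn = g_psc = 1.

## 3. Minicolumns, events, and the parameter LUT

A minicolumn has 100 neurons in up to 8 types, assigned to contiguous lane
blocks at granularity 4 in type-index order (the ordering is fixed for
reproducibility; the hardware multiplexer fixes only the granularity).
Per-type spike totals are clipped to 4 bits (saturation, not wrap-around:
wrapping would alias high activity into low counts) and form the outgoing
event.

Configuration is resolved through a range table of up to 512 strictly
increasing 27-bit thresholds with half-open ranges `[A_i, A_{i+1})` (the
boundary convention is fixed here; an address below the first threshold is
an error). Addresses split as hypercolumn = `addr >> 7` (20 bits),
minicolumn = `addr & 127`. Each range carries: the minicolumn spec; a post
connection (≤ 16 targets of {hypercolumn offset, delay 1–16 ms, conn_id});
and per-conn_id pre rules ({subset size ≤ 128 ≤ destination hypercolumn
size, offset, 8 per-source-type Q4 weights, 8×8 type mask}). Delayed event
copies carry their `conn_id` so the receive side can retrieve the matching
pre rule — the stored payload is not specified by the architecture and
this is the minimal sufficient tag.

## 4. Axonal delays

Transmit: one copy per post target, appended to the FIFO queue of its delay
(odd delays bank A, even bank B, mirroring the alternating single-port
memory access; in software the banking is bookkeeping only). Receive has
two modes:

* **exact** (default): a copy enqueued at `t` with delay `d` is released at
  `t + d`, FIFO within queues. This is the functional semantics at the
  1 ms resolution that the built-in experiment needs.
* **stochastic** (faithful): per access slot, a 10-bit draw gates the slot
  (enabled iff `f ≤ draw`, probability `(1024 − f)/1024`, so `f = 0` always
  enables and `f = 1023` enables 1/1024 of the time), then a 20-bit draw
  selects a queue through cumulative thresholds `T_i` built from
  `R_i = round(P_i · 2²⁰)` with `P_i = P_1/i`, `ΣP_i = 1` (so
  `P_1 = 1/H₁₆`). An empty selected queue wastes the slot. The number of
  access slots per 1 ms step is a configurable budget (default 200),
  standing for the hardware's inter-burst access window; drain-time ratios
  between queues converge to 1:2:…:16 in steady state, which is the
  mechanism's design target and is verified by simulation.

Conservation (enqueued = released + pending, per queue) holds in both modes
and is asserted in the tests.

## 5. Synapse array and dynamic assignment

For each released copy the destination hypercolumn is
`(source_hc + offset) mod 2²⁰` (offset 0 = recurrent), and `conn_size`
distinct destination minicolumns are selected from the destination
hypercolumn by ranking keyed hashes of (source address, conn_id, global
seed, candidate index) — a deterministic function, so a source always
projects to the same destination set, with uniform marginals
`conn_size/dest_hc_size` across candidates.

Weight modulation computes, per destination type,
`Σ_src mask[dest,src] · weight[src] · count[src]`, arithmetic-shifted by a
configurable `shift` and saturated to Q4. The default `shift = 0` is the
dimensionally consistent choice: weight codes and W codes share the 1/8
normalization, so one presynaptic spike with weight code `w` contributes
exactly `w` — with any positive shift a single spike of |weight| < 0.5
would contribute nothing and a 10 Hz afferent could never drive the
network. The hardware's scaling of this sum is not published; the shift
makes the choice explicit.

Sixteen arbiters, selected by the top 4 address bits, perform dynamic
assignment: a bound address accumulates into its slot's per-type 4-bit
accumulators; an unbound address takes the next free slot from a
round-robin index counter. Contributions within one delivery batch (one
1 ms step) are summed at full precision and saturated once on commit — the
hardware's saturation granularity is unstated; per-batch commit is
order-independent and is also what the brute-force oracle in the tests
implements. The consecutive-address bypass of the hardware CAM is modeled
as a statistics counter only (it cannot change functional results). Slot
release happens at the end of each step for every column that is fully
quiescent: all PSC codes zero, all membrane offsets zero, and no pending
accumulated W. This matches the architecture's definition of an *active*
minicolumn (a neuron integrating or firing, or nonzero PSC); the precise
hardware reassignment instant is unpublished, and end-of-step release is
the conservative choice that makes `active_minicolumn_count` equal the
number of bound slots.

Arbiter capacity overflow either raises (strict mode, modeling the master
stalling the pipeline) or drops-with-count (default, reported in the run
statistics; the scaled experiments never overflow).

## 6. The master loop

Each 1 ms step runs compute → expand → deliver → release → record, with
inputs delivered in step `t` integrated in step `t + 1` (the accumulated W
is read and cleared at the start of the next compute phase). The hardware
overlaps these phases with pipelines and flow control, which cannot change
functional results at 1 ms granularity; the fixed ordering is the semantic
contract. Flow-control pauses (FIFO watermarks) are not functional events
in software and appear nowhere as event loss. Slot iteration is by slot
index and all groupings are in sorted order, so a (configuration, seed)
pair yields a bit-identical trajectory.

The timing model is cycle accounting only:
`period = ceil(n_slots/1024) · (1024 + slot_cycles) · clock_period`, with a
5 ns clock and up to 200 access cycles between the 1024-slot segment
bursts. Real-time capacity inverts this at a 1 ms budget. These formulas
reproduce the published operating points (176 k slots ≈ 1.08 ms ≈ real
time; 200 k slots at 200 MHz with no access windows) and make no wall-clock
claim about the Python process itself.

## 7. The auditory-cortex experiment

The built-in experiment is a tonotopic array of `n_channels` mutually
unconnected channels; each channel has 100 hypercolumns × 100 minicolumns
× 100 neurons (10⁸ neurons at the published 100-channel scale). Types per
minicolumn: L2/3 = 32e + 8i, L4 = 16e + 4i, L5/6 = 32e + 8i (4:1
excitatory:inhibitory). Weights: +0.4 (code 3, the nearest representable
0.375) excitatory, −1.0 (code −8) inhibitory. Each minicolumn projects to
24 others: 8 random in its own hypercolumn and 8 in each tonotopic
neighbour; boundary hypercolumns drop (not wrap) the missing neighbour —
the tonotopic axis is not circular. All connections use the minimum 1 ms
axonal delay (the experiment's delay value is unpublished).

**Connection motif.** The original architecture does not fully specify its
group-level connection motif, so the motif ships as an explicit, editable
8×8 mask table. The defaults keep the canonical skeleton — stimulus→L4e, L4e→L2/3,
L2/3e→L5/6, L5/6e→L2/3 within a hypercolumn; excitatory types project
between hypercolumns; inhibitory types stay within their hypercolumn — and
fix the remaining freedom (which e/i types each projection contacts) by a
balance argument on the event arithmetic. Because each event's masked sum
is saturated to 4 bits per destination type, stability is governed by the
sign of that sum at the extremes: the defaults make every pyramidal
target's per-event sum negative at count saturation (activity self-limits:
e.g. L2/3e receives 3·15 + 3·15 from L4e/L5/6e against −8·8 − 8·4 from
L2/3i/L4i) and positive at low rates (activity self-sustains), while
interneurons receive excitation only (inhibition stays recruited at high
activity) and between-hypercolumn projections contact interneurons
(surround inhibition confines activity spatially). Motifs violating these
sign conditions were observed to either saturate the whole network or die
immediately; the chosen defaults put each channel in the noise-driven
asynchronous-irregular regime with sparse population activity that the
architecture is designed to exploit.

**Stimulus.** A pure-tone sweep is emulated directly as its spike schedule
(no audio or cochlear filter bank is modeled): channel `c`'s 10 Poisson
neurons fire at 10 Hz (independent 1 ms Bernoulli bins, rate 0.01/ms)
during the window `[(s·n_channels + c)·10 ms, +10 ms)` of each sweep `s`,
and are silent otherwise; the nominal 10 Hz is the within-window rate. Each
Poisson neuron permanently targets 8 random minicolumns of one of 10
random hypercolumns of its channel, and its spikes deliver the excitatory
weight to the L4e accumulator only, entering the delivery phase of their
time step like external events (target columns bind a slot that step and
integrate the next).

**Observables.** `channel_rate_map` bins per-channel event counts split by
excitatory/inhibitory types, normalized by population and bin width (note
the 4-bit count saturation makes these slight undercounts at very high
synchrony). `active_fraction_trace` reports the percentage of all
minicolumn addresses bound to a slot each ms; its steady-state mean
excludes a warm-up of one sweep period by default.

**What the scale-down shows.** The desk-scale demo (2–4 channels, 10
sweeps) exercises every mechanism — sparse binding, routing, balance,
release — but compresses the sweep period from 1 s to tens of ms, so a
channel is re-stimulated before its activity has fully decayed. The
steady-state active fraction therefore drifts slowly downward as the
channel count (hence sweep period) grows at this scale; the acceptance
measurement uses the 2-channel configuration, 10 sweeps, averaged over 10
seeds after the one-sweep warm-up. Passing it shows the dynamic-assignment
statistic of the scaled system matches the full-scale figure, not that the
10⁸-neuron real-time run itself was reproduced; the full-scale run, power
figures, and logic-utilization numbers are hardware measurements outside
software reach.

## 8. Problem sizes and numerical checks

Defaults used by the test suite and acceptance script, chosen to keep a
full run on one CPU in minutes: decay-constant fits use 10⁴ trajectories ×
100 steps (log-linear fit over bins with mean > 5 % of the start value);
stimulus statistics use 10 channels × 100 sweeps = 10⁴ neuron-windows;
the emergent-dynamics run uses 2 channels × 10 sweeps × 10 seeds; the
drain-ratio experiment loads 1000 copies per delay queue. Exhaustive
enumerations (dither unbiasedness for all q < 2¹⁵, decay monotonicity over
the full code × leak × dither grid, state-packing round-trip) are exact.

## 9. Known limitations

* No synaptic plasticity (STDP or delay plasticity) — static weights only.
* Pipeline-, burst-, and handshake-level hardware behavior (11-stage neuron
  pipeline, ping-pong memory buffering, TX/RX cross-lock, FIFO depths) is
  represented only by the cycle-accounting timing model, never
  functionally.
* The stochastic readout mode models access slots per 1 ms step, not 5 µs
  wall-clock slots; sub-millisecond delay statistics are therefore shaped
  by the configured access budget.
* Spike counts saturate at 15 per type per step; population rates computed
  from events undercount during extreme synchrony.
* The arbiter's W commit granularity and the event-count scaling into W
  are explicit package choices (per-batch commit, shift 0) where the
  hardware is unspecified.
* The built-in experiment's motif is a documented reconstruction, not the
  published figure; single-neuron parameters are uniform across types.
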