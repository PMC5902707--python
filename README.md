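# cortexsim

A behavioral software model of a massively parallel cortex-simulator
architecture: fixed-point stochastic leaky integrate-and-fire (LIF) neurons
organized into 100-neuron **minicolumns** and up-to-128-column
**hypercolumns**, hierarchical spike-count event routing with programmable
1–16 ms axonal delays, and **dynamic assignment** of the sparsely active
minicolumns to a bounded pool of time-multiplexed update slots.

The package is for computational neuroscientists and neuromorphic-hardware
researchers who want to study this class of architecture — its arithmetic,
its routing contracts, and its emergent sparse-activity statistics — as an
ordinary, deterministic, testable Python library, at desk scale rather than
on an FPGA.

## The model

**Neuron.** Each neuron carries 8 bits of state: a signed 4-bit
post-synaptic current code (PSC, excitatory positive / inhibitory negative,
value = code/8) and a signed 4-bit membrane offset *u* from the resting
value. Per 1 ms step:

    PSC(t+1) = decay(PSC(t); L_psc, r1) + round(g_syn · W(t))
    u(t+1)   = decay(u(t);  L_mem, r2) + round(g_psc · PSC(t+1))

where `W` is the accumulated per-type synaptic input (4-bit), `g_syn, g_psc`
are 8-bit gains in [0.0625, 16], and `decay(x; L, r)` multiplies |x| by an
8-bit leak factor `L` (retention `L/256 ≈ τ/(τ+1)`), truncates to 1/32
units and adds a 5-bit dither `r` before the final shift — *stochastic
rounding*. The rounding is exactly unbiased (`E_r[decay] = x·L/256` up to
3-bit product truncation), stores only 4 bits per variable, and
decorrelates otherwise identical neurons. The 1/32 dither resolution caps
the effective time constant near 31 steps (~30 ms). A spike is emitted when
the membrane sum overflows the 4-bit range while the PSC is excitatory;
*u* then resets to −8 and decays back to rest (stochastic refractoriness,
τ_rfc). Inhibitory input can never trigger a spike.

**Communication.** Minicolumns exchange *events*: the source address plus
eight 4-bit per-type spike counts per 1 ms step. Connectivity is
hierarchical — an address-range lookup table (≤ 512 ranges over the 27-bit
address space) maps every minicolumn to its neuron parameters, its ≤ 16
fan-out targets (hypercolumn offset + 1–16 ms delay), and per-connection
rules (destination subset size, per-type weights, an 8×8 type mask) — so a
10⁸-neuron network is described in kilobytes. Delayed copies are released
either exactly (functional mode) or by the faithful stochastic multi-rate
readout, where a queue with delay *i* is drained at rate ∝ 1/i
(`P_i = P_1/i`, encoded as 20-bit thresholds against an LFSR draw).

**Dynamic assignment.** Of the up to 2²⁷ addressable minicolumns, only
*active* ones (a neuron integrating or firing, or pending input) occupy one
of the time-multiplexed slots; 16 arbiters bind addresses to slots, saturate
per-type weight accumulators, and the scheduler releases slots on
quiescence. Cortical activity is sparse — at full scale roughly 8 % of
minicolumns are active at a time — which is what lets a bounded pool
emulate a much larger network in real time.

## Worked example

`examples/06_auditory_sweep.py` builds a 2-channel tonotopic model of
auditory cortex (2 × 100 hypercolumns × 100 minicolumns × 100 neurons),
drives it with a cochlear pure-tone-sweep stimulus (10 Poisson neurons per
channel at ~10 Hz during the channel's 10 ms window of each sweep), and
prints:

```
network: 2,000,000 neurons, 20,000 minicolumns, 200 hypercolumns, 6 LUT ranges, out-degree 24
stimulus: 16 Poisson spikes, within-window rate 8.00 Hz (nominal 10 Hz)
ran 200 ms: 29161 spike-count events
mean excitatory population rate per channel (Hz/neuron): [0.097 0.087]
mean inhibitory population rate per channel (Hz/neuron): [1.461 1.005]
active minicolumns: peak 10.9%, steady-state mean 6.09% of 20,000 addresses
```

Each minicolumn projects to 24 others (8 in its own hypercolumn, 8 in each
tonotopic neighbour); channels are mutually unconnected. After a channel's
input burst it settles into a noise-driven asynchronous-irregular state that
persists between stimulations; the last line is the dynamic-assignment
statistic — the fraction of minicolumn addresses bound to an update slot,
the quantity the slot pool is sized by.

The other examples each demonstrate one capability: dithered decay
arithmetic (`01`), a single neuron (`02`), the delay store and its
drain-rate ratios (`03`), the bind/accumulate/release slot lifecycle (`04`),
and the update-loop timing model (`05`). A thin CLI wraps the library:
`cortexsim demo auditory --channels 2 --out DIR` and
`cortexsim run --config net.yaml --duration-ms 100 --out DIR`.

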