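"""The hardware timing model: real-time capacity of the update loop.

The time-multiplexed minicolumn pool is processed in 1024-slot segments (one
5 ns clock cycle per slot, matching the memory burst length), with an
up-to-200-cycle event-store access window between segments.  These two
numbers fix how many minicolumns one update sweep can serve within the 1 ms
biological step — the real-time capacity of the architecture.
"""

from cortexsim import TimingModel, addressable_capacity, estimate_update_period, real_time_capacity

# the published real-time configuration: 176 k minicolumn slots
tm = TimingModel(n_tm=176 * 1024, clock_period_ns=5.0, segment_size=1024, slot_cycles=200)
period = estimate_update_period(tm)
print(f"176 k slots, 200-cycle windows @ 5 ns: update period {period:.5f} ms "
      f"(rounds to {round(period)} ms -> real time)")

# one segment alone
print(f"single 1024-slot segment: {estimate_update_period(TimingModel(n_tm=1024)) * 1e3:.2f} us")

# capacity with no event-store windows: 1 ms / 5 ns = 200 k slots
cap = real_time_capacity(clock_period_ns=5.0, budget_ms=1.0, slot_cycles=0)
print(f"real-time slot capacity at 200 MHz without access windows: {cap:,}")

# the dynamic-assignment leverage: 2^20 slots at assignment ratio 128
print(f"addressable minicolumns with 2^20 slots at ratio 128: "
      f"{addressable_capacity(1 << 20, 128):,} (= 2^27)")
print(f"  -> at 100 neurons per minicolumn: "
      f"{addressable_capacity(1 << 20, 128) * 100 / 1e9:.1f} billion neurons addressable")
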