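"""Tonotopic network construction, sweep stimulus statistics, and analysis."""

import numpy as np
import pytest

from cortexsim.auditory import (
    AuditoryConfig,
    active_fraction_trace,
    build_auditory_network,
    channel_rate_map,
    compile_stimulus,
    default_inter_mask,
    default_intra_mask,
    estimate_poisson_rate,
    poisson_sweep_stimulus,
    read_events,
    run_auditory_demo,
    write_events,
)
from cortexsim.engine import CompiledNetwork, Simulator
from cortexsim.lut import split_address


class TestNetworkBuilder:
    def test_published_scale_totals(self):
        cfg = AuditoryConfig()
        lut, report = build_auditory_network(cfg)
        assert report.n_neurons == 100_000_000
        assert report.n_minicolumns == 1_000_000
        assert report.n_hypercolumns == 10_000
        assert report.out_degree_interior == 24

    def test_structural_counts_scale_linearly(self):
        for nch in (1, 2, 5):
            cfg = AuditoryConfig(n_channels=nch)
            _, report = build_auditory_network(cfg)
            assert report.n_neurons == nch * 1_000_000
            assert report.n_minicolumns == nch * 10_000

    def test_range_count_stays_within_table_budget(self):
        lut, report = build_auditory_network(AuditoryConfig())
        assert report.n_ranges == 300  # 3 per channel
        assert len(lut.thresholds) <= 512

    def test_boundary_hypercolumns_drop_missing_neighbour(self):
        cfg = AuditoryConfig(n_channels=1, hc_per_channel=3)
        lut, _ = build_auditory_network(cfg)
        first = lut.get_post_connection(cfg.address(0, 0, 0))
        mid = lut.get_post_connection(cfg.address(0, 1, 0))
        last = lut.get_post_connection(cfg.address(0, 2, 0))
        assert len(first.targets) == 2  # recurrent + next
        assert len(mid.targets) == 3
        assert len(last.targets) == 2  # recurrent + previous
        offs = {t.hc_offset for t in mid.targets}
        assert offs == {0, 1, (1 << 20) - 1}

    def test_weight_codes_nearest_representable(self):
        w = AuditoryConfig().source_weights()
        assert w[0] == 3 and w[2] == 3 and w[4] == 3       # 0.4 -> 3/8
        assert w[1] == -8 and w[3] == -8 and w[5] == -8    # -1.0 -> -8/8

    def test_motif_masks_shape_and_inhibition_locality(self):
        intra, inter = default_intra_mask().mask, default_inter_mask().mask
        assert intra.shape == inter.shape == (8, 8)
        # inhibitory types project intracortically only
        for src in (1, 3, 5):
            assert inter[:, src].sum() == 0


class TestPoissonStimulus:
    def test_stream_is_deterministic_per_seed(self):
        cfg = AuditoryConfig(n_channels=3, n_sweeps=2)
        a = poisson_sweep_stimulus(cfg, seed=5)
        b = poisson_sweep_stimulus(cfg, seed=5)
        assert a == b
        c = poisson_sweep_stimulus(cfg, seed=6)
        assert a != c

    def test_spikes_confined_to_channel_windows(self):
        cfg = AuditoryConfig(n_channels=4, n_sweeps=3)
        for ev in poisson_sweep_stimulus(cfg, seed=1):
            window = (ev.t_ms // cfg.sweep_window_ms) % cfg.n_channels
            assert window == ev.channel

    def test_targets_stay_inside_the_channel(self):
        cfg = AuditoryConfig(n_channels=3, n_sweeps=1)
        for ev in poisson_sweep_stimulus(cfg, seed=2):
            for addr in ev.targets:
                hc, mc = split_address(addr)
                assert hc // cfg.hc_per_channel == ev.channel
                assert mc < cfg.mc_per_hc

    def test_rate_close_to_ten_hz(self):
        cfg = AuditoryConfig(n_channels=10, n_sweeps=100)
        events = poisson_sweep_stimulus(cfg, seed=3)
        rate = estimate_poisson_rate(events, cfg)
        assert rate == pytest.approx(10.0, rel=0.07)

    def test_window_counts_are_poisson_dispersed(self):
        # variance/mean of per-window counts in [0.8, 1.2]
        cfg = AuditoryConfig(n_channels=10, n_sweeps=100)
        events = poisson_sweep_stimulus(cfg, seed=4)
        counts = np.zeros((cfg.n_sweeps, cfg.n_channels, cfg.poisson_per_channel))
        for ev in events:
            counts[ev.t_ms // cfg.sweep_period_ms, ev.channel, ev.neuron_id] += 1
        flat = counts.ravel()  # 10^4 neuron-windows
        assert len(flat) == 10_000
        assert 0.8 < flat.var() / flat.mean() < 1.2

    def test_compiled_stimulus_hits_only_l4e(self):
        cfg = AuditoryConfig(n_channels=2, n_sweeps=1)
        stim = compile_stimulus(poisson_sweep_stimulus(cfg, seed=7), cfg)
        for _, (addrs, W) in stim.items():
            assert np.all(W[:, 2] > 0)  # L4e drive
            assert np.all(W[:, [0, 1, 3, 4, 5, 6, 7]] == 0)


class TestChannelIsolation:
    def test_no_cross_channel_activity(self):
        """Stimulating only channel 0 must never produce events in channel 1:
        there are no inter-channel connections."""
        cfg = AuditoryConfig(n_channels=2, hc_per_channel=10, n_sweeps=2)
        lut, _ = build_auditory_network(cfg)
        full = poisson_sweep_stimulus(cfg, seed=9)
        only0 = [ev for ev in full if ev.channel == 0]
        assert only0, "need some channel-0 stimulus"
        stim = compile_stimulus(only0, cfg)
        sim = Simulator(CompiledNetwork(lut), seed=9)
        rec = sim.run(cfg.duration_ms, stimulus=stim)
        _, addrs, _ = rec.events()
        if len(addrs):
            channels = (addrs >> 7) // cfg.hc_per_channel
            assert np.all(channels == 0)


class TestAnalysis:
    def test_rate_map_zero_without_spikes(self):
        cfg = AuditoryConfig(n_channels=2, n_sweeps=1)
        exc, inh = channel_rate_map(
            np.zeros(0), np.zeros(0), np.zeros((0, 8)), cfg
        )
        assert exc.shape == (2, 2)  # 20 ms / 10 ms bins
        assert not exc.any() and not inh.any()

    def test_rate_map_conserves_spike_totals(self):
        cfg = AuditoryConfig(n_channels=2, hc_per_channel=4, n_sweeps=3)
        sim, rec = run_auditory_demo(cfg, seed=1)
        ts, addrs, counts = rec.events()
        exc, inh = channel_rate_map(ts, addrs, counts, cfg)
        tc = np.asarray(cfg.type_counts)
        pop = cfg.hc_per_channel * cfg.mc_per_hc
        bin_s = 0.01
        exc_total = exc.sum() * tc[[0, 2, 4]].sum() * pop * bin_s
        inh_total = inh.sum() * tc[[1, 3, 5]].sum() * pop * bin_s
        assert exc_total == pytest.approx(counts[:, [0, 2, 4]].sum())
        assert inh_total == pytest.approx(counts[:, [1, 3, 5]].sum())

    def test_rate_map_single_channel_row(self):
        cfg = AuditoryConfig(n_channels=3, n_sweeps=1)
        ts = np.array([5, 12])
        addrs = np.array([cfg.address(1, 0, 0), cfg.address(1, 2, 7)])
        counts = np.zeros((2, 8), int)
        counts[:, 0] = 4
        exc, _ = channel_rate_map(ts, addrs, counts, cfg)
        assert exc[1].sum() > 0
        assert exc[[0, 2]].sum() == 0

    def test_active_fraction_rest_is_zero(self):
        cfg = AuditoryConfig(n_channels=2, n_sweeps=2)
        t = np.arange(40)
        pct, steady = active_fraction_trace(t, np.zeros(40), cfg, warmup_ms=10)
        assert not pct.any() and steady == 0.0


class TestEventIO:
    def test_empty_roundtrip(self, tmp_path):
        path = tmp_path / "ev.tsv"
        write_events(path, [], [], np.zeros((0, 8)))
        ts, addrs, counts = read_events(path)
        assert len(ts) == 0 and counts.shape == (0, 8)

    def test_random_events_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 500
        ts = np.sort(rng.integers(0, 1000, n))
        addrs = rng.integers(0, 1 << 27, n)
        counts = rng.integers(0, 16, (n, 8))
        path = tmp_path / "ev.tsv"
        write_events(path, ts, addrs, counts)
        ts2, addrs2, counts2 = read_events(path)
        assert np.array_equal(ts, ts2)
        assert np.array_equal(addrs, addrs2)
        assert np.array_equal(counts, counts2)

    def test_malformed_rows_report_line_numbers(self, tmp_path):
        path = tmp_path / "ev.tsv"
        write_events(path, [1], [2], np.zeros((1, 8), int))
        with open(path, "a") as fh:
            fh.write("3\t4\t5\n")  # truncated row
        with pytest.raises(ValueError, match=":3:"):
            read_events(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "ev.tsv"
        path.write_text("not a header\n")
        with pytest.raises(ValueError, match=":1:"):
            read_events(path)
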