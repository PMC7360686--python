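"""Synthetic MEA / calcium generators: determinism, planted statistics."""

import numpy as np
import pytest

from culturenet import (CalciumSpec, NetworkSpec, condition_preset,
                       generate_calcium_traces, generate_mea_recording,
                       hub_network_spec, preset_names, write_spike_table)


class TestMeaGenerator:
    def test_silent_spec_empty_raster(self):
        spec = NetworkSpec(n_electrodes=10, background_rate_hz=0.0,
                           burst_rate_per_min=0.0)
        raster, truth = generate_mea_recording(spec, 60.0, 0)
        assert raster.n_spikes == 0
        assert raster.n_electrodes == 10

    def test_deterministic_relay_limit(self):
        """w=1, zero jitter: every follower spike sits exactly one edge
        delay after a hub spike."""
        spec = hub_network_spec(n_electrodes=5, n_hubs=1, n_followers=1,
                                w=1.0, delay_min_s=0.005, delay_max_s=0.005,
                                jitter_sd_s=0.0, background_rate_hz=0.0,
                                burst_rate_per_min=2.0, burst_packet=(1, 0.005))
        raster, truth = generate_mea_recording(spec, 120.0, 1)
        hub = truth.hub_ids[0]
        follower = truth.planted_edges()[0][1]
        hub_times = raster.spike_times[hub]
        assert hub_times.size > 0
        expected = hub_times + 0.005
        expected = expected[expected <= 120.0]
        np.testing.assert_array_equal(raster.spike_times[follower], expected)

    def test_background_poisson_statistics(self):
        """w=0: total spike count matches Poisson moments over seeds."""
        spec = NetworkSpec(n_electrodes=59, background_rate_hz=1.0,
                           burst_rate_per_min=0.0)
        mean = 59 * 300  # rate x electrodes x duration
        totals = [generate_mea_recording(spec, 300.0, s)[0].n_spikes
                  for s in range(10)]
        sd_of_mean = np.sqrt(mean / len(totals))
        assert abs(np.mean(totals) - mean) < 3 * sd_of_mean

    def test_seed_determinism_bit_identical(self, tmp_path):
        spec = hub_network_spec(n_hubs=2, n_followers=5)
        r1, _ = generate_mea_recording(spec, 60.0, 42)
        r2, _ = generate_mea_recording(spec, 60.0, 42)
        for eid in r1.electrode_ids:
            np.testing.assert_array_equal(r1.spike_times[eid],
                                          r2.spike_times[eid])
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_spike_table(r1, a)
        write_spike_table(r2, b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self):
        spec = hub_network_spec(n_hubs=2, n_followers=5)
        r1, _ = generate_mea_recording(spec, 60.0, 1)
        r2, _ = generate_mea_recording(spec, 60.0, 2)
        assert r1.n_spikes != r2.n_spikes

    def test_ground_truth_packets_in_raster(self):
        """Every planted packet spike appears in the emitted raster."""
        spec = hub_network_spec(n_hubs=2, n_followers=5,
                                burst_rate_per_min=4.0)
        raster, truth = generate_mea_recording(spec, 120.0, 7)
        n_packet, dt = spec.burst_packet
        for hub, inits in truth.burst_initiations.items():
            times = raster.spike_times[hub]
            for t0 in inits:
                for k in range(n_packet):
                    t = t0 + k * dt
                    if t <= 120.0:
                        assert np.any(times == t)

    def test_transmitted_count_monotone_in_w(self):
        """Same seed: transmitted spikes never decrease as w grows."""
        counts = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = hub_network_spec(n_hubs=1, n_followers=3, w=w,
                                    background_rate_hz=0.0,
                                    burst_rate_per_min=5.0)
            raster, truth = generate_mea_recording(spec, 120.0, 9)
            followers = {j for _, j in truth.planted_edges()}
            counts.append(sum(raster.spike_times[f].size for f in followers))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[0] == 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            NetworkSpec(n_electrodes=5, hub_ids=["el01"],
                        adjacency={("el01", "el02"): 1.5},
                        delays={("el01", "el02"): 0.005})
        with pytest.raises(ValueError, match="delay"):
            NetworkSpec(n_electrodes=5, hub_ids=["el01"],
                        adjacency={("el01", "el02"): 0.5})


class TestCalciumGenerator:
    def test_inactive_all_noise(self):
        spec = CalciumSpec(n_cells=5, active_fraction=0.0, duration_s=60.0)
        traces, truth = generate_calcium_traces(spec, 0)
        assert not any(truth.active_cells.values())
        assert np.all(np.abs(traces.traces - spec.baseline)
                      < 6 * spec.noise_sd)

    def test_noiseless_kernel_peak_equals_amplitude(self):
        spec = CalciumSpec(n_cells=4, active_fraction=1.0,
                           event_rate_per_min=0.4, event_duration_s=8.0,
                           noise_sd=0.0, duration_s=300.0)
        traces, truth = generate_calcium_traces(spec, 2)
        for i, cid in enumerate(traces.cell_ids):
            if not truth.event_times[cid]:
                continue
            dff = traces.traces[i] / spec.baseline - 1.0
            # sampled peak is within one frame of decay from the amplitude
            assert dff.max() <= spec.amplitude + 1e-12
            assert dff.max() >= spec.amplitude * np.exp(
                -0.5 / spec.decay_tau_s) - 1e-12

    def test_planted_event_count_statistics(self):
        """2 events/min for 300 s: mean count per active cell near 10."""
        spec = CalciumSpec(n_cells=100, active_fraction=1.0,
                           event_rate_per_min=2.0, event_duration_s=6.0,
                           duration_s=300.0)
        counts = []
        for seed in range(3):
            _, truth = generate_calcium_traces(spec, seed)
            counts += [len(v) for v in truth.event_times.values()]
        # renewal with corrected rate: variance at most Poisson-like
        sd_of_mean = np.sqrt(10 / len(counts))
        assert abs(np.mean(counts) - 10) < 3 * sd_of_mean

    def test_seed_determinism(self):
        spec = CalciumSpec(n_cells=10, duration_s=60.0)
        t1, _ = generate_calcium_traces(spec, 5)
        t2, _ = generate_calcium_traces(spec, 5)
        np.testing.assert_array_equal(t1.traces, t2.traces)

    def test_truth_events_visible_in_trace(self):
        spec = CalciumSpec(n_cells=10, active_fraction=1.0,
                           event_rate_per_min=1.0, duration_s=120.0)
        traces, truth = generate_calcium_traces(spec, 3)
        for i, cid in enumerate(traces.cell_ids):
            dff = traces.traces[i] / spec.baseline - 1.0
            for t0 in truth.event_times[cid]:
                frame = int(np.ceil(t0 * spec.frame_rate_hz))
                if frame < traces.n_frames:
                    assert dff[frame] > 0.2  # well above noise

    def test_infeasible_rate_rejected(self):
        spec = CalciumSpec(n_cells=2, active_fraction=1.0,
                           event_rate_per_min=8.0, event_duration_s=13.0,
                           duration_s=60.0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_calcium_traces(spec, 0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            generate_calcium_traces(
                CalciumSpec(n_cells=1, duration_s=0.5, frame_rate_hz=2.0), 0)


class TestPresets:
    def test_sham_div28_rate(self):
        _, cal = condition_preset("sham_DIV28")
        assert cal.event_rate_per_min == 2.49
        assert cal.active_fraction == 0.687
        assert cal.event_duration_s == 6.2

    def test_abeta_div28_duration(self):
        _, cal = condition_preset("abeta_DIV28")
        assert cal.event_duration_s == 13.24
        assert cal.event_rate_per_min == 0.35

    def test_fivexfad_div21(self):
        _, cal = condition_preset("fiveXFAD_DIV21")
        assert cal.active_fraction == 0.443
        assert cal.event_rate_per_min == 1.16

    def test_sham_div21_network_shape(self):
        net, _ = condition_preset("sham_DIV21")
        assert net.n_electrodes == 59
        assert len(net.hub_ids) == 5
        assert len(net.adjacency) == 50
        assert all(w == 0.8 for w in net.adjacency.values())
        # planted initiation total matches the printed small-burst rate
        assert net.burst_rate_per_min * len(net.hub_ids) * 5 \
            == pytest.approx(217.5)

    def test_unknown_token_lists_registry(self):
        with pytest.raises(ValueError, match="sham_DIV21"):
            condition_preset("nope")
        assert "abeta_DIV28" in preset_names()
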