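"""Session simulator: packet scheduling, transport impairments, emulation."""

import json

import numpy as np
import pytest

import rcstream as rc
from rcstream.simulator import (
    SESSION_FILES,
    TIMESTAMP_EPOCH_UNIX_S,
    _dumps,
    emulate_fft_power_stream,
)

from conftest import surviving_sample_indices


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"td_fs": 300}, "td_fs"),
            ({"td_fs": 1000, "td_channels": 3}, "1000"),
            ({"td_channels": 5}, "td_channels"),
            ({"accel_fs": 100}, "accel_fs"),
            ({"drop_probability": 1.5}, "drop_probability"),
            ({"packet_size_range": (0, 10)}, "packet_size_range"),
            ({"duration": -1}, "duration"),
        ],
    )
    def test_invalid_config_names_offending_field(self, kwargs, field):
        with pytest.raises(rc.ConfigurationError, match=field):
            rc.SimulationConfig(**kwargs)

    def test_more_than_eight_power_bands_rejected(self):
        bands = tuple(rc.PowerBand(5 + i, 6 + i) for i in range(9))
        with pytest.raises(rc.ConfigurationError, match="eight"):
            rc.SimulationConfig(power_bands=bands)


class TestSchedulePackets:
    def test_single_packet_when_range_covers_stream(self):
        t = 1_589_544_000_000 + np.arange(100) * 4.0
        packets = rc.schedule_packets(t, (100, 100), seed=0, initial_seq=17)
        assert len(packets) == 1
        assert packets[0].data_type_sequence == 17
        assert packets[0].n_samples == 100

    def test_tick_difference_matches_sample_count(self):
        # two packets at 250 Hz, second holds 50 samples -> 2000 ticks apart
        t = 1_589_544_000_000 + np.arange(100) * 4.0
        packets = rc.schedule_packets(t, (50, 50), seed=0)
        assert len(packets) == 2
        dt = (packets[1].system_tick - packets[0].system_tick) % (1 << 16)
        assert dt == 2000

    def test_timestamp_resolution_is_one_second(self):
        fs = 250
        t = 1_589_544_000_000 + np.arange(20 * fs) * (1000.0 / fs)
        packets = rc.schedule_packets(t, (10, 40), seed=1)
        stamps = {p.timestamp for p in packets}
        assert len(stamps) <= 21

    def test_timestamp_epoch_is_march_2000(self):
        t = np.array([1_589_544_000_000.0])
        (p,) = rc.schedule_packets(t, (1, 1), seed=0)
        assert p.timestamp == 1_589_544_000 - TIMESTAMP_EPOCH_UNIX_S

    def test_every_sample_in_exactly_one_packet(self):
        t = 1_589_544_000_000 + np.arange(997) * 4.0
        packets = rc.schedule_packets(t, (30, 120), seed=2)
        covered = sorted(
            i for p in packets for i in range(p.start, p.stop)
        )
        assert covered == list(range(997))

    def test_empty_stream_rejected(self):
        with pytest.raises(rc.EmptyStreamError):
            rc.schedule_packets(np.empty(0), (10, 20), seed=0)


class TestTransportImpairments:
    def make_packets(self, n=1000):
        t = 1_589_544_000_000 + np.arange(n * 50) * 4.0
        return rc.schedule_packets(t, (50, 50), seed=0)

    def test_no_impairment_is_identity(self):
        packets = self.make_packets(100)
        out, log = rc.apply_transport_impairments(packets, 0.0, 0.0, 0.0, seed=1)
        assert out == packets
        assert [e for e in log if e["event"] != "drop"] == []

    def test_total_loss(self):
        packets = self.make_packets(50)
        out, log = rc.apply_transport_impairments(packets, 1.0, 0.0, 0.0, seed=1)
        assert out == []
        assert sum(e["event"] == "drop" for e in log) == 50

    def test_drop_fraction_within_binomial_bounds(self):
        packets = self.make_packets(10_000)
        out, log = rc.apply_transport_impairments(packets, 0.05, 0.0, 0.0, seed=3)
        n_drop = sum(e["event"] == "drop" for e in log)
        p, n = 0.05, 10_000
        sd = (n * p * (1 - p)) ** 0.5
        assert abs(n_drop - n * p) < 3 * sd

    def test_jitter_standard_deviation(self):
        packets = self.make_packets(1000)
        out, _ = rc.apply_transport_impairments(packets, 0.0, 0.0, 50.0, seed=4)
        err = np.array([p.packet_gen_time - p.true_last_time for p in out])
        assert 40.0 < err.std() < 60.0

    def test_rx_time_after_gen_time_without_jitter(self):
        packets = self.make_packets(200)
        out, _ = rc.apply_transport_impairments(packets, 0.0, 0.0, 0.0, seed=5)
        assert all(p.packet_rx_unix_time >= p.packet_gen_time for p in out)

    def test_reordering_swaps_adjacent_pairs(self):
        packets = self.make_packets(500)
        out, log = rc.apply_transport_impairments(packets, 0.0, 0.3, 0.0, seed=6)
        swaps = [e for e in log if e["event"] == "swap"]
        assert swaps  # at 30% some swaps certainly occur
        seqs = [p.index for p in out]
        assert sorted(seqs) == list(range(500))
        assert seqs != list(range(500))
        # every displacement is local: one position
        assert max(abs(s - i) for i, s in enumerate(seqs)) == 1


class TestSimulateSession:
    def test_determinism_bytes(self, impaired_config):
        c1, _ = rc.simulate_session(impaired_config)
        c2, _ = rc.simulate_session(impaired_config)
        for fname in SESSION_FILES:
            assert _dumps(c1[fname]) == _dumps(c2[fname])

    def test_different_seed_changes_output(self, impaired_config):
        import dataclasses

        c1, _ = rc.simulate_session(impaired_config)
        c2, _ = rc.simulate_session(dataclasses.replace(impaired_config, seed=8))
        assert _dumps(c1["RawDataTD.json"]) != _dumps(c2["RawDataTD.json"])

    def test_sample_conservation(self, impaired_session):
        contents, truth = impaired_session
        for stream, fname in (("RawDataTD", "RawDataTD.json"),):
            in_json = sum(
                len(p["ChannelSamples"]["0"]) for p in contents[fname]["Packets"]
            )
            dropped = sum(
                p["n_samples"] for p in truth.packet_log[stream] if p["dropped"]
            )
            assert in_json + dropped == len(truth.sample_times[stream])

    def test_truth_covers_every_sample_with_exact_spacing(self, impaired_session):
        _, truth = impaired_session
        td = truth.sample_times["RawDataTD"]
        np.testing.assert_allclose(np.diff(td), 4.0, rtol=0, atol=1e-9)
        ac = truth.sample_times["RawDataAccel"]
        np.testing.assert_allclose(np.diff(ac), 1000.0 / 64, rtol=0, atol=1e-9)

    def test_clock_consistency_without_drift(self, clean_session):
        """Tick and timestamp elapsed agree within 1 s for close packets."""
        contents, _ = clean_session
        pkts = contents["RawDataTD.json"]["Packets"]
        for a, b in zip(pkts, pkts[1:]):
            dt_tick = ((b["SystemTick"] - a["SystemTick"]) % (1 << 16)) / 1e4
            if dt_tick < 6.5535:
                assert abs(dt_tick - (b["Timestamp"] - a["Timestamp"])) <= 1.0

    def test_disabled_stream_writes_empty_record_list(self):
        cfg = rc.SimulationConfig(
            duration=10.0, seed=2, stream_enable_flags={"RawDataFFT": False}
        )
        contents, _ = rc.simulate_session(cfg)
        assert contents["RawDataFFT.json"]["Records"] == []


class TestFFTPowerEmulation:
    def test_zero_signal_gives_zero_power(self):
        cfg = rc.FFTConfig(fft_size=256, interval=0.1, fs=250)
        cal = rc.AmplifierCalibration()
        t = 1_589_544_000_000 + np.arange(2500) * 4.0
        _, q, raw = emulate_fft_power_stream(
            np.zeros(2500), t, cfg, (rc.PowerBand(8, 12),), cal
        )
        assert np.all(raw["8-12Hz"] == 0)

    def test_emulator_equals_offdevice_recomputation(self, clean_session):
        """The central oracle: identical arithmetic stream-side and off-device."""
        contents, truth = clean_session
        sig = truth.signals["RawDataTD"]["0"]
        t = truth.sample_times["RawDataTD"]
        cfg = rc.FFTConfig(fft_size=256, interval=0.1, fs=250)
        cal = rc.AmplifierCalibration()
        band = rc.PowerBand(8.05, 12.20)
        _, _, raw = emulate_fft_power_stream(sig, t, cfg, (band,), cal, quantize=False)
        series = rc.calculate_new_power(sig, cfg, band, cal, times=t)
        ref = raw[band.label]
        assert np.max(np.abs(series.power - ref) / np.maximum(np.abs(ref), 1e-300)) < 1e-9

    def test_burst_scenario_produces_three_plateaus(self):
        """25 uV sine at 20 Hz in three 5 s bursts -> three power plateaus."""
        cfg = rc.SimulationConfig(
            duration=30.0,
            td_fs=250,
            drop_probability=0.0,
            reorder_probability=0.0,
            pgt_jitter_sd=0.0,
            systemtick_drift_ppm=0.0,
            signal_specs=(
                rc.SignalSpec(
                    "burst_sine", amplitude=0.025, frequency=20.0,
                    burst_on=5.0, burst_off=5.0, channel=0,
                ),
            ),
            power_bands=(rc.PowerBand(18.0, 22.0),),
            quantize_power=False,
            seed=9,
        )
        contents, truth = rc.simulate_session(cfg)
        p = truth.power_unquantized["Band0"]
        high = p > p.max() / 2
        # count rising edges of the high mask: one per burst
        edges = np.flatnonzero(np.diff(high.astype(int)) == 1)
        n_bursts = len(edges) + (1 if high[0] else 0)
        assert n_bursts == 3
        floor = p[~high][p[~high] > 0]
        assert p[high].min() / np.median(p[~high]) > 100


class TestWriteSession:
    def test_all_files_strictly_parse(self, clean_folder):
        for fname in SESSION_FILES:
            json.loads((clean_folder / fname).read_text())

    def test_groundtruth_sidecar_marked_synthetic(self, clean_folder):
        doc = json.loads((clean_folder / "_groundtruth.json").read_text())
        assert "SYNTHETIC" in doc["note"]

    def test_malformed_file_fails_strict_parse_but_repairs(self, tmp_path, clean_session):
        contents, truth = clean_session
        folder = tmp_path / "mal"
        rc.write_session(folder, contents, truth, malform=True)
        text = (folder / "RawDataTD.json").read_text()
        with pytest.raises(ValueError):
            json.loads(text)
        json.loads(rc.repair_malformed_json(text))
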