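"""Time reconstruction: cleaning, chunking, anchoring, grid snapping."""

import dataclasses
import itertools

import numpy as np
import pytest

import rcstream as rc
from rcstream.timealign import _continuous, restore_packet_order

from conftest import surviving_sample_indices

T0 = 1_589_544_000_000  # unix ms session start used throughout
EPOCH = 951_868_800


def make_packet(seq, n=50, fs=250.0, t_last=None, tick=None, ts=None, pgt=None):
    """A hand-built packet whose timing fields are mutually consistent
    for a continuous stream starting at T0, unless overridden."""
    if t_last is None:
        t_last = T0 + (seq + 1) * n * (1000.0 / fs)
    elapsed_s = (t_last - T0) / 1000.0
    if tick is None:
        tick = int(elapsed_s * 1e4) % (1 << 16)
    if ts is None:
        ts = int(t_last // 1000) - EPOCH
    if pgt is None:
        pgt = int(round(t_last))
    return rc.Packet(
        system_tick=tick,
        timestamp=ts,
        packet_gen_time=pgt,
        packet_rx_unix_time=pgt + 60,
        data_type_sequence=seq % 256,
        sample_rate=fs,
        samples={"0": np.zeros(n)},
    )


def continuous_stream(n_packets, n=50, fs=250.0):
    return [make_packet(i, n=n, fs=fs) for i in range(n_packets)]


class TestClockConstants:
    def test_tick_cycle_length(self):
        c = rc.ClockConstants()
        assert c.tick_cycle_s == pytest.approx(6.5535, abs=1e-12)

    def test_timestamp_epoch_conversion(self):
        # calendar oracle: 2000-03-01T00:00:00Z in unix seconds
        import datetime

        epoch = datetime.datetime(2000, 3, 1, tzinfo=datetime.timezone.utc)
        assert rc.ClockConstants().timestamp_epoch_unix_s == int(epoch.timestamp())
        assert rc.ClockConstants().timestamp_to_unix_ms(0) == 951_868_800_000.0


class TestRejectInvalidPackets:
    def test_clean_stream_kept_whole(self):
        pkts = continuous_stream(10)
        kept, log = rc.reject_invalid_packets(pkts)
        assert kept == pkts and len(log) == 0

    def test_negative_packet_gen_time(self):
        pkts = continuous_stream(5)
        pkts[2] = dataclasses.replace(pkts[2], packet_gen_time=-1)
        kept, log = rc.reject_invalid_packets(pkts)
        assert len(kept) == 4
        assert log.iloc[0]["rule"] == "negative_packet_gen_time"

    def test_backward_beyond_500ms(self):
        pkts = continuous_stream(5)
        pkts[3] = dataclasses.replace(
            pkts[3], packet_gen_time=pkts[2].packet_gen_time - 600
        )
        kept, log = rc.reject_invalid_packets(pkts)
        assert log.iloc[0]["rule"] == "backward_packet_gen_time"
        assert len(kept) == 4

    def test_backward_within_500ms_kept(self):
        pkts = continuous_stream(5)
        pkts[3] = dataclasses.replace(
            pkts[3], packet_gen_time=pkts[2].packet_gen_time - 400
        )
        kept, _ = rc.reject_invalid_packets(pkts)
        assert len(kept) == 5

    def test_timestamp_outlier_beyond_24h(self):
        pkts = continuous_stream(9)
        pkts[4] = dataclasses.replace(pkts[4], timestamp=pkts[4].timestamp + 25 * 3600)
        kept, log = rc.reject_invalid_packets(pkts)
        assert log.iloc[0]["rule"] == "timestamp_outlier"
        assert len(kept) == 8

    def test_pgt_timestamp_disagreement(self):
        pkts = continuous_stream(5)
        # push PGT forward 3 s: no backward trigger, but elapsed PGT
        # disagrees with elapsed timestamp by ~3 s
        pkts[3] = dataclasses.replace(
            pkts[3], packet_gen_time=pkts[3].packet_gen_time + 3000
        )
        kept, log = rc.reject_invalid_packets(pkts)
        assert log.iloc[0]["rule"] == "pgt_timestamp_disagreement"

    def test_comparisons_use_previous_kept_packet(self):
        pkts = continuous_stream(6)
        # packet 2 is invalid (negative PGT); packet 3 is 400 ms behind
        # packet 1's PGT, which is fine vs packet 1 but would look fine
        # vs packet 2 too -- the reference must be the previous KEPT one
        pkts[2] = dataclasses.replace(pkts[2], packet_gen_time=-5)
        pkts[3] = dataclasses.replace(
            pkts[3], packet_gen_time=pkts[1].packet_gen_time - 400
        )
        kept, log = rc.reject_invalid_packets(pkts)
        assert len(kept) == 5
        assert set(log["rule"]) == {"negative_packet_gen_time"}


class TestIdentifyChunks:
    def test_unimpaired_stream_is_one_chunk(self):
        chunks = rc.identify_chunks(continuous_stream(20))
        assert len(chunks) == 1
        assert chunks[0].n_samples == 20 * 50

    def test_dropped_packet_splits_at_the_drop(self):
        pkts = continuous_stream(10)
        del pkts[4]
        chunks = rc.identify_chunks(pkts)
        assert len(chunks) == 2
        assert (chunks[0].n_packets, chunks[1].n_packets) == (4, 5)

    def test_sequence_rollover_stays_one_chunk(self):
        pkts = [make_packet(i) for i in range(254, 258)]  # seq 254,255,0,1
        assert [p.data_type_sequence for p in pkts] == [254, 255, 0, 1]
        assert len(rc.identify_chunks(pkts)) == 1

    def test_rate_change_forces_boundary(self):
        a = continuous_stream(3)
        t_next = a[-1].packet_gen_time + 4
        b = [
            make_packet(3 + i, n=50, fs=500.0, t_last=t_next + 100 * (i + 1))
            for i in range(3)
        ]
        chunks = rc.identify_chunks(a + b)
        assert len(chunks) >= 2
        assert chunks[0].fs == 250 and chunks[-1].fs == 500

    def test_partition_equals_brute_force_on_small_instances(self):
        """For <= 5 packets the maximal-run partition must equal the
        coarsest partition consistent with the pairwise continuity
        predicate, found by exhaustive search over all partitions."""
        rng = np.random.default_rng(12)
        c = rc.ClockConstants()
        for trial in range(200):
            n = int(rng.integers(2, 6))
            pkts = continuous_stream(n)
            # randomly corrupt some adjacencies
            for i in range(1, n):
                if rng.random() < 0.4:
                    kind = rng.integers(3)
                    if kind == 0:
                        pkts[i] = dataclasses.replace(
                            pkts[i], data_type_sequence=(pkts[i].data_type_sequence + 7) % 256
                        )
                    elif kind == 1:
                        pkts[i] = dataclasses.replace(
                            pkts[i], system_tick=(pkts[i].system_tick + 5000) % (1 << 16)
                        )
                    else:
                        pkts[i] = dataclasses.replace(pkts[i], timestamp=pkts[i].timestamp + 5)
            got = [(ch.start, ch.stop) for ch in rc.identify_chunks(pkts)]
            # brute force: all contiguous partitions whose blocks are
            # internally continuous; the coarsest (fewest blocks) is unique
            best = None
            for mask in itertools.product([0, 1], repeat=n - 1):
                blocks, start = [], 0
                for i, cut in enumerate(mask, start=1):
                    if cut:
                        blocks.append((start, i))
                        start = i
                blocks.append((start, n))
                ok = all(
                    _continuous(pkts[i - 1], pkts[i], c)
                    for a, b in blocks
                    for i in range(a + 1, b)
                )
                if ok and (best is None or len(blocks) < len(best)):
                    best = blocks
            assert got == best


class TestGapsAndAnchors:
    def test_gap_classification_thresholds(self):
        pkts = continuous_stream(4)
        chunks = [rc.Chunk(0, 2, 250.0, 100), rc.Chunk(2, 4, 250.0, 100)]
        for dt, expected in [(5, "short"), (6, "long"), (0, "short")]:
            mod = list(pkts)
            mod[2] = dataclasses.replace(mod[2], timestamp=mod[1].timestamp + dt)
            assert rc.classify_gap(chunks[0], chunks[1], mod) == expected

    def test_single_packet_chunk_anchors_on_its_own_pgt(self):
        pkts = continuous_stream(1)
        chunk = rc.Chunk(0, 1, 250.0, 50)
        assert rc.adjusted_anchor(chunk, pkts) == pkts[0].packet_gen_time

    def test_mean_offset_arithmetic(self):
        # three packets of 50 samples at 250 Hz; packets 2 and 3 report
        # PGT 10 ms and 20 ms late -> anchor = PGT_first + 15 ms
        pkts = continuous_stream(3)
        pkts[1] = dataclasses.replace(pkts[1], packet_gen_time=pkts[1].packet_gen_time + 10)
        pkts[2] = dataclasses.replace(pkts[2], packet_gen_time=pkts[2].packet_gen_time + 20)
        chunk = rc.Chunk(0, 3, 250.0, 150)
        assert rc.adjusted_anchor(chunk, pkts) == pytest.approx(
            pkts[0].packet_gen_time + 15.0
        )

    def test_zero_jitter_anchor_is_true_time(self, clean_session, clean_processed):
        _, truth = clean_session
        td = clean_processed.td
        first_chunk = td.chunks[0]
        # anchor = true time of first packet's last sample
        n_first = truth.packet_log["RawDataTD"][0]["n_samples"]
        assert first_chunk.anchor_time == pytest.approx(
            truth.sample_times["RawDataTD"][n_first - 1], abs=1e-9
        )

    def test_derive_times_direct_evaluation(self):
        chunk = rc.Chunk(0, 1, 250.0, 3)
        times = rc.derive_times_for_chunk(chunk, anchor=1000.0, fs=250.0, c1=3)
        np.testing.assert_allclose(times, [992.0, 996.0, 1000.0])
        assert np.allclose(np.diff(times), 4.0)

    def test_gap_method_rollover_arithmetic(self):
        # ticks 65000 -> 500 crosses the rollover: elapsed 0.1036 s
        prev_end_ms = 5000.0
        nxt = rc.Chunk(0, 1, 250.0, 1)
        pkt = make_packet(0, n=1, tick=500)
        times = rc.derive_times_gap_method(prev_end_ms, 65000, nxt, [pkt], "short")
        assert times[-1] == pytest.approx(5000.0 + 103.6)

    def test_gap_method_refuses_long_gaps(self):
        nxt = rc.Chunk(0, 1, 250.0, 1)
        with pytest.raises(rc.UsageError):
            rc.derive_times_gap_method(0.0, 100, nxt, [make_packet(0, n=1)], "long")


class TestSnapToGrid:
    def test_on_grid_identity(self):
        t = 1000.0 + np.arange(5) * 4.0
        np.testing.assert_array_equal(rc.snap_to_grid(t, 1000.0, 250.0), t)

    def test_nearest_multiple(self):
        t = 1000.0 + 1.4 * 4.0 + np.arange(5) * 4.0
        snapped = rc.snap_to_grid(t, 1000.0, 250.0)
        assert snapped[0] == pytest.approx(1004.0)
        np.testing.assert_allclose(np.diff(snapped), 4.0)

    def test_halfway_tie_rounds_earlier(self):
        t = np.array([1002.0, 1006.0])  # exactly half a 4 ms step off grid
        snapped = rc.snap_to_grid(t, 1000.0, 250.0)
        assert snapped[0] == 1000.0


class TestReconstructStream:
    def test_unimpaired_reconstruction_matches_truth_exactly(
        self, clean_session, clean_processed
    ):
        _, truth = clean_session
        td = clean_processed.td
        np.testing.assert_allclose(
            td.derived_time, truth.sample_times["RawDataTD"], atol=1e-9
        )

    def test_strictly_increasing_and_exact_spacing(self, impaired_processed):
        for name, series in impaired_processed.streams().items():
            assert np.all(np.diff(series.grid_index) >= 1), name
            within = np.diff(series.provenance) == 0
            steps = np.diff(series.grid_index)[within]
            assert np.all(steps == 1), f"{name}: within-chunk spacing not 1/fs"

    def test_grid_congruence_invariant(self, impaired_processed):
        td = impaired_processed.td
        resid = (td.derived_time - td.t_ref) - td.grid_index * td.step_ms
        assert np.max(np.abs(resid)) < 1e-6

    def test_chunk_count_matches_drop_log(self, impaired_session, impaired_processed):
        _, truth = impaired_session
        td = impaired_processed.td
        # boundaries arise from maximal runs of dropped packets (plus any
        # rejections; with 50 ms jitter rejections are not expected)
        dropped = [p["dropped"] for p in truth.packet_log["RawDataTD"]]
        runs = sum(
            1 for i in range(1, len(dropped)) if dropped[i - 1] and not dropped[i]
        )
        interior_runs = runs if not dropped[0] else runs - 1
        assert len(td.rejection_log) == 0
        assert len(td.chunks) == 1 + interior_runs

    def test_reordered_packets_are_restored(self):
        pkts = continuous_stream(10)
        pkts[3], pkts[4] = pkts[4], pkts[3]
        restored = restore_packet_order(pkts)
        assert [p.data_type_sequence for p in restored] == list(range(10))
        assert len(rc.identify_chunks(restored)) == 1

    def test_empty_stream_result_with_warning(self):
        out = rc.reconstruct_stream([])
        assert len(out) == 0 and out.warnings

    def test_drift_bounded_default_vs_accumulating_gap_method(self):
        """With a fast tick clock (100 ppm) and many short gaps, the
        tick-bridging method accumulates error while the default stays
        anchored to PacketGenTime."""
        cfg = rc.SimulationConfig(
            duration=600.0,
            td_fs=250,
            drop_probability=0.08,
            reorder_probability=0.0,
            pgt_jitter_sd=0.0,
            systemtick_drift_ppm=100.0,
            seed=21,
        )
        contents, truth = rc.simulate_session(cfg)
        from rcstream.ingestion import _parse_packets

        pkts = _parse_packets(contents["RawDataTD.json"], "RawDataTD")
        surv = surviving_sample_indices(truth, "RawDataTD")
        truth_t = truth.sample_times["RawDataTD"][surv]

        err_default = np.abs(
            rc.reconstruct_stream(pkts, method="default").derived_time - truth_t
        )
        err_gap = np.abs(
            rc.reconstruct_stream(pkts, method="gap").derived_time - truth_t
        )
        # default: bounded by grid-snap + anchor error; gap method: drift
        # accumulates across every bridged gap
        assert err_default.max() < 50.0
        assert err_gap.max() > err_default.max()
        # and gap-method error grows toward the end of the recording
        last_tenth = err_gap[-len(err_gap) // 10 :]
        first_tenth = err_gap[: len(err_gap) // 10]
        assert last_tenth.mean() > first_tenth.mean()

    def test_gap_method_exact_with_zero_drift(self):
        cfg = rc.SimulationConfig(
            duration=120.0,
            td_fs=250,
            drop_probability=0.05,
            reorder_probability=0.0,
            pgt_jitter_sd=0.0,
            systemtick_drift_ppm=0.0,
            seed=22,
        )
        contents, truth = rc.simulate_session(cfg)
        from rcstream.ingestion import _parse_packets

        pkts = _parse_packets(contents["RawDataTD.json"], "RawDataTD")
        surv = surviving_sample_indices(truth, "RawDataTD")
        truth_t = truth.sample_times["RawDataTD"][surv]
        out = rc.reconstruct_stream(pkts, method="gap")
        # every short gap bridged by ticks lands exactly; long gaps (rare
        # at 2 min) fall back to the anchor path
        assert np.abs(out.derived_time - truth_t).max() < 0.51  # PGT int rounding

    def test_no_tick_cycle_jumps_across_rollovers(self, impaired_processed):
        """A minute-long stream spans >9 tick rollovers; a reconstruction
        slip would show as a +/-6.5536 s discontinuity."""
        td = impaired_processed.td
        d = np.diff(td.derived_time) / 1000.0
        cycle = 6.5536
        assert not np.any(np.abs(np.abs(d) - cycle) < 0.05)
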