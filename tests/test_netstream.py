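"""Datagram data plane: fragmentation, loss, reassembly, bandwidth."""

import io

import numpy as np
import pytest

from drivedaq.netstream import (
    DEFAULT_WORDS_PER_PACKET,
    HEADER_BYTES,
    MAX_DATAGRAM_BYTES,
    DataPacket,
    PacketMode,
    lossy_channel,
    packetize_snapshot,
    packetize_stream,
    read_packet_log,
    reassemble,
    stream_bandwidth,
    write_packet_log,
)
from drivedaq.simulate import SimConfig, generate_session

from conftest import random_sample


@pytest.fixture(scope="module")
def samples():
    cfg = SimConfig(n_chips=2, n_units=2, duration_samples=32, seed=21)
    return list(generate_session(cfg))


class TestPacketization:
    def test_snapshot_fragment_count_is_minimal(self, rng):
        s = random_sample(rng)
        packets = packetize_snapshot(s, words_per_packet=700)
        assert len(packets) == 2  # ceil(1024 / 700)
        assert [p.channel_count for p in packets] == [700, 324]
        assert all(p.sample_index == s.metadata.sample_index for p in packets)
        assert all(p.fragment_total == 2 for p in packets)

    def test_single_channel_stream_is_one_fragment(self, samples):
        packets = packetize_stream(samples[:1], [5])
        assert len(packets) == 1
        assert packets[0].channel_count == 1

    def test_every_packet_fits_one_ethernet_frame(self, samples):
        packets = packetize_snapshot(samples[0]) + packetize_stream(samples, range(100))
        for p in packets:
            assert HEADER_BYTES + 2 * p.channel_count <= MAX_DATAGRAM_BYTES
            assert len(p.pack()) <= MAX_DATAGRAM_BYTES

    def test_oversized_fragment_cap_rejected(self, samples):
        with pytest.raises(ValueError):
            packetize_snapshot(samples[0], words_per_packet=1000)

    def test_empty_channel_selection_rejected(self, samples):
        with pytest.raises(ValueError):
            packetize_stream(samples, [])

    def test_pack_unpack_roundtrip(self, rng):
        p = packetize_snapshot(random_sample(rng))[1]
        q = DataPacket.unpack(p.pack())
        assert q.mode is PacketMode.SNAPSHOT
        assert q.key() == p.key() and np.array_equal(q.payload, p.payload)


class TestLossChannel:
    def test_degenerate_probabilities(self, samples):
        packets = packetize_snapshot(samples[0])
        assert lossy_channel(packets, 0.0, seed=1) == packets
        assert lossy_channel(packets, 1.0, seed=1) == []

    def test_survivor_count_within_binomial_band(self):
        packets = [
            DataPacket(PacketMode.STREAM, 1, 2, i, 0, 0, 1, np.zeros(4, dtype=np.uint16))
            for i in range(10_000)
        ]
        survivors = lossy_channel(packets, 0.1, seed=77)
        sigma = np.sqrt(10_000 * 0.1 * 0.9)
        assert abs(len(survivors) - 9_000) < 4 * sigma

    def test_deterministic_per_seed(self, samples):
        packets = [p for s in samples for p in packetize_snapshot(s)]
        a = lossy_channel(packets, 0.3, seed=5)
        b = lossy_channel(packets, 0.3, seed=5)
        assert [p.key() for p in a] == [p.key() for p in b]


class TestReassembly:
    def test_lossless_snapshot_roundtrip(self, samples):
        packets = [p for s in samples for p in packetize_snapshot(s)]
        data, gaps = reassemble(packets)
        assert not gaps.missing_fragments and not gaps.missing_samples
        for s in samples:
            assert np.array_equal(data[s.metadata.sample_index], s.neural)

    def test_lossless_stream_roundtrip(self, samples):
        ids = [0, 7, 64, 1024]
        packets = packetize_stream(samples, ids)
        data, gaps = reassemble(packets)
        assert not gaps.missing_fragments and not gaps.missing_samples
        for s in samples:
            expect = [s.neural[0], s.neural[7], s.neural[64], s.aux[0]]
            assert data[s.metadata.sample_index].tolist() == expect

    def test_out_of_order_delivery_tolerated(self, samples):
        packets = [p for s in samples for p in packetize_snapshot(s)]
        data, gaps = reassemble(packets[::-1])
        assert not gaps.missing_fragments
        assert sorted(data) == [s.metadata.sample_index for s in samples]

    def test_dropped_fragment_enumerated_exactly(self, samples):
        packets = [p for s in samples[:8] for p in packetize_snapshot(s)]
        victim = packets[5]  # sample 2, fragment 1
        survivors = [p for p in packets if p is not victim]
        data, gaps = reassemble(survivors)
        assert gaps.missing_fragments == [(victim.sample_index, victim.fragment_ordinal)]
        # surviving fragment of the damaged sample is still placed
        s = samples[victim.sample_index]
        assert np.array_equal(data[victim.sample_index][:700], s.neural[:700])

    def test_fully_dropped_sample_reported_as_missing(self, samples):
        packets = [p for s in samples[:5] for p in packetize_snapshot(s)]
        survivors = [p for p in packets if p.sample_index != 2]
        _, gaps = reassemble(survivors)
        assert gaps.missing_samples == [2]

    def test_duplicates_are_idempotent(self, samples):
        packets = [p for s in samples[:4] for p in packetize_snapshot(s)]
        data_a, _ = reassemble(packets)
        data_b, gaps = reassemble(packets + packets[:3])
        assert gaps.duplicates == 3
        assert all(np.array_equal(data_a[k], data_b[k]) for k in data_a)

    def test_gap_count_matches_disjoint_drop_count(self, samples):
        packets = [p for s in samples for p in packetize_snapshot(s)]
        rng = np.random.default_rng(4)
        # keep the first and last samples intact so wholly-missing samples
        # fall inside the observed index range
        drop = set((2 + rng.choice(len(packets) - 4, size=10, replace=False)).tolist())
        survivors = [p for i, p in enumerate(packets) if i not in drop]
        _, gaps = reassemble(survivors)
        assert gaps.total_missing(fragments_per_sample=2) == 10


class TestBandwidth:
    def test_full_array_payload_rate(self):
        # 1024 channels x 30 kS/s x 16 bit = 491.52 Mb/s of payload
        payload_bits = 1024 * 30_000 * 16
        assert payload_bits == 491_520_000
        total = stream_bandwidth(1024)
        assert total > payload_bits
        overhead = total - payload_bits
        assert overhead == 2 * HEADER_BYTES * 8 * 30_000  # two fragments/sample
        assert total < 1e9  # fits gigabit

    def test_single_channel_far_below_gigabit(self):
        assert stream_bandwidth(1) < 1e7

    def test_monotone_in_channel_count(self):
        rates = [stream_bandwidth(n) for n in range(0, 1025, 64)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))


class TestPacketLog:
    def test_log_roundtrip(self, samples):
        packets = [p for s in samples[:6] for p in packetize_snapshot(s)]
        buf = io.BytesIO()
        assert write_packet_log(packets, buf) == len(packets)
        buf.seek(0)
        back = read_packet_log(buf)
        assert [p.key() for p in back] == [p.key() for p in packets]
        assert all(np.array_equal(a.payload, b.payload) for a, b in zip(back, packets))
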