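"""Fountain outer code: chunking, seeded selection, GF(2) decoding."""

import itertools
import struct
import zlib

import numpy as np
import pytest
from scipy import stats

from dnacodec import FountainConfig, Packet, UndecodableError
from dnacodec.fountain import (
    FountainError,
    _gf2_solve,
    decode_packets,
    degree_point_mass,
    encode_packets,
    gf2_rank,
    packet_from_wire,
    packet_to_wire,
    parse_header,
    reassemble,
    robust_soliton,
    select_chunks,
    split_file,
)


def make_packets(chunks, seeds, config, metrics=None):
    packets = encode_packets(chunks, seeds, config)
    if metrics is not None:
        for p, mval in zip(packets, metrics):
            p.final_metric = mval
    return packets


class TestSplitAndHeader:
    def test_chunk_count_and_padding(self):
        config = FountainConfig(chunk_size=12, use_header=True)
        chunks = split_file(bytes(range(30)), config, "x.bin")
        assert len(chunks) == 4  # header + ceil(30/12) = 3 data chunks
        assert chunks[-1] == bytes(range(24, 30)) + bytes(6)
        padding, crc, name = parse_header(chunks[0])
        assert padding == 6
        assert name == "x.bin"
        assert crc == zlib.crc32(bytes(range(30)))

    def test_reassemble_roundtrip(self):
        config = FountainConfig(chunk_size=16)
        data = b"the quick brown fox"
        chunks = split_file(data, config, "fox.txt")
        back, name = reassemble(chunks, config)
        assert back == data and name == "fox.txt"

    def test_filename_too_long_fatal(self):
        with pytest.raises(FountainError, match="does not fit"):
            split_file(b"x", FountainConfig(chunk_size=8), "a" * 30)


class TestSelectChunks:
    def test_deterministic(self):
        probs = robust_soliton(40)
        assert select_chunks(99, 40, probs) == select_chunks(99, 40, probs)

    def test_point_mass_degree_one(self):
        probs = degree_point_mass(10, 1)
        for seed in range(50):
            assert len(select_chunks(seed, 10, probs)) == 1

    def test_indices_distinct_and_in_range(self):
        probs = robust_soliton(12)
        for seed in range(200):
            idx = select_chunks(seed, 12, probs)
            assert len(set(idx)) == len(idx)
            assert all(0 <= i < 12 for i in idx)

    def test_degree_histogram_matches_distribution(self):
        k = 15
        probs = robust_soliton(k)
        observed = np.zeros(k)
        n = 10_000
        for seed in range(n):
            observed[len(select_chunks(seed, k, probs)) - 1] += 1
        # merge degrees with tiny expectation into one tail bin
        expected = probs * n
        big = expected >= 5
        obs, exp = observed[big], expected[big]
        if (~big).any():
            obs = np.append(obs, observed[~big].sum())
            exp = np.append(exp, expected[~big].sum())
        res = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert res.pvalue > 0.01


class TestEncodePackets:
    def test_single_chunk_payload_identity(self):
        config = FountainConfig(chunk_size=4, use_header=False)
        chunks = split_file(b"abcd", config)
        for p in encode_packets(chunks, [0, 1, 7], config):
            assert p.payload == b"abcd"

    def test_xor_involution(self):
        config = FountainConfig(chunk_size=2, use_header=False,
                                degree_probs=(0.0, 1.0))
        chunks = [b"ab", b"cd"]
        (p,) = encode_packets(chunks, [3], config)
        assert p.indices == (0, 1)
        xor = bytes(a ^ b for a, b in zip(*chunks))
        assert p.payload == xor
        assert bytes(a ^ b for a, b in zip(p.payload, chunks[0])) == chunks[1]

    def test_seed_collision_fatal(self):
        config = FountainConfig(chunk_size=2, use_header=False)
        with pytest.raises(FountainError, match="seed collision"):
            encode_packets([b"ab"], [5, 5], config)

    @pytest.mark.parametrize("crc_bytes", [2, 4])
    def test_wire_roundtrip(self, crc_bytes):
        config = FountainConfig(chunk_size=3, use_header=False,
                                use_packet_crc=True,
                                packet_crc_bytes=crc_bytes)
        (p,) = encode_packets([b"xyz"], [42], config)
        wire = packet_to_wire(p, config)
        assert len(wire) == 4 + 3 + crc_bytes
        back = packet_from_wire(wire, config, final_metric=-1.5)
        assert back.seed == 42 and back.payload == b"xyz"
        assert back.crc_ok(crc_bytes)
        corrupt = bytearray(wire)
        corrupt[5] ^= 1
        assert not packet_from_wire(bytes(corrupt), config).crc_ok(crc_bytes)


class TestDecodePackets:
    def config(self, **kw):
        kw.setdefault("chunk_size", 8)  # header needs 6 fixed bytes + name
        kw.setdefault("use_header", True)
        return FountainConfig(**kw)

    def test_bare_chunks_reconstruct(self):
        config = self.config()
        data = bytes(range(16))
        chunks = split_file(data, config, "f")
        k = len(chunks)
        config2 = self.config(degree_probs=(1.0,))
        # degree-1 packets cannot cover all chunks from few seeds; use many
        packets = make_packets(chunks, range(60), config2)
        out, report = decode_packets(packets, k, config2)
        assert out == data
        assert report["rank"] == k

    def test_two_packet_elimination(self):
        # p1 = c0, p2 = c0 xor c1 -> c1 = p1 xor p2
        masks = [0b01, 0b11]
        payloads = [np.frombuffer(b"ab", dtype=np.uint8),
                    np.frombuffer(bytes(a ^ b for a, b in zip(b"ab", b"cd")),
                                  dtype=np.uint8)]
        chunks, used = _gf2_solve(masks, payloads, 2)
        assert chunks == [b"ab", b"cd"]
        assert used == [0, 1]

    def test_rank_deficit_reported(self):
        config = self.config(degree_probs=(1.0,))
        chunks = split_file(bytes(16), config, "f")
        packets = make_packets(chunks, [0], config)
        with pytest.raises(UndecodableError, match="need more packets") as ei:
            decode_packets(packets, len(chunks), config)
        assert ei.value.rank < ei.value.k

    def test_success_iff_rank_k(self, rng):
        """Decoder outcome must match an independent GF(2) rank computation."""
        config = self.config(use_header=False, chunk_size=2)
        k = 6
        chunks = [bytes(rng.integers(0, 256, 2, dtype=np.uint8)) for _ in range(k)]
        probs = robust_soliton(k)
        for trial in range(40):
            nsel = int(rng.integers(3, 10))
            seeds = list(rng.choice(1000, nsel, replace=False))
            packets = make_packets(chunks, [int(s) for s in seeds], config)
            # independent dense-matrix rank oracle
            mat = np.zeros((nsel, k), dtype=np.uint8)
            for i, p in enumerate(packets):
                mat[i, list(p.indices)] = 1
            rank = 0
            mat = mat.copy()
            for col in range(k):
                piv = next((r for r in range(rank, nsel) if mat[r, col]), None)
                if piv is None:
                    continue
                mat[[rank, piv]] = mat[[piv, rank]]
                for r in range(nsel):
                    if r != rank and mat[r, col]:
                        mat[r] ^= mat[rank]
                rank += 1
            if rank == k:
                out, _ = decode_packets(packets, k, config)
                assert out == b"".join(chunks)
            else:
                with pytest.raises(UndecodableError):
                    decode_packets(packets, k, config)

    def test_erasure_tolerance(self, rng):
        config = self.config()
        data = bytes(rng.integers(0, 256, 40, dtype=np.uint8))
        chunks = split_file(data, config, "f")
        k = len(chunks)
        packets = make_packets(chunks, range(3 * k), config)
        out_full, _ = decode_packets(packets, k, config)
        assert out_full == data
        for _ in range(10):
            keep = [p for p in packets if rng.random() > 0.3]
            if gf2_rank([sum(1 << i for i in p.indices) for p in keep], k) < k:
                continue
            out, _ = decode_packets(keep, k, config)
            assert out == data

    def test_overhead_1_3_suffices(self, rng):
        """1.3k random packets over k=20 chunks decode in >=95% of trials."""
        config = self.config(use_header=False, chunk_size=1)
        k = 20
        chunks = [bytes([i]) for i in range(k)]
        good = 0
        trials = 100
        for t in range(trials):
            seeds = [int(s) for s in
                     rng.choice(100_000, size=26, replace=False)]
            packets = make_packets(chunks, seeds, config)
            try:
                out, _ = decode_packets(packets, k, config)
                good += out == bytes(range(k))
            except UndecodableError:
                pass
        assert good >= 95

    def test_metric_ordering_excludes_worst_corrupt_packet(self, rng):
        config = self.config(use_header=False, chunk_size=2)
        k = 5
        chunks = [bytes(rng.integers(0, 256, 2, dtype=np.uint8)) for _ in range(k)]
        packets = make_packets(chunks, range(40), config,
                               metrics=[float(40 - i) for i in range(40)])
        clean = packets[:-1]
        assert gf2_rank([sum(1 << i for i in p.indices) for p in clean], k) == k
        bad = packets[-1]
        bad.payload = bytes(x ^ 0xFF for x in bad.payload)
        bad.final_metric = -999.0
        out, report = decode_packets(packets, k, config)
        assert out == b"".join(chunks)
        assert bad.seed not in report["packets_used"]

    def test_corrupt_packet_recovered_via_checksum_fallback(self, rng):
        """No packet CRC: the file-wide checksum fallback must find a clean subset."""
        config = self.config()
        data = bytes(rng.integers(0, 256, 48, dtype=np.uint8))
        chunks = split_file(data, config, "f")
        k = len(chunks)
        packets = make_packets(chunks, range(k + 3), config)
        # corrupt the packet with the *best* metric so first-pass GE uses it
        for i, p in enumerate(packets):
            p.final_metric = 0.0
        packets[0].final_metric = 10.0
        packets[0].payload = bytes(x ^ 0x55 for x in packets[0].payload)
        # oracle: some clean full-rank subset must exist
        masks = [sum(1 << i for i in p.indices) for p in packets[1:]]
        assert gf2_rank(masks, k) == k
        out, report = decode_packets(packets, k, config)
        assert out == data
        assert report["fallback_attempts"] >= 1

    def test_exhaustive_subset_oracle_small_k(self, rng):
        """Fallback finds a solution whenever any clean subset solves (k<=8)."""
        config = self.config()
        data = bytes(rng.integers(0, 256, 40, dtype=np.uint8))
        chunks = split_file(data, config, "f")
        k = len(chunks)
        packets = make_packets(chunks, range(k + 4), config)
        corrupt_idx = {1, 4}
        for i in corrupt_idx:
            packets[i].payload = bytes(x ^ 0x3C for x in packets[i].payload)
        clean = [p for i, p in enumerate(packets) if i not in corrupt_idx]
        solvable = any(
            gf2_rank([sum(1 << i for i in p.indices) for p in sub], k) == k
            for r in range(k, len(clean) + 1)
            for sub in itertools.combinations(clean, r)
        )
        config_big = self.config(fallback_budget=500)
        if solvable:
            out, _ = decode_packets(packets, k, config_big)
            assert out == data
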