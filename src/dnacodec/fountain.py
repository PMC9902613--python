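"""Seeded fountain outer code with metric-ordered GF(2) decoding.

Files are split into fixed-size chunks (optionally preceded by a header
chunk carrying the filename, the padding length of the last chunk, and a
file-wide CRC-32).  Each packet is the XOR of a seed-determined chunk
subset: the seed drives a pinned 32-bit generator (numpy PCG64) that first
samples a degree from the configured distribution (robust soliton by
default) and then draws that many distinct chunk indices, so the decoder
reconstructs the selection from the seed alone.

Decoding solves the GF(2) selection system by online Gaussian elimination
with metric-ordered pivoting: packets are offered best inner-decoder metric
first, and a packet is only drawn into the solution when it is linearly
independent of the better packets already used.  Any (1+eps)*k packets whose
selection matrix has rank k suffice.  After reassembly the file-wide
checksum is verified; on mismatch the decoder retries with reordered packet
subsets drawn from the over-complete set, which recovers the file whenever a
full-rank subset avoiding the corrupt packets exists.
"""

from __future__ import annotations

import math
import struct
import zlib
from dataclasses import dataclass

import numpy as np

HEADER_FIXED = struct.Struct(">HI")  # u16 padding, u32 file CRC-32


class FountainError(ValueError):
    pass


class UndecodableError(FountainError):
    def __init__(self, message: str, rank: int | None = None, k: int | None = None):
        super().__init__(message)
        self.rank = rank
        self.k = k


# ---------------------------------------------------------------------------
# Degree distributions
# ---------------------------------------------------------------------------

def robust_soliton(k: int, c: float = 0.1, delta: float = 0.05) -> np.ndarray:
    """Robust soliton probabilities over degrees 1..k."""
    if k < 1:
        raise FountainError("need at least one chunk")
    if k == 1:
        return np.array([1.0])
    rho = np.zeros(k)
    rho[0] = 1.0 / k
    d = np.arange(2, k + 1)
    rho[1:] = 1.0 / (d * (d - 1.0))
    R = c * math.log(k / delta) * math.sqrt(k)
    tau = np.zeros(k)
    spike = int(k / R) if R > 0 else k
    spike = min(max(spike, 1), k)
    for i in range(1, spike):
        tau[i - 1] = R / (i * k)
    tau[spike - 1] = R * math.log(R / delta) / k if R > delta else 0.0
    probs = rho + tau
    return probs / probs.sum()


def degree_point_mass(k: int, degree: int = 1) -> np.ndarray:
    """Degenerate distribution putting all mass on one degree (for tests/repeats)."""
    probs = np.zeros(k)
    probs[degree - 1] = 1.0
    return probs


@dataclass(frozen=True)
class FountainConfig:
    chunk_size: int = 16
    overhead: float = 0.5           # epsilon: fraction of extra packets
    use_header: bool = True
    use_packet_crc: bool = False
    packet_crc_bytes: int = 2       # checksum width when enabled (2 or 4)
    soliton_c: float = 0.1
    soliton_delta: float = 0.05
    degree_probs: tuple | None = None   # explicit distribution override
    fallback_budget: int = 50
    fallback_seed: int = 0

    def __post_init__(self):
        if self.chunk_size < 1:
            raise FountainError("chunk_size must be >= 1")
        if self.overhead < 0:
            raise FountainError("overhead epsilon must be >= 0")
        if self.packet_crc_bytes not in (2, 4):
            raise FountainError("packet_crc_bytes must be 2 or 4")

    def packet_crc(self, seed: int, payload: bytes) -> int:
        crc = zlib.crc32(struct.pack(">I", seed) + payload)
        return crc & 0xFFFF if self.packet_crc_bytes == 2 else crc

    def degree_distribution(self, k: int) -> np.ndarray:
        if self.degree_probs is not None:
            probs = np.asarray(self.degree_probs, dtype=float)
            if len(probs) > k:
                probs = probs[:k].copy()
            elif len(probs) < k:
                probs = np.concatenate([probs, np.zeros(k - len(probs))])
            if probs.sum() <= 0:
                raise FountainError("degree distribution has no mass on degrees <= k")
            return probs / probs.sum()
        return robust_soliton(k, self.soliton_c, self.soliton_delta)


@dataclass
class Packet:
    """A seeded XOR of chunks, plus the inner decoder's confidence after decode."""

    seed: int
    payload: bytes
    degree: int = 0
    indices: tuple[int, ...] = ()
    packet_crc: int | None = None
    final_metric: float | None = None

    def crc_ok(self, crc_bytes: int = 4) -> bool:
        if self.packet_crc is None:
            return True
        crc = zlib.crc32(struct.pack(">I", self.seed) + self.payload)
        if crc_bytes == 2:
            crc &= 0xFFFF
        return self.packet_crc == crc


# ---------------------------------------------------------------------------
# Chunking and the header chunk
# ---------------------------------------------------------------------------

def build_header(filename: str, padding: int, file_crc: int, chunk_size: int) -> bytes:
    name = filename.encode("utf-8") + b"\0"
    raw = HEADER_FIXED.pack(padding, file_crc) + name
    if len(raw) > chunk_size:
        raise FountainError(
            f"filename {filename!r} does not fit a {chunk_size}-byte header chunk"
        )
    return raw + bytes(chunk_size - len(raw))


def parse_header(chunk: bytes) -> tuple[int, int, str]:
    """Returns (padding, file_crc32, filename)."""
    padding, file_crc = HEADER_FIXED.unpack_from(chunk)
    rest = chunk[HEADER_FIXED.size:]
    end = rest.find(b"\0")
    if end == -1:
        raise FountainError("malformed header chunk: unterminated filename")
    return padding, file_crc, rest[:end].decode("utf-8")


def split_file(data: bytes, config: FountainConfig,
               filename: str = "file") -> list[bytes]:
    """Split into equal chunks (last one zero-padded), header chunk first if enabled."""
    cs = config.chunk_size
    nchunks = -(-len(data) // cs)
    chunks = []
    for i in range(nchunks):
        block = data[i * cs : (i + 1) * cs]
        chunks.append(block + bytes(cs - len(block)))
    padding = nchunks * cs - len(data)
    if config.use_header:
        header = build_header(filename, padding, zlib.crc32(data), cs)
        return [header] + chunks
    return chunks


def reassemble(chunks: list[bytes], config: FountainConfig) -> tuple[bytes, str]:
    """Inverse of `split_file` (header layout required); verifies the file CRC."""
    if not config.use_header:
        raise FountainError("reassemble needs the header chunk layout")
    padding, file_crc, filename = parse_header(chunks[0])
    body = b"".join(chunks[1:])
    data = body[: len(body) - padding] if padding else body
    if zlib.crc32(data) != file_crc:
        raise FountainError("file-wide checksum mismatch")
    return data, filename


# ---------------------------------------------------------------------------
# Seeded chunk selection and packet encoding
# ---------------------------------------------------------------------------

def select_chunks(seed: int, num_chunks: int, degree_probs: np.ndarray) -> tuple[int, ...]:
    """Deterministic seed -> (degree, chunk index set) sampling.

    The same seed always yields the same sorted index tuple, on any platform,
    because the generator (PCG64) and the draw order are pinned.
    """
    if num_chunks < 1:
        raise FountainError("num_chunks must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    cdf = np.cumsum(degree_probs)
    degree = int(np.searchsorted(cdf, rng.random(), side="right")) + 1
    degree = min(degree, num_chunks)
    idx = rng.choice(num_chunks, size=degree, replace=False)
    return tuple(sorted(int(i) for i in idx))


def _xor_chunks(chunks: list[bytes], indices: tuple[int, ...]) -> bytes:
    acc = np.zeros(len(chunks[0]), dtype=np.uint8)
    for i in indices:
        acc ^= np.frombuffer(chunks[i], dtype=np.uint8)
    return acc.tobytes()


def encode_packets(chunks: list[bytes], seeds, config: FountainConfig) -> list[Packet]:
    """Generate one packet per seed; any number of packets from a seed range."""
    k = len(chunks)
    if k == 0:
        raise FountainError("no chunks to encode")
    probs = config.degree_distribution(k)
    packets = []
    seen = set()
    for seed in seeds:
        if seed in seen:
            raise FountainError(f"seed collision within one encoding: {seed}")
        seen.add(seed)
        indices = select_chunks(seed, k, probs)
        payload = _xor_chunks(chunks, indices)
        crc = config.packet_crc(seed, payload) if config.use_packet_crc else None
        packets.append(Packet(seed, payload, len(indices), indices, crc))
    return packets


def packet_to_wire(packet: Packet, config: FountainConfig) -> bytes:
    wire = struct.pack(">I", packet.seed) + packet.payload
    if config.use_packet_crc:
        fmt = ">H" if config.packet_crc_bytes == 2 else ">I"
        wire += struct.pack(fmt, config.packet_crc(packet.seed, packet.payload))
    return wire


def packet_from_wire(wire: bytes, config: FountainConfig,
                     final_metric: float | None = None) -> Packet:
    base = 4 + config.chunk_size
    expect = base + (config.packet_crc_bytes if config.use_packet_crc else 0)
    if len(wire) != expect:
        raise FountainError(f"packet wire length {len(wire)}, expected {expect}")
    (seed,) = struct.unpack_from(">I", wire)
    payload = wire[4:base]
    crc = None
    if config.use_packet_crc:
        fmt = ">H" if config.packet_crc_bytes == 2 else ">I"
        (crc,) = struct.unpack_from(fmt, wire, base)
    return Packet(seed, payload, packet_crc=crc, final_metric=final_metric)


def wire_length(config: FountainConfig) -> int:
    return 4 + config.chunk_size + (config.packet_crc_bytes
                                    if config.use_packet_crc else 0)


# ---------------------------------------------------------------------------
# GF(2) elimination
# ---------------------------------------------------------------------------

def _gf2_solve(masks: list[int], payloads: list[np.ndarray], k: int):
    """Online GF(2) elimination, rows offered in the given (best-first) order.

    Returns (chunks, used_row_positions) on rank k, else (None, rank).
    Chunk index i maps to bit i; a row becomes a pivot on the highest set bit
    of its residual after reduction by earlier pivots.
    """
    pivots: dict[int, tuple[int, np.ndarray, int]] = {}
    for pos, (mask, data) in enumerate(zip(masks, payloads)):
        m = mask
        d = data
        copied = False
        while m:
            col = m.bit_length() - 1
            if col not in pivots:
                pivots[col] = (m, d if copied else d.copy(), pos)
                break
            pmask, pdata, _ = pivots[col]
            m ^= pmask
            if not copied:
                d = d ^ pdata
                copied = True
            else:
                d ^= pdata
        if len(pivots) == k:
            break
    if len(pivots) < k:
        return None, len(pivots)
    chunks: list[np.ndarray | None] = [None] * k
    for col in range(k):
        m, d, _ = pivots[col]
        acc = d.copy()
        m &= ~(1 << col)
        while m:
            j = m.bit_length() - 1
            acc ^= chunks[j]
            m &= ~(1 << j)
        chunks[col] = acc
    used = sorted(p for _, _, p in pivots.values())
    return [c.tobytes() for c in chunks], used


def gf2_rank(masks: list[int], k: int) -> int:
    pivots: dict[int, int] = {}
    for mask in masks:
        m = mask
        while m:
            col = m.bit_length() - 1
            if col not in pivots:
                pivots[col] = m
                break
            m ^= pivots[col]
    return len(pivots)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode_packets(packets: list[Packet], num_chunks: int,
                   config: FountainConfig) -> tuple[bytes, dict]:
    """Recover the file from any sufficient packet subset.

    Packets are ordered by inner-decoder final metric (best first; absent
    metrics rank equal and last), packets failing their own checksum are
    discarded, and the GF(2) system is solved preferring the best packets.
    If the recovered file fails the file-wide checksum, over-complete
    fallback reordering retries with packet subsets until the budget is
    exhausted.  Raises `UndecodableError` with the rank deficit if no
    sufficient subset exists.
    """
    k = num_chunks
    report: dict = {"k": k, "packets_seen": len(packets), "discarded_crc": 0,
                    "fallback_attempts": 0}

    alive = []
    for p in packets:
        if config.use_packet_crc and not p.crc_ok(config.packet_crc_bytes):
            report["discarded_crc"] += 1
            continue
        alive.append(p)
    # dedupe by seed, keeping the best-metric copy
    by_seed: dict[int, Packet] = {}
    for p in alive:
        old = by_seed.get(p.seed)
        if old is None or (p.final_metric or 0.0) > (old.final_metric or 0.0):
            by_seed[p.seed] = p
    alive = sorted(by_seed.values(),
                   key=lambda p: -(p.final_metric if p.final_metric is not None else 0.0))
    report["packets_usable"] = len(alive)

    probs = config.degree_distribution(k)
    masks = []
    payloads = []
    for p in alive:
        indices = p.indices or select_chunks(p.seed, k, probs)
        mask = 0
        for i in indices:
            mask |= 1 << i
        masks.append(mask)
        payloads.append(np.frombuffer(p.payload, dtype=np.uint8))

    def attempt(order: list[int]):
        chunks, used = _gf2_solve([masks[i] for i in order],
                                  [payloads[i] for i in order], k)
        if chunks is None:
            return None, used
        if not config.use_header:
            return b"".join(chunks), [order[i] for i in used]
        try:
            data, filename = reassemble(chunks, config)
        except FountainError:
            return None, None  # checksum mismatch: caller retries
        report["filename"] = filename
        return data, [order[i] for i in used]

    base_order = list(range(len(alive)))
    rank = gf2_rank(masks, k)
    report["rank"] = rank
    if rank < k:
        raise UndecodableError(
            f"undecodable: need more packets (rank {rank} of {k})", rank, k
        )

    data, used = attempt(base_order)
    if data is not None:
        report["packets_used"] = [alive[i].seed for i in used]
        report["success"] = True
        return data, report

    # Fallback: the rank is sufficient but the checksum failed, so some used
    # packet is corrupt.  Greedily drop one candidate at a time (worst metric
    # first), then try seeded random subsets from the over-complete pool.
    rng = np.random.Generator(np.random.PCG64(config.fallback_seed))
    budget = config.fallback_budget
    for drop in reversed(base_order):
        if budget <= 0:
            break
        order = [i for i in base_order if i != drop]
        report["fallback_attempts"] += 1
        budget -= 1
        data, used = attempt(order)
        if data is not None:
            report["packets_used"] = [alive[i].seed for i in used]
            report["success"] = True
            return data, report
    while budget > 0:
        keep = rng.random(len(alive)) > 0.25
        order = [i for i in base_order if keep[i]]
        report["fallback_attempts"] += 1
        budget -= 1
        data, used = attempt(order)
        if data is not None:
            report["packets_used"] = [alive[i].seed for i in used]
            report["success"] = True
            return data, report
    raise UndecodableError(
        "undecodable: checksum mismatch persists after fallback reordering",
        rank, k,
    )
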