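"""End-to-end orchestration: file -> packets -> framed strands and back.

Encoding: the file is split into chunks (with a header chunk), fountain
packets are generated from sequential seeds, each packet's wire bytes
([u32 seed][chunk payload][optional u32 CRC]) are framed with periodic 8-bit
CRCs and expanded onto DNA by the arithmetic modulator.  The encoder checks
that the emitted packet set spans all chunks over GF(2) and appends extra
seeds if it does not, so a clean channel always decodes.

Decoding: every strand is decoded independently by the sequential stack
decoder (failures become erasures), the surviving packets are handed to the
fountain decoder ordered by final metric, and the file is reassembled and
checksum-verified.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import fountain
from .codebook import reverse_complement
from .fountain import FountainConfig, Packet
from .inner import frame_payload, framed_length, modulate
from .model import TransitionModel
from .stack import ChannelPriors, DecoderConfig, decode_packet

#: fixed keystream seed for payload whitening (see _whiten)
_WHITEN_SEED = 0x5EED
_whiten_cache: dict[int, np.ndarray] = {}


def _whiten(wire: bytes) -> bytes:
    """XOR the packet wire with a fixed pseudo-random keystream (self-inverse).

    Packet wires start with small sequential seeds, and low-entropy bytes
    make the arithmetic modulator walk the low end of every interval —
    visibly repetitive strand prefixes shared by all packets.  Whitening
    restores the uniform-bit assumption (and the flat base composition that
    follows from it) without touching either code: the keystream is pinned,
    so encoder and decoder agree bit-exactly.
    """
    n = len(wire)
    mask = _whiten_cache.get(n)
    if mask is None:
        gen = np.random.Generator(np.random.PCG64(_WHITEN_SEED))
        mask = gen.integers(0, 256, n, dtype=np.uint8)
        _whiten_cache[n] = mask
    return (np.frombuffer(wire, dtype=np.uint8) ^ mask).tobytes()


@dataclass(frozen=True)
class CodecParams:
    """Everything the pipeline needs besides the model itself."""

    fountain: FountainConfig = field(default_factory=FountainConfig)
    step_size: int = 4
    stack_size: int = 2000
    pop_count: int = 1
    # subtree penalty off by default: end-to-end it mostly demotes the
    # truth-containing subtree, and disabling it enables state merging
    penalty: float = 0.0
    max_iterations: int = 200_000
    priors: ChannelPriors = field(default_factory=ChannelPriors)
    filename: str = "file"
    first_seed: int = 1
    #: iteration caps for progressive decoding: every strand is tried at the
    #: first cap, and only while the fountain still lacks packets are the
    #: leftovers escalated to later caps (ending at max_iterations).  The
    #: fountain decode is attempted as soon as enough packets accumulate, so
    #: easy channels never pay the full search budget.
    budget_schedule: tuple[int, ...] = (30_000,)
    #: retry failed strands in the reverse-complement orientation
    revcomp_retry: bool = False

    def decoder_config(self, expected_bytes: int) -> DecoderConfig:
        return DecoderConfig(
            expected_bytes=expected_bytes,
            s=self.step_size,
            M=self.stack_size,
            pop_count=self.pop_count,
            penalty=self.penalty,
            max_iterations=self.max_iterations,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def encode_file(data: bytes, model: TransitionModel,
                params: CodecParams) -> tuple[list[tuple[int, str]], dict]:
    """Encode a file into DNA strands; returns ([(seed, strand)], manifest)."""
    fc = params.fountain
    chunks = fountain.split_file(data, fc, params.filename)
    k = len(chunks)
    npackets = max(k, math.ceil((1.0 + fc.overhead) * k))
    probs = fc.degree_distribution(k)
    seeds = list(range(params.first_seed, params.first_seed + npackets))
    # top up seeds until the selection matrix has full rank over GF(2)
    masks = []
    for seed in seeds:
        mask = 0
        for i in fountain.select_chunks(seed, k, probs):
            mask |= 1 << i
        masks.append(mask)
    next_seed = seeds[-1] + 1
    while fountain.gf2_rank(masks, k) < k and len(seeds) < 10 * k + 16:
        mask = 0
        for i in fountain.select_chunks(next_seed, k, probs):
            mask |= 1 << i
        masks.append(mask)
        seeds.append(next_seed)
        next_seed += 1

    packets = fountain.encode_packets(chunks, seeds, fc)
    records = []
    for p in packets:
        wire = fountain.packet_to_wire(p, fc)
        framed = frame_payload(_whiten(wire), params.step_size)
        records.append((p.seed, modulate(framed, model)))

    manifest = {
        "first_seed": params.first_seed,
        "filename": params.filename,
        "file_bytes": len(data),
        "num_chunks": k,
        "chunk_size": fc.chunk_size,
        "num_packets": len(seeds),
        "wire_bytes": fountain.wire_length(fc),
        "framed_bytes": framed_length(fountain.wire_length(fc), params.step_size),
        "step_size": params.step_size,
        "use_header": fc.use_header,
        "use_packet_crc": fc.use_packet_crc,
        "config_digest": params.digest(),
    }
    return records, manifest


def decode_strands(strands: list[str], model: TransitionModel,
                   params: CodecParams, manifest: dict) -> tuple[bytes, dict]:
    """Decode noisy strands back to the original file.

    Per-strand failures are erasures; the fountain code recovers the file as
    long as enough strands decode to a full-rank packet set.
    """
    fc = params.fountain
    wire_len = manifest["wire_bytes"]
    k = manifest["num_chunks"]
    lo = manifest.get("first_seed", 1)
    hi = lo + manifest["num_packets"]
    packets: list[Packet] = []
    strand_reports = []
    caps = [c for c in params.budget_schedule if c < params.max_iterations]
    caps.append(params.max_iterations)

    def attempt():
        if len(packets) < k:
            return None
        try:
            return fountain.decode_packets(packets, k, fc)
        except fountain.UndecodableError:
            return None

    pending = list(enumerate(strands))
    outcome = None
    skipped = 0
    for cap in caps:
        if outcome is not None:
            break
        dconfig = params.decoder_config(wire_len)
        dconfig.max_iterations = cap
        leftovers = []
        since_attempt = 0
        for idx, (i, strand) in enumerate(pending):
            result = decode_packet(strand, model, params.priors, dconfig)
            if not result.success and params.revcomp_retry:
                result = decode_packet(reverse_complement(strand), model,
                                       params.priors, dconfig)
            if result.success:
                packet = fountain.packet_from_wire(_whiten(result.payload), fc,
                                                   result.final_metric)
                # a seed outside the encoder's range marks a corrupt decode
                if lo <= packet.seed < hi:
                    packets.append(packet)
                    since_attempt += 1
                strand_reports.append({
                    "strand": i, "success": True,
                    "final_metric": result.final_metric,
                    "iterations": result.iterations,
                })
            else:
                leftovers.append((i, strand))
            if since_attempt >= 10:
                since_attempt = 0
                outcome = attempt()
                if outcome is not None:
                    skipped += len(pending) - idx - 1
                    break
        pending = leftovers
        if outcome is None:
            outcome = attempt()
    erasures = len(pending)
    if outcome is None:
        data, report = fountain.decode_packets(packets, k, fc)
    else:
        data, report = outcome
    for i, _ in pending:
        strand_reports.append({"strand": i, "success": False,
                               "final_metric": None, "iterations": None})
    report["erasures"] = erasures
    report["skipped"] = skipped
    report["strands"] = sorted(strand_reports, key=lambda r: r["strand"])
    return data, report
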