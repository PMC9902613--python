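"""Arithmetic-coding modulation of framed payloads onto constrained DNA.

The modulator runs an arithmetic *decoder* over the payload bitstream: the
bits are treated as the compressed representation of a DNA string, and each
step selects the base whose model subinterval contains the current code
value.  The exact inverse (the error-free fast path) is an arithmetic
*encoder* over the bases, which reproduces the payload bits.  Because every
interval partition follows the codebook model, the emitted strand adheres to
the codebook's constraints by construction.

Payloads are framed with 8-bit CRC synchronization markers: one CRC after
every ``s`` payload bytes plus a final CRC covering the trailing (possibly
short) block.  The markers let the sequential decoder prune wrong hypotheses
and resynchronize after insertions and deletions.

The integer engine uses a 32-bit coding interval with standard E1/E2
renormalization and E3 straddle (pending-bit) handling; subintervals are laid
out in fixed A, C, G, T order.  An exact rational interval engine over an
arbitrary alphabet (`arith_interval`) is provided as an independent
verification oracle.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

from .codebook import BASES, BASE_INDEX
from .model import TransitionModel

PRECISION = 32
FULL = 1 << PRECISION
HALF = FULL >> 1
QUARTER = FULL >> 2
THREE_QUARTERS = HALF + QUARTER

CRC8_POLY = 0x07
CRC8_INIT = 0x00


class InnerCodecError(ValueError):
    pass


class ConstraintViolation(InnerCodecError):
    """A strand base is forbidden by the model at its position."""

    def __init__(self, position: int):
        self.position = position
        super().__init__(f"constraint violation at position {position}")


# ---------------------------------------------------------------------------
# CRC-8
# ---------------------------------------------------------------------------

def _make_crc8_table(poly: int) -> list[int]:
    table = []
    for byte in range(256):
        reg = byte
        for _ in range(8):
            reg = ((reg << 1) ^ poly) & 0xFF if reg & 0x80 else (reg << 1) & 0xFF
        table.append(reg)
    return table


_CRC8_TABLES: dict[int, list[int]] = {}


def crc8(data: bytes, poly: int = CRC8_POLY, init: int = CRC8_INIT) -> int:
    """Table-driven CRC-8 (default poly 0x07, init 0x00, no reflection)."""
    try:
        table = _CRC8_TABLES[poly]
    except KeyError:
        table = _CRC8_TABLES[poly] = _make_crc8_table(poly)
    reg = init
    for b in data:
        reg = table[reg ^ b]
    return reg


# ---------------------------------------------------------------------------
# CRC framing
# ---------------------------------------------------------------------------

def framed_length(payload_len: int, s: int) -> int:
    """Framed byte count for a payload: len + ceil(len/s) CRCs (1 CRC if empty)."""
    if s < 1:
        raise InnerCodecError("step size s must be >= 1")
    if payload_len == 0:
        return 1
    return payload_len + -(-payload_len // s)


def window_layout(payload_len: int, s: int) -> list[tuple[int, int]]:
    """CRC windows as (start, end) framed indices; framed[end] checks framed[start:end].

    The last window covers the trailing partial block; when the payload length
    is an exact multiple of ``s`` the last window CRC doubles as the final CRC.
    """
    if s < 1:
        raise InnerCodecError("step size s must be >= 1")
    if payload_len == 0:
        return [(0, 0)]
    windows = []
    pos = 0
    remaining = payload_len
    while remaining > 0:
        block = min(s, remaining)
        windows.append((pos, pos + block))
        pos += block + 1
        remaining -= block
    return windows


def frame_payload(payload: bytes, s: int) -> bytes:
    """Insert an 8-bit CRC after every ``s`` payload bytes (plus a final CRC)."""
    if s < 1:
        raise InnerCodecError("step size s must be >= 1")
    out = bytearray()
    if not payload:
        out.append(crc8(b""))
        return bytes(out)
    for i in range(0, len(payload), s):
        block = payload[i : i + s]
        out += block
        out.append(crc8(block))
    return bytes(out)


def _payload_length_for(framed_len: int, s: int) -> int:
    if framed_len == 1:
        return 0
    # L + ceil(L/s) == framed_len has at most one solution; try both candidates
    for L in ((framed_len * s) // (s + 1), (framed_len * s) // (s + 1) + 1):
        if L > 0 and framed_length(L, s) == framed_len:
            return L
    raise InnerCodecError(f"malformed frame: length {framed_len} impossible for s={s}")


def deframe_and_check(framed: bytes, s: int) -> tuple[bytes, list[bool]]:
    """Strip CRC markers, returning (payload, per-window pass flags)."""
    payload_len = _payload_length_for(len(framed), s)
    payload = bytearray()
    checks = []
    for start, end in window_layout(payload_len, s):
        block = framed[start:end]
        checks.append(crc8(block) == framed[end])
        payload += block
    return bytes(payload), checks


# ---------------------------------------------------------------------------
# Fixed-precision integer arithmetic engine
# ---------------------------------------------------------------------------

def encoder_step(low: int, high: int, pending: int,
                 cum_lo: int, cum_hi: int, total: int):
    """One symbol of arithmetic encoding; returns (low, high, pending, bits).

    ``bits`` is the list of output bits resolved by renormalization (straddle
    bits are held in ``pending`` until their direction is known).
    """
    span = high - low + 1
    high = low + span * cum_hi // total - 1
    low = low + span * cum_lo // total
    bits: list[int] = []
    while True:
        if high < HALF:
            bits.append(0)
            bits.extend([1] * pending)
            pending = 0
        elif low >= HALF:
            bits.append(1)
            bits.extend([0] * pending)
            pending = 0
            low -= HALF
            high -= HALF
        elif low >= QUARTER and high < THREE_QUARTERS:
            pending += 1
            low -= QUARTER
            high -= QUARTER
        else:
            break
        low <<= 1
        high = (high << 1) | 1
    return low, high, pending, bits


class ArithmeticEncoder:
    """Streaming integer encoder collecting output bits MSB-first into bytes."""

    __slots__ = ("low", "high", "pending", "data", "bitbuf", "bitcnt", "nbits")

    def __init__(self):
        self.low = 0
        self.high = FULL - 1
        self.pending = 0
        self.data = bytearray()
        self.bitbuf = 0
        self.bitcnt = 0
        self.nbits = 0

    def _push_bits(self, bits: Iterable[int]) -> None:
        for b in bits:
            self.bitbuf = (self.bitbuf << 1) | b
            self.bitcnt += 1
            self.nbits += 1
            if self.bitcnt == 8:
                self.data.append(self.bitbuf)
                self.bitbuf = 0
                self.bitcnt = 0

    def encode(self, cum_lo: int, cum_hi: int, total: int) -> None:
        self.low, self.high, self.pending, bits = encoder_step(
            self.low, self.high, self.pending, cum_lo, cum_hi, total
        )
        self._push_bits(bits)

    def finish(self) -> None:
        """Flush: emit one disambiguating bit plus pending straddle bits."""
        self.pending += 1
        if self.low < QUARTER:
            self._push_bits([0] + [1] * self.pending)
        else:
            self._push_bits([1] + [0] * self.pending)
        self.pending = 0

    def first_bytes(self, n: int) -> bytes:
        """First n bytes of output (zero-padding a trailing partial byte)."""
        if len(self.data) >= n:
            return bytes(self.data[:n])
        if len(self.data) == n - 1 and self.bitcnt:
            return bytes(self.data) + bytes([self.bitbuf << (8 - self.bitcnt)])
        raise InnerCodecError("not enough output bits")


def _bit_source(data: bytes) -> Iterator[int]:
    """MSB-first bits of ``data`` followed by an alternating 0101... tail.

    The tail makes the implied code value non-dyadic, so it can never sit
    exactly on a renormalization boundary; every payload bit therefore
    resolves after finitely many emitted symbols (an all-zero tail can stall
    in the straddle state indefinitely).
    """
    for byte in data:
        for shift in range(7, -1, -1):
            yield (byte >> shift) & 1
    while True:
        yield 0
        yield 1


class ArithmeticDecoder:
    """Streaming integer decoder driven by an (implicitly zero-padded) bit source."""

    __slots__ = ("low", "high", "value", "_bits")

    def __init__(self, data: bytes):
        self.low = 0
        self.high = FULL - 1
        self._bits = _bit_source(data)
        value = 0
        for _ in range(PRECISION):
            value = (value << 1) | next(self._bits)
        self.value = value

    def decode(self, cum: Sequence[int], total: int) -> int:
        """Pick the symbol whose subinterval contains the code value; renormalize."""
        span = self.high - self.low + 1
        offset = ((self.value - self.low + 1) * total - 1) // span
        sym = 0
        while cum[sym + 1] <= offset:
            sym += 1
        self.high = self.low + span * cum[sym + 1] // total - 1
        self.low = self.low + span * cum[sym] // total
        while True:
            if self.high < HALF:
                pass
            elif self.low >= HALF:
                self.low -= HALF
                self.high -= HALF
                self.value -= HALF
            elif self.low >= QUARTER and self.high < THREE_QUARTERS:
                self.low -= QUARTER
                self.high -= QUARTER
                self.value -= QUARTER
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1
            self.value = (self.value << 1) | next(self._bits)
        return sym


# ---------------------------------------------------------------------------
# Modulation: bits -> constrained DNA and back
# ---------------------------------------------------------------------------

def modulate(framed: bytes, model: TransitionModel,
             target_length: int | None = None) -> str:
    """Expand a framed payload into a constraint-adhering DNA strand.

    Runs arithmetic decoding of the input bits against the model, emitting
    one base per step, while a shadow encoder tracks how many payload bits
    the inverse operation has already recovered.  Emission stops as soon as
    the shadow has resolved every payload bit, which is the minimal flush;
    ``target_length`` optionally pads the strand with a deterministic
    most-probable-base walk (discarded by the demodulator, which knows the
    payload byte count).
    """
    nbits = 8 * len(framed)
    rate = _model_rate(model)  # bits/base carried by the codebook
    if rate <= 0:
        raise InnerCodecError("codebook carries no information (|C| = 1)")
    max_bases = 64 + int((nbits + PRECISION) / min(2.0, max(rate, 0.01)))
    dec = ArithmeticDecoder(framed)
    enc = ArithmeticEncoder()
    state = model.initial_state()
    bases: list[str] = []
    while enc.nbits < nbits:
        if len(bases) > max_bases:
            raise InnerCodecError(
                "modulation did not terminate; codebook capacity too low"
            )
        tab = model.table(state)
        sym = dec.decode(tab.cum, tab.total)
        enc.encode(tab.cum[sym], tab.cum[sym + 1], tab.total)
        bases.append(BASES[sym])
        state = model.advance_index(state, sym)
    if enc.first_bytes(len(framed)) != framed:
        raise AssertionError("modulator/demodulator lockstep mismatch")
    if target_length is not None:
        if len(bases) > target_length:
            raise InnerCodecError(
                f"natural strand length {len(bases)} exceeds target {target_length}"
            )
        while len(bases) < target_length:
            tab = model.table(state)
            sym = max(range(4), key=lambda i: (tab.counts[i], -i))
            bases.append(BASES[sym])
            state = model.advance_index(state, sym)
    return "".join(bases)


def _model_rate(model: TransitionModel) -> float:
    return math.log2(len(model.codebook)) / model.codebook.word_length


def demodulate(dna: str, model: TransitionModel, expected_bytes: int) -> bytes:
    """Exact inverse of `modulate` on clean input.

    ``expected_bytes`` is the framed byte count; trailing padding bases are
    ignored once that many bytes have been recovered.  A base forbidden by
    the model raises `ConstraintViolation` with its position — the inner
    code's error-detection signal (the error-tolerant path is the stack
    decoder).
    """
    nbits = 8 * expected_bytes
    enc = ArithmeticEncoder()
    state = model.initial_state()
    for i, ch in enumerate(dna):
        if enc.nbits >= nbits:
            break
        idx = BASE_INDEX.get(ch.upper())
        if idx is None:
            raise ConstraintViolation(i)
        tab = model.table(state)
        if tab.counts[idx] == 0:
            raise ConstraintViolation(i)
        enc.encode(tab.cum[idx], tab.cum[idx + 1], tab.total)
        state = model.advance_index(state, idx)
    if enc.nbits < nbits:
        enc.finish()
    if enc.nbits < nbits:
        raise InnerCodecError(
            f"strand too short: recovered {enc.nbits} of {nbits} payload bits"
        )
    return enc.first_bytes(expected_bytes)


# ---------------------------------------------------------------------------
# Exact rational interval engine (verification oracle)
# ---------------------------------------------------------------------------

def arith_interval(symbols: Sequence, probs: dict) -> tuple[Fraction, Fraction]:
    """Exact final interval [low, high) of static arithmetic coding.

    ``probs`` maps each alphabet symbol to its probability; subintervals are
    laid out in the dict's declaration order.  Probabilities must be positive
    and sum to 1 (dyadic floats convert exactly).  The empty sequence yields
    [0, 1); each symbol shrinks the interval by exactly its probability.
    """
    frac_probs = {s: Fraction(p) for s, p in probs.items()}
    if any(p <= 0 for p in frac_probs.values()):
        raise InnerCodecError("all symbol probabilities must be positive")
    if sum(frac_probs.values()) != 1:
        raise InnerCodecError("symbol probabilities must sum to 1")
    cum: dict[object, Fraction] = {}
    acc = Fraction(0)
    for s, p in frac_probs.items():
        cum[s] = acc
        acc += p
    low = Fraction(0)
    width = Fraction(1)
    for s in symbols:
        if s not in frac_probs:
            raise InnerCodecError(f"symbol {s!r} not in alphabet")
        low += width * cum[s]
        width *= frac_probs[s]
    return low, low + width
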