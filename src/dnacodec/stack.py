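"""Sequential stack decoding of modulated strands with an adjusted Fano metric.

The decoder searches the tree of arithmetic-demodulation states for the
most plausible encoded strand given a noisy channel output ``y``.  Each node
carries the internal state of the arithmetic decoder (coding interval,
straddle bits, recovered payload bytes), the model state, the channel
position consumed so far, and a cumulative path metric.  Per symbol the
metric is the Fano metric for a binary symmetric channel with transition
probability p_t and code rate R,

    match:     log2(2 (1 - p_t)) - R
    mismatch:  log2(2 p_t)       - R

adjusted by the model's prior probability of the hypothesized base, added in
the log domain (log2 P(base | state)) so the metric stays additive.
Insertion and deletion hypotheses reuse the mismatch shape with the event's
own probability.

A node is extended to up to nine branches: four that hypothesize the next
base as A, C, G or T against the current channel symbol (match or
substitution), four that assume the channel lost a base (deletion: the base
is hypothesized but no channel symbol is consumed), and one that assumes the
channel inserted a base (the current symbol is skipped), allowed when the
following channel symbol is itself a plausible continuation.  Branches whose
base the model forbids are removed.

Every time the recovered byte count crosses a CRC window boundary the
window's checksum is verified; failures prune the node, and once two paths
descending from the same passed-CRC anchor have failed, the whole subtree
still on the stack is penalized to push the search out of the local optimum.
The stack is bounded at M entries (worst metrics evicted) and the search
pops ``pop_count`` nodes per iteration (the generalized stack algorithm).
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import _fastdecode as _fast
from .codebook import BASE_INDEX
from .inner import (
    FULL,
    crc8,
    deframe_and_check,
    encoder_step,
    framed_length,
    window_layout,
)
from .model import TransitionModel

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ChannelPriors:
    """Channel error priors and metric parameters.

    ``p_t`` is the aggregate transition probability of the approximating
    binary symmetric channel; when unset it defaults to p_sub + p_ins + p_del.
    ``R`` is the bias (code rate, bits per base); when unset the decoder uses
    the realized rate 8 * payload_bytes / strand_bases.
    """

    p_sub: float = 0.01
    p_ins: float = 0.0
    p_del: float = 0.0
    p_t: float | None = None
    R: float | None = None

    def __post_init__(self):
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def resolved_pt(self) -> float:
        pt = self.p_t if self.p_t is not None else self.p_sub + self.p_ins + self.p_del
        return min(max(pt, 1e-12), 1.0 - 1e-12)


def fano_increment(y_i: str | None, b_i: str | None, priors: ChannelPriors,
                   prior_prob: float, R: float | None = None) -> float:
    """Metric delta for one branch.

    ``y_i`` is the observed base (None for a deletion hypothesis, where no
    channel symbol is consumed); ``b_i`` is the hypothesized base (None for
    an insertion hypothesis, where no base is emitted).  ``prior_prob`` is
    the model probability of the hypothesized base and must be positive —
    forbidden bases are never scored.
    """
    if R is None:
        R = priors.R if priors.R is not None else 0.0
    if b_i is None:  # insertion: channel symbol skipped, nothing hypothesized
        return math.log2(2.0 * priors.p_ins) - R
    if prior_prob <= 0.0:
        raise ValueError("prior_prob must be positive: forbidden bases are never scored")
    prior = math.log2(prior_prob)
    if y_i is None:  # deletion: base hypothesized without consuming a symbol
        return math.log2(2.0 * priors.p_del) - R + prior
    pt = priors.resolved_pt()
    if y_i == b_i:
        return math.log2(2.0 * (1.0 - pt)) - R + prior
    return math.log2(2.0 * pt) - R + prior


@dataclass
class DecoderConfig:
    """Search parameters for one strand."""

    expected_bytes: int
    s: int = 4                      # CRC step size (payload bytes per window)
    M: int = 2000                   # stack bound
    pop_count: int = 1              # nodes expanded per iteration
    penalty: float = 2.0            # bits subtracted from a failing subtree
    max_iterations: int = 1_000_000
    tail_slack: int = 8             # unconsumed channel symbols tolerated at
                                    # termination (covers trailing insertions
                                    # and any modulation padding)
    drift_margin: float = 0.25      # target upward metric drift of the
                                    # correct path, bits per base
    merge_equivalent: bool = True   # collapse paths that reach an identical
                                    # decoder state (same interval, bytes,
                                    # model state and channel position) onto
                                    # the best metric; indel orderings that
                                    # commute otherwise multiply the search.
                                    # Applied only with the subtree penalty
                                    # off (merged paths lose anchor identity).


class DecoderNode:
    """One decoding state (X_n, K_n) with its cumulative metric."""

    __slots__ = ("low", "high", "pending", "framed", "bitbuf", "bitcnt",
                 "state", "v", "metric", "anchor", "nwin", "terminal")

    def __init__(self, low, high, pending, framed, bitbuf, bitcnt,
                 state, v, metric, anchor, nwin, terminal=False):
        self.low = low
        self.high = high
        self.pending = pending
        self.framed = framed        # bytes recovered so far
        self.bitbuf = bitbuf
        self.bitcnt = bitcnt
        self.state = state
        self.v = v                  # channel symbols consumed
        self.metric = metric
        self.anchor = anchor        # id of the subtree root at the last passed CRC
        self.nwin = nwin            # CRC windows verified so far
        self.terminal = terminal

    @property
    def K(self) -> int:
        """Symbols (framed bytes) decodable in this state."""
        return len(self.framed)


class DecodeStack:
    """Bounded best-first candidate set with lazy dual-heap bookkeeping.

    Pop order is best metric first with stable FIFO among ties; eviction
    removes the worst metric.  Subtree penalties re-key affected entries.
    """

    def __init__(self, M: int):
        self.M = M
        self._best: list = []    # (-metric, seq, entry)
        self._worst: list = []   # (metric, -seq, entry)
        self._alive: dict[int, list] = {}
        self._seq = 0

    def __len__(self) -> int:
        return len(self._alive)

    def push(self, node: DecoderNode) -> None:
        seq = self._seq
        self._seq += 1
        entry = [node, True, seq]
        heapq.heappush(self._best, (-node.metric, seq, entry))
        heapq.heappush(self._worst, (node.metric, -seq, entry))
        self._alive[seq] = entry

    def pop_best(self) -> DecoderNode | None:
        while self._best:
            _, seq, entry = heapq.heappop(self._best)
            if entry[1]:
                entry[1] = False
                del self._alive[seq]
                return entry[0]
        return None

    def trim(self) -> int:
        """Evict worst entries until at most M remain; returns eviction count."""
        evicted = 0
        while len(self._alive) > self.M:
            _, negseq, entry = heapq.heappop(self._worst)
            if entry[1]:
                entry[1] = False
                del self._alive[-negseq]
                evicted += 1
        return evicted

    def penalize(self, anchor: int, penalty: float) -> int:
        """Subtract ``penalty`` from every stacked node under ``anchor``."""
        hit = [e for e in self._alive.values() if e[0].anchor == anchor]
        for entry in hit:
            entry[1] = False
            node = entry[0]
            del self._alive[entry[2]]
            node.metric -= penalty
            self.push(node)
        return len(hit)

    def nodes(self) -> list[DecoderNode]:
        return [e[0] for e in self._alive.values()]


@dataclass
class DecodeResult:
    payload: bytes | None
    final_metric: float
    success: bool
    iterations: int = 0
    crc_failures: int = 0


def _append_bits(framed: bytes, bitbuf: int, bitcnt: int, bits: list[int]):
    if not bits:
        return framed, bitbuf, bitcnt
    new = None
    for b in bits:
        bitbuf = (bitbuf << 1) | b
        bitcnt += 1
        if bitcnt == 8:
            if new is None:
                new = []
            new.append(bitbuf)
            bitbuf = 0
            bitcnt = 0
    if new is not None:
        framed = framed + bytes(new)  # copy only when a byte completes
    return framed, bitbuf, bitcnt


def decode_packet(y: str, model: TransitionModel, priors: ChannelPriors,
                  config: DecoderConfig) -> DecodeResult:
    """Error-tolerant decode of one strand; failures are returned, not raised.

    Returns the recovered payload (CRC markers stripped), the terminal node's
    metric, and a success flag; on stack exhaustion or the iteration guard
    the result has ``success=False`` and the outer code treats the strand as
    an erasure.  With an error-free strand the search expands only the greedy
    path and the payload equals the error-free demodulator's output.

    A compiled fast path (same semantics, see `_fastdecode`) handles the
    common configuration; other configurations use the reference search.
    """
    if (_fast.NUMBA_AVAILABLE and config.pop_count == 1
            and config.penalty == 0.0 and model.n >= model.ctx_len
            and model.ctx_len <= 8):
        return _decode_packet_fast(y, model, priors, config)
    return _decode_packet_reference(y, model, priors, config)


def _metric_constants(model: TransitionModel, priors: ChannelPriors,
                      config: DecoderConfig):
    pt = priors.resolved_pt()
    if priors.R is not None:
        R = priors.R
    else:
        # Bias so the correct path's expected increment is +drift_margin:
        # the log-prior term contributes about -H(model) per base, so the
        # bias must absorb the model entropy or the search turns
        # breadth-first and the stack explodes on clean strands.
        h_model = math.log2(len(model.codebook)) / model.codebook.word_length
        R = math.log2(2.0 * (1.0 - pt)) - h_model - config.drift_margin
    m_match = math.log2(2.0 * (1.0 - pt)) - R
    m_sub = math.log2(2.0 * pt) - R if pt > 0 else NEG_INF
    m_del = math.log2(2.0 * priors.p_del) - R if priors.p_del > 0 else NEG_INF
    m_ins = math.log2(2.0 * priors.p_ins) - R if priors.p_ins > 0 else NEG_INF
    return m_match, m_sub, m_del, m_ins


def _decode_packet_fast(y: str, model: TransitionModel, priors: ChannelPriors,
                        config: DecoderConfig) -> DecodeResult:
    framed_len = framed_length(config.expected_bytes, config.s)
    windows = window_layout(config.expected_bytes, config.s)
    m_match, m_sub, m_del, m_ins = _metric_constants(model, priors, config)
    tables = getattr(model, "_fast_tables", None)
    if tables is None:
        tables = _fast.build_context_tables(model)
        model._fast_tables = tables
    forb_ptr, forb_code, forb_len = tables
    from .inner import _CRC8_TABLES, _make_crc8_table, CRC8_POLY

    table = _CRC8_TABLES.setdefault(CRC8_POLY, _make_crc8_table(CRC8_POLY))
    crc_table = np.array(table, dtype=np.uint8)
    y_idx = np.array([BASE_INDEX.get(ch.upper(), -1) for ch in y], dtype=np.int8)
    win_start = np.array([w[0] for w in windows], dtype=np.int64)
    win_end = np.array([w[1] for w in windows], dtype=np.int64)
    success, metric, iterations, crc_failures, out = _fast._decode_kernel(
        model._codes, model.n, model.ctx_len, forb_ptr, forb_code, forb_len,
        crc_table, win_start, win_end, y_idx,
        framed_len, config.M, config.max_iterations, config.tail_slack,
        m_match, m_sub,
        m_del if m_del > NEG_INF else 0.0,
        m_ins if m_ins > NEG_INF else 0.0,
        m_del > NEG_INF, m_ins > NEG_INF,
        config.merge_equivalent, _fast.make_seen_dict(),
    )
    if success:
        payload, _checks = deframe_and_check(bytes(out), config.s)
        return DecodeResult(payload, metric, True, iterations, crc_failures)
    return DecodeResult(None, NEG_INF, False, iterations, crc_failures)


def _decode_packet_reference(y: str, model: TransitionModel,
                             priors: ChannelPriors,
                             config: DecoderConfig) -> DecodeResult:
    framed_len = framed_length(config.expected_bytes, config.s)
    windows = window_layout(config.expected_bytes, config.s)
    y_idx = [BASE_INDEX.get(ch.upper(), -1) for ch in y]
    ny = len(y_idx)

    consts = _metric_constants(model, priors, config)

    stack = DecodeStack(config.M)
    stack.push(root_node(model))

    fail_counts: dict[int, int] = {}
    penalized: set[int] = set()
    transitions: dict = {}   # state -> (table, lazily filled child states)
    anchor_counter = itertools.count(1)
    iterations = 0
    crc_failures = 0
    merging = config.merge_equivalent and config.penalty == 0.0
    seen: dict = {}          # equivalent-state key -> best metric reached

    while len(stack) and iterations < config.max_iterations:
        popped = []
        for _ in range(config.pop_count):
            node = stack.pop_best()
            if node is None:
                break
            if node.terminal:
                # accept only if (nearly) all channel symbols are explained;
                # a CRC-consistent path that ignores most of y is spurious
                if node.v >= ny - config.tail_slack:
                    payload, _checks = deframe_and_check(
                        node.framed[:framed_len], config.s
                    )
                    return DecodeResult(payload, node.metric, True,
                                        iterations, crc_failures)
                continue
            popped.append(node)
        if not popped:
            break
        for node in popped:
            iterations += 1
            children, fails = _extend(node, y_idx, model, transitions, windows,
                                      framed_len, consts, anchor_counter)
            crc_failures += fails
            if fails:
                cnt = fail_counts.get(node.anchor, 0) + fails
                fail_counts[node.anchor] = cnt
                if cnt >= 2 and node.anchor not in penalized:
                    penalized.add(node.anchor)
                    penalize_subtree(stack, node.anchor, config.penalty)
            for child in children:
                if merging:
                    key = (child.low, child.high, child.pending, child.bitbuf,
                           child.bitcnt, child.framed, child.v,
                           child.state.phase, child.state.prefix,
                           child.state.context)
                    best = seen.get(key)
                    if best is not None and best >= child.metric:
                        continue
                    seen[key] = child.metric
                stack.push(child)
        stack.trim()

    return DecodeResult(None, NEG_INF, False, iterations, crc_failures)


def _extend(node: DecoderNode, y_idx, model: TransitionModel, transitions,
            windows, framed_len, consts, anchor_counter):
    """Generate a node's children; returns (children, crc_failure_count).

    Match/substitution and deletion children share one arithmetic/model
    transition per base; the insertion child changes only the channel
    position.  Children whose newly resolved bytes fail a CRC window are
    pruned before creation (one failure event per pruned base hypothesis).
    """
    m_match, m_sub, m_del, m_ins = consts
    ny = len(y_idx)
    nwindows = len(windows)
    children: list[DecoderNode] = []
    fails = 0
    memo = transitions.get(node.state)
    if memo is None:
        memo = (model.table(node.state), [None, None, None, None])
        transitions[node.state] = memo
    tab, kids = memo
    counts, total, cum, logp = tab
    yv = y_idx[node.v] if node.v < ny else None
    for b in range(4):
        if counts[b] == 0:
            continue
        low2, high2, pend2, bits = encoder_step(
            node.low, node.high, node.pending, cum[b], cum[b + 1], total
        )
        framed2, bitbuf2, bitcnt2 = _append_bits(
            node.framed, node.bitbuf, node.bitcnt, bits
        )
        # CRC gate on newly resolved bytes (shared by match/del child)
        nwin2 = node.nwin
        ok = True
        nbytes = len(framed2)
        while nwin2 < nwindows and windows[nwin2][1] < nbytes:
            start, end = windows[nwin2]
            if crc8(framed2[start:end]) != framed2[end]:
                ok = False
                break
            nwin2 += 1
        if not ok:
            fails += 1
            continue
        state2 = kids[b]
        if state2 is None:
            state2 = kids[b] = model.advance_index(node.state, b)
        terminal = nbytes >= framed_len
        passed_window = nwin2 > node.nwin
        prior = logp[b]
        if yv is not None:
            delta = (m_match if b == yv else m_sub) + prior
            anchor2 = next(anchor_counter) if passed_window else node.anchor
            children.append(DecoderNode(
                low2, high2, pend2, framed2, bitbuf2, bitcnt2,
                state2, node.v + 1, node.metric + delta,
                anchor2, nwin2, terminal,
            ))
        if m_del > NEG_INF:
            anchor2 = next(anchor_counter) if passed_window else node.anchor
            children.append(DecoderNode(
                low2, high2, pend2, framed2, bitbuf2, bitcnt2,
                state2, node.v, node.metric + m_del + prior,
                anchor2, nwin2, terminal,
            ))
    # insertion branch: skip y_v when the next channel symbol is a
    # plausible continuation in the current state
    if (m_ins > NEG_INF and yv is not None and node.v + 1 < ny
            and y_idx[node.v + 1] >= 0 and counts[y_idx[node.v + 1]] > 0):
        children.append(DecoderNode(
            node.low, node.high, node.pending, node.framed,
            node.bitbuf, node.bitcnt, node.state, node.v + 1,
            node.metric + m_ins, node.anchor, node.nwin, node.terminal,
        ))
    return children, fails


def extend(node: DecoderNode, y: str, model: TransitionModel,
           priors: ChannelPriors, config: DecoderConfig) -> list[DecoderNode]:
    """Extend one decoding node to its up-to-nine children.

    Four branches hypothesize the next base against the current channel
    symbol, four assume a channel deletion (enabled when p_del > 0), and one
    assumes a channel insertion (p_ins > 0 and the following symbol is
    model-plausible); model-forbidden bases are removed, as are children
    failing a CRC window crossed by their newly resolved bytes.
    """
    consts = _metric_constants(model, priors, config)
    windows = window_layout(config.expected_bytes, config.s)
    framed_len = framed_length(config.expected_bytes, config.s)
    y_idx = [BASE_INDEX.get(ch.upper(), -1) for ch in y]
    children, _fails = _extend(node, y_idx, model, {}, windows, framed_len,
                               consts, itertools.count(node.anchor + 1))
    return children


def crc_gate(node: DecoderNode, s: int) -> bool:
    """Verify every complete CRC window among the node's resolved bytes.

    Returns True (keep) iff each full ``s``-byte window followed by its CRC
    byte checks out; the node pruning and anchor bookkeeping around this
    check live in `decode_packet`.
    """
    framed = node.framed
    pos = 0
    while pos + s < len(framed):
        block = framed[pos : pos + s]
        if crc8(block) != framed[pos + s]:
            return False
        pos += s + 1
    return True


def root_node(model: TransitionModel) -> DecoderNode:
    """Fresh decoding root: full coding interval, initial model state."""
    return DecoderNode(0, FULL - 1, 0, b"", 0, 0, model.initial_state(),
                       0, 0.0, 0, 0)


def penalize_subtree(stack: DecodeStack, crc_anchor: int,
                     penalty: float) -> int:
    """Push down every stacked node descending from a failing CRC anchor.

    Invoked once per anchor after its second CRC failure; returns the number
    of re-ranked nodes.
    """
    return stack.penalize(crc_anchor, penalty)
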