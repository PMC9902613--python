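"""Finite-state transition model over a codebook.

The model turns a codebook plus concatenation scheme into a finite state
transition diagram whose states are (position within the current codeword,
the codeword prefix emitted so far, the rolling suffix of the whole emitted
stream).  The probability of emitting base ``x`` in a state is the empirical
frequency of codewords that extend the current prefix with ``x``, with
codewords excluded when the junction context forbids their prefix.  These
per-state frequencies are exactly what the arithmetic modulator partitions
its coding interval with, and what the sequential decoder uses as the prior
probability of a hypothesized base.

States are realized lazily; prefix counts are range queries on the sorted
integer codes of the codebook, so no explicit state diagram is materialized
even for codebooks with hundreds of thousands of words.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from typing import NamedTuple

import numpy as np

from .codebook import (
    BASES,
    BASE_INDEX,
    Codebook,
    ConcatenationScheme,
    encode_word,
)


class ModelError(ValueError):
    pass


class InvalidTransition(ValueError):
    """Raised when a base has zero probability in the current state.

    During decoding this is the constraint-violation detection signal: an
    errored strand eventually requests a transition the codebook forbids.
    """


class ModelState(NamedTuple):
    phase: int              # position within the current codeword, in [0, n)
    prefix: int             # base-4 code of the current within-word prefix
    context: str            # last ctx_len bases of the whole emitted stream
    fset: tuple             # forbidden-prefix constraints pending for this word,
                            # as (code, length) pairs with length > phase


class _StateTable(NamedTuple):
    counts: tuple[int, int, int, int]   # codewords extending prefix with A,C,G,T
    total: int
    cum: tuple[int, int, int, int, int]  # cumulative counts in A,C,G,T order
    logp: tuple                          # log2(count/total) or None per base


class TransitionModel:
    """Lazily evaluated FSTD with per-state base frequencies."""

    def __init__(self, codebook: Codebook, scheme: ConcatenationScheme):
        self.codebook = codebook
        self.scheme = scheme
        self.n = codebook.word_length
        for key, prefixes in scheme.forbidden_pairs.items():
            for p in prefixes:
                if len(p) > self.n:
                    raise ModelError(
                        f"scheme prefix {p!r} is longer than the codeword length {self.n}"
                    )
        self.ctx_len = scheme.max_suffix_length
        self._codes = codebook.codes
        # plain-int sorted list: bisect beats per-call numpy overhead in the
        # decoder's hot loop
        self._codes_list = self._codes.tolist()
        self._table_cache: dict[tuple, _StateTable] = {}
        self._forbidden_cache: dict[str, tuple] = {}
        self._check_junctions()

    # -- state plumbing ----------------------------------------------------

    def initial_state(self) -> ModelState:
        return ModelState(0, 0, "", ())

    def _range_count(self, code: int, length: int) -> int:
        """Number of codewords whose first ``length`` bases have code ``code``."""
        shift = 2 * (self.n - length)
        lst = self._codes_list
        return bisect_left(lst, (code + 1) << shift) - bisect_left(lst, code << shift)

    def _forbidden_tuple(self, context: str) -> tuple:
        try:
            return self._forbidden_cache[context]
        except KeyError:
            prefixes = self.scheme.forbidden_after(context)
            out = tuple((encode_word(p), len(p)) for p in prefixes)
            self._forbidden_cache[context] = out
            return out

    def table(self, state: ModelState) -> _StateTable:
        key = (state.phase, state.prefix, state.fset)
        try:
            return self._table_cache[key]
        except KeyError:
            pass
        L = state.phase
        shift = 2 * (self.n - L - 1)
        base = state.prefix << 2
        lst = self._codes_list
        edges = [bisect_left(lst, (base + x) << shift) for x in range(5)]
        counts = [edges[x + 1] - edges[x] for x in range(4)]
        if state.fset:
            for x in range(4):
                if not counts[x]:
                    continue
                code = base | x
                for fcode, flen in state.fset:
                    if flen >= L + 1 and (fcode >> 2 * (flen - L - 1)) == code:
                        counts[x] -= self._range_count(fcode, flen)
        total = sum(counts)
        if total == 0:
            raise ModelError(
                "scheme eliminates all codewords at state "
                f"(phase={state.phase}, prefix={state.prefix}, context={state.context!r})"
            )
        cum = (0, counts[0], counts[0] + counts[1],
               counts[0] + counts[1] + counts[2], total)
        logp = tuple(math.log2(c / total) if c else None for c in counts)
        tab = _StateTable(tuple(counts), total, cum, logp)
        self._table_cache[key] = tab
        return tab

    def counts(self, state: ModelState) -> tuple[int, int, int, int]:
        return self.table(state).counts

    def allowed_bases(self, state: ModelState) -> tuple[str, ...]:
        c = self.counts(state)
        return tuple(BASES[i] for i in range(4) if c[i])

    def advance_index(self, state: ModelState, base_index: int) -> ModelState:
        """Advance by base index without re-validating (caller checked counts)."""
        if self.ctx_len:
            context = (state.context + BASES[base_index])[-self.ctx_len:]
        else:
            context = ""
        if state.phase == self.n - 1:
            return ModelState(0, 0, context, self._forbidden_tuple(context))
        fset = tuple(f for f in state.fset if f[1] > state.phase + 1)
        return ModelState(state.phase + 1, (state.prefix << 2) | base_index,
                          context, fset)

    # -- startup sanity ----------------------------------------------------

    def _check_junctions(self) -> None:
        """Fail fast if some reachable junction context kills every codeword.

        When the context window fits inside one codeword, the reachable
        post-wrap contexts are exactly the codeword suffixes of that width;
        otherwise (short words) contexts are explored by a bounded walk over
        word completions.
        """
        if self.ctx_len == 0:
            self.table(self.initial_state())
            return
        if self.ctx_len <= self.n:
            contexts = {w[-self.ctx_len:] for w in self.codebook.words}
            for ctx in sorted(contexts):
                self.table(ModelState(0, 0, ctx, self._forbidden_tuple(ctx)))
            return
        seen: set[str] = set()
        frontier = [""]
        while frontier:
            ctx = frontier.pop()
            state = ModelState(0, 0, ctx, self._forbidden_tuple(ctx))
            tab = self.table(state)  # raises ModelError on a dead context
            forbidden = self.scheme.forbidden_after(ctx)
            for w in self.codebook.words:
                if any(w.startswith(p) for p in forbidden):
                    continue
                nxt = (ctx + w)[-self.ctx_len:]
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
            del tab


def build_model(codebook: Codebook, scheme: ConcatenationScheme | None = None) -> TransitionModel:
    """Build the transition model for a codebook and (optional) scheme."""
    return TransitionModel(codebook, scheme or ConcatenationScheme())


def next_distribution(model: TransitionModel, state: ModelState) -> dict[str, float]:
    """Normalized base -> probability map for a state (zero for forbidden bases)."""
    tab = model.table(state)
    return {BASES[i]: tab.counts[i] / tab.total for i in range(4)}


def advance(model: TransitionModel, state: ModelState, base: str) -> ModelState:
    """Advance the model by one emitted base; forbidden bases raise."""
    idx = BASE_INDEX.get(base.upper())
    if idx is None:
        raise InvalidTransition(f"not a DNA base: {base!r}")
    if model.counts(state)[idx] == 0:
        raise InvalidTransition(
            f"invalid transition: base {base} forbidden at phase {state.phase} "
            f"(prefix code {state.prefix}, context {state.context!r})"
        )
    return model.advance_index(state, idx)
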