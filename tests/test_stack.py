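"""Sequential stack decoder: metric, branching, pruning, search quality."""

import math

import numpy as np
import pytest

from dnacodec import (
    ChannelPriors,
    Codebook,
    ConstraintSpec,
    DecodeStack,
    DecoderConfig,
    ErrorRates,
    build_model,
    corrupt,
    crc_gate,
    decode_packet,
    demodulate,
    extend,
    fano_increment,
    frame_payload,
    generate_codebook,
    modulate,
    penalize_subtree,
    root_node,
)
from dnacodec.inner import crc8, framed_length, window_layout
from dnacodec.stack import (
    DecoderNode,
    _decode_packet_fast,
    _decode_packet_reference,
    _metric_constants,
)


class TestFanoIncrement:
    def test_uninformative_channel_collapses_to_bias(self):
        priors = ChannelPriors(p_sub=0.5, p_t=0.5, R=0.7)
        match = fano_increment("A", "A", priors, 1.0)
        mismatch = fano_increment("A", "C", priors, 1.0)
        assert match == pytest.approx(-0.7)
        assert mismatch == pytest.approx(-0.7)

    def test_quarter_transition_probability(self):
        priors = ChannelPriors(p_sub=0.25, p_t=0.25, R=1.0)
        assert fano_increment("G", "G", priors, 1.0) == pytest.approx(-0.415, abs=5e-4)
        assert fano_increment("G", "T", priors, 1.0) == pytest.approx(-2.0)

    def test_clean_channel_limit_with_uniform_prior(self):
        priors = ChannelPriors(p_sub=1e-12, p_t=1e-12, R=0.5)
        val = fano_increment("A", "A", priors, 0.25)
        assert val == pytest.approx(1.0 - 0.5 + math.log2(0.25), abs=1e-6)

    def test_indel_hypotheses_use_event_probabilities(self):
        priors = ChannelPriors(p_sub=0.01, p_ins=0.004, p_del=0.008, R=0.0)
        assert fano_increment(None, "A", priors, 0.5) == pytest.approx(
            math.log2(2 * 0.008) + math.log2(0.5)
        )
        assert fano_increment("A", None, priors, 1.0) == pytest.approx(
            math.log2(2 * 0.004)
        )

    def test_zero_prior_is_contract_violation(self):
        with pytest.raises(ValueError, match="prior_prob"):
            fano_increment("A", "A", ChannelPriors(), 0.0)


class TestExtend:
    def priors(self):
        return ChannelPriors(p_sub=0.05, p_ins=0.01, p_del=0.01)

    def test_nine_branches_when_insertion_condition_holds(self, uniform_model):
        config = DecoderConfig(expected_bytes=4, s=2)
        node = root_node(uniform_model)
        children = extend(node, "ACGT", uniform_model, self.priors(), config)
        # 4 match/sub + 4 deletion + 1 insertion
        assert len(children) == 9

    def test_eight_branches_without_insertion_symbol(self, uniform_model):
        config = DecoderConfig(expected_bytes=4, s=2)
        node = root_node(uniform_model)
        children = extend(node, "A", uniform_model, self.priors(), config)
        assert len(children) == 8

    def test_forbidden_bases_removed(self, no_gg_model):
        from dnacodec import advance

        config = DecoderConfig(expected_bytes=4, s=2)
        node = root_node(no_gg_model)
        state_after_g = advance(no_gg_model, no_gg_model.initial_state(), "G")
        node.state = state_after_g
        children = extend(node, "GAT", no_gg_model, self.priors(), config)
        # no G hypotheses: 3 match + 3 deletion, +1 insertion (y[1]=A allowed)
        assert len(children) == 7
        for child in children:
            assert child.state.context != "GG"

    def test_metric_additivity(self, uniform_model):
        config = DecoderConfig(expected_bytes=4, s=2)
        priors = self.priors()
        consts = _metric_constants(uniform_model, priors, config)
        m_match, m_sub, m_del, m_ins = consts
        node = root_node(uniform_model)
        children = extend(node, "ACGT", uniform_model, priors, config)
        prior = math.log2(0.25)
        expected = sorted(
            [m_match + prior, m_sub + prior, m_sub + prior, m_sub + prior]
            + [m_del + prior] * 4 + [m_ins]
        )
        assert sorted(c.metric for c in children) == pytest.approx(expected)


class TestCrcGate:
    def test_clean_windows_keep(self, uniform_model, rng):
        payload = bytes(rng.integers(0, 256, 6, dtype=np.uint8))
        framed = frame_payload(payload, 2)
        node = root_node(uniform_model)
        node.framed = framed
        assert crc_gate(node, 2)

    def test_corrupt_window_drops(self, uniform_model, rng):
        payload = bytes(rng.integers(0, 256, 6, dtype=np.uint8))
        framed = bytearray(frame_payload(payload, 2))
        framed[0] ^= 0x10
        node = root_node(uniform_model)
        node.framed = bytes(framed)
        assert not crc_gate(node, 2)

    def test_partial_window_not_gated(self, uniform_model):
        node = root_node(uniform_model)
        node.framed = b"\x12"  # less than one full window: nothing to check
        assert crc_gate(node, 2)


class TestDecodeStack:
    def node(self, metric):
        n = DecoderNode(0, 1, 0, b"", 0, 0, None, 0, metric, 0, 0)
        return n

    def test_best_first_with_fifo_ties(self):
        stack = DecodeStack(10)
        a, b, c = self.node(1.0), self.node(2.0), self.node(1.0)
        for n in (a, b, c):
            stack.push(n)
        assert stack.pop_best() is b
        assert stack.pop_best() is a  # FIFO among equal metrics
        assert stack.pop_best() is c

    def test_trim_evicts_worst(self):
        stack = DecodeStack(3)
        nodes = [self.node(float(i)) for i in range(6)]
        for n in nodes:
            stack.push(n)
        stack.trim()
        assert len(stack) == 3
        kept = {n.metric for n in stack.nodes()}
        assert kept == {3.0, 4.0, 5.0}

    def test_penalize_reorders_subtree(self):
        stack = DecodeStack(10)
        inside = self.node(5.0)
        inside.anchor = 7
        outside = self.node(4.5)
        outside.anchor = 3
        stack.push(inside)
        stack.push(outside)
        moved = penalize_subtree(stack, 7, 1.0)
        assert moved == 1
        assert stack.pop_best() is outside
        popped = stack.pop_best()
        assert popped is inside and popped.metric == pytest.approx(4.0)

    def test_penalize_no_descendants_noop(self):
        stack = DecodeStack(10)
        n = self.node(1.0)
        stack.push(n)
        assert penalize_subtree(stack, 99, 2.0) == 0
        assert stack.pop_best() is n


@pytest.fixture(scope="module")
def packet_setup():
    spec = ConstraintSpec(gc_min=0.25, gc_max=0.75, gc_interval=4, hp_max=2)
    cb, scheme = generate_codebook(spec, 4)
    model = build_model(cb, scheme)
    rng = np.random.default_rng(77)
    payload = bytes(rng.integers(0, 256, 20, dtype=np.uint8))
    framed = frame_payload(payload, 2)
    strand = modulate(framed, model)
    return model, payload, framed, strand


class TestDecodePacket:
    def config(self, **kw):
        kw.setdefault("expected_bytes", 20)
        kw.setdefault("s", 2)
        kw.setdefault("M", 3000)
        kw.setdefault("penalty", 0.0)
        kw.setdefault("max_iterations", 150_000)
        return DecoderConfig(**kw)

    def test_clean_strand_greedy_and_matches_demodulate(self, packet_setup):
        model, payload, framed, strand = packet_setup
        res = decode_packet(strand, model, ChannelPriors(p_sub=0.02),
                            self.config())
        assert res.success
        assert res.payload == payload
        assert frame_payload(res.payload, 2) == demodulate(strand, model,
                                                           len(framed))
        # greedy: one expansion per base
        assert res.iterations == len(strand)

    @pytest.mark.parametrize("err", ["sub", "del", "ins"])
    def test_single_error_recovery(self, packet_setup, err, rng):
        model, payload, _, strand = packet_setup
        priors = ChannelPriors(p_sub=0.02, p_ins=0.005, p_del=0.005)
        ok = 0
        for t in range(20):
            pos = int(rng.integers(5, len(strand) - 5))
            if err == "sub":
                repl = "ACGT"[(("ACGT".index(strand[pos])) + 1 + int(rng.integers(3))) % 4]
                noisy = strand[:pos] + repl + strand[pos + 1:]
            elif err == "del":
                noisy = strand[:pos] + strand[pos + 1:]
            else:
                noisy = strand[:pos] + "ACGT"[int(rng.integers(4))] + strand[pos:]
            res = decode_packet(noisy, model, priors, self.config())
            ok += res.success and res.payload == payload
        assert ok == 20

    def test_failure_is_returned_not_raised(self, packet_setup):
        model, payload, _, strand = packet_setup
        noisy = corrupt(strand, ErrorRates(sub=0.4), 3)
        res = decode_packet(noisy, model, ChannelPriors(p_sub=0.05),
                            self.config(max_iterations=3000, M=500))
        if not res.success:
            assert res.payload is None
            assert res.final_metric == float("-inf")

    def test_monotone_degradation(self, packet_setup):
        model, payload, _, strand = packet_setup
        priors = ChannelPriors(p_sub=0.05, p_ins=0.01, p_del=0.01)
        rates_grid = [0.01, 0.08, 0.25]
        succ = []
        for i, r in enumerate(rates_grid):
            ok = 0
            for t in range(20):
                noisy = corrupt(strand, ErrorRates(sub=r, ins=r / 5, dele=r / 5),
                                1000 * i + t)
                res = decode_packet(noisy, model, priors,
                                    self.config(max_iterations=30_000))
                ok += res.success and res.payload == payload
            succ.append(ok)
        assert succ[0] >= succ[1] >= succ[2] - 1  # small-sample slack
        assert succ[0] >= 18

    def test_indel_reliability_matches_substitution(self, packet_setup, rng):
        model, payload, _, strand = packet_setup
        priors = ChannelPriors(p_sub=0.02, p_ins=0.01, p_del=0.01)
        counts = {}
        for err in ("sub", "del", "ins"):
            ok = 0
            for t in range(15):
                pos = int(rng.integers(5, len(strand) - 5))
                if err == "sub":
                    repl = "ACGT"[("ACGT".index(strand[pos]) + 1) % 4]
                    noisy = strand[:pos] + repl + strand[pos + 1:]
                elif err == "del":
                    noisy = strand[:pos] + strand[pos + 1:]
                else:
                    noisy = strand[:pos] + "T" + strand[pos:]
                res = decode_packet(noisy, model, priors, self.config())
                ok += res.success and res.payload == payload
            counts[err] = ok
        assert counts["del"] >= counts["sub"] - 1
        assert counts["ins"] >= counts["sub"] - 1

    def test_fast_path_matches_reference(self, packet_setup):
        model, payload, _, strand = packet_setup
        priors = ChannelPriors(p_sub=0.04, p_ins=0.01, p_del=0.01)
        config = self.config(M=1500, max_iterations=20_000,
                             merge_equivalent=False)
        for t in range(10):
            noisy = corrupt(strand, ErrorRates(sub=0.05, ins=0.01, dele=0.01), t)
            fast = _decode_packet_fast(noisy, model, priors, config)
            ref = _decode_packet_reference(noisy, model, priors, config)
            assert fast.success == ref.success
            assert fast.payload == ref.payload
            if fast.success:
                assert fast.final_metric == pytest.approx(ref.final_metric)


class TestExhaustiveOracle:
    """On tiny instances the stack decoder must equal brute-force search."""

    def oracle(self, y, model, priors, config):
        """Enumerate every branch sequence; best CRC-consistent terminal."""
        from dnacodec.inner import encoder_step
        from dnacodec.stack import _append_bits

        framed_len = framed_length(config.expected_bytes, config.s)
        windows = window_layout(config.expected_bytes, config.s)
        consts = _metric_constants(model, priors, config)
        m_match, m_sub, m_del, m_ins = consts
        y_idx = ["ACGT".index(c) for c in y]
        ny = len(y)
        best = [float("-inf"), None]
        max_bases = framed_len * 4 + 2

        def rec(low, high, pend, framed, bitbuf, bitcnt, state, v, metric,
                nbases):
            if len(framed) >= framed_len:
                _, checks = __import__("dnacodec").deframe_and_check(
                    framed[:framed_len], config.s)
                if all(checks) and v >= ny - config.tail_slack:
                    if metric > best[0]:
                        best[0] = metric
                        best[1] = framed[:framed_len]
                return
            if nbases > max_bases:
                return
            tab = model.table(state)
            counts, total, cum, logp = tab
            yv = y_idx[v] if v < ny else None
            for b in range(4):
                if counts[b] == 0:
                    continue
                low2, high2, pend2, bits = encoder_step(
                    low, high, pend, cum[b], cum[b + 1], total)
                framed2, bitbuf2, bitcnt2 = _append_bits(framed, bitbuf,
                                                         bitcnt, bits)
                # prune CRC-inconsistent prefixes exactly like the gate
                ok = True
                for start, end in windows:
                    if end < len(framed2) and crc8(framed2[start:end]) != framed2[end]:
                        ok = False
                        break
                if not ok:
                    continue
                state2 = model.advance_index(state, b)
                if yv is not None:
                    delta = (m_match if b == yv else m_sub) + logp[b]
                    rec(low2, high2, pend2, framed2, bitbuf2, bitcnt2, state2,
                        v + 1, metric + delta, nbases + 1)
                if m_del > float("-inf"):
                    rec(low2, high2, pend2, framed2, bitbuf2, bitcnt2, state2,
                        v, metric + m_del + logp[b], nbases + 1)
            if (m_ins > float("-inf") and yv is not None and v + 1 < ny
                    and counts[y_idx[v + 1]] > 0):
                rec(low, high, pend, framed, bitbuf, bitcnt, state, v + 1,
                    metric + m_ins, nbases)

        from dnacodec.inner import FULL

        rec(0, FULL - 1, 0, b"", 0, 0, model.initial_state(), 0, 0.0, 0)
        return best

    @pytest.mark.parametrize("mutate", [
        lambda s: s,                                   # clean
        lambda s: "C" + s[1:],                         # substitution
        lambda s: s[1:],                               # deletion
        lambda s: s[:2] + "G" + s[2:],                 # insertion
        lambda s: "T" + s[:-1],                        # shift-like corruption
    ], ids=["clean", "sub", "del", "ins", "shift"])
    def test_matches_bruteforce_max_metric(self, uniform_model, mutate):
        # empty payload -> frame is the single final CRC byte -> 4 bases
        framed = frame_payload(b"", 1)
        strand = modulate(framed, uniform_model)
        assert len(strand) == 4
        y = mutate(strand)
        priors = ChannelPriors(p_sub=0.05, p_ins=0.02, p_del=0.02, R=0.0)
        config = DecoderConfig(expected_bytes=0, s=1, M=100_000,
                               penalty=0.0, max_iterations=500_000,
                               tail_slack=1, merge_equivalent=False)
        best_metric, best_framed = self.oracle(y, uniform_model, priors, config)
        res = _decode_packet_reference(y, uniform_model, priors, config)
        assert res.success == (best_framed is not None)
        if res.success:
            assert res.final_metric == pytest.approx(best_metric)
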