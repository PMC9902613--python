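"""Array-based fast path for the sequential stack decoder.

Semantics mirror the reference implementation in `stack.decode_packet`
(same branch order, same FIFO tie-breaking among equal metrics, same
worst-first eviction); only the data layout differs — a fixed node pool in
struct-of-arrays form, lazy dual binary heaps keyed by (metric, insertion
sequence) with periodic compaction, and CRC/model lookups on flat arrays,
compiled with numba.  The fast path handles the common configuration
(single pop per iteration, no subtree penalty, codeword length >= junction
context width); everything else falls back to the reference implementation.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit, types
    from numba.typed import Dict as NumbaDict

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    NUMBA_AVAILABLE = False
    types = None
    NumbaDict = None

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


def make_seen_dict():
    """Fresh equivalent-state table (hash -> best metric) for one decode."""
    if NUMBA_AVAILABLE:
        return NumbaDict.empty(key_type=types.uint64, value_type=types.float64)
    return {}


_FNV_OFFSET = np.uint64(1469598103934665603)
_FNV_PRIME = np.uint64(1099511628211)


_HALF = 1 << 31
_QUARTER = 1 << 30
_THREEQ = _HALF + _QUARTER
_FULL = 1 << 32


def build_context_tables(model):
    """Flatten the scheme's forbidden-prefix sets per junction context code."""
    from .codebook import decode_word, encode_word

    ctx_len = model.ctx_len
    n_ctx = 4 ** ctx_len
    ptr = np.zeros(n_ctx + 1, dtype=np.int64)
    codes: list[int] = []
    lens: list[int] = []
    for c in range(n_ctx):
        context = decode_word(c, ctx_len) if ctx_len else ""
        for p in model.scheme.forbidden_after(context):
            codes.append(encode_word(p))
            lens.append(len(p))
        ptr[c + 1] = len(codes)
    return (ptr, np.array(codes, dtype=np.int64), np.array(lens, dtype=np.int64))


@njit(cache=True)
def _heap_push(hmet, hseq, hslot, hver, size, metric, seq, slot, ver, best):
    i = size
    hmet[i] = metric
    hseq[i] = seq
    hslot[i] = slot
    hver[i] = ver
    while i > 0:
        p = (i - 1) >> 1
        if best:
            swap = hmet[i] > hmet[p] or (hmet[i] == hmet[p] and hseq[i] < hseq[p])
        else:
            swap = hmet[i] < hmet[p] or (hmet[i] == hmet[p] and hseq[i] > hseq[p])
        if not swap:
            break
        hmet[i], hmet[p] = hmet[p], hmet[i]
        hseq[i], hseq[p] = hseq[p], hseq[i]
        hslot[i], hslot[p] = hslot[p], hslot[i]
        hver[i], hver[p] = hver[p], hver[i]
        i = p
    return size + 1


@njit(cache=True)
def _heap_pop(hmet, hseq, hslot, hver, size, best):
    slot = hslot[0]
    ver = hver[0]
    size -= 1
    if size > 0:
        hmet[0] = hmet[size]
        hseq[0] = hseq[size]
        hslot[0] = hslot[size]
        hver[0] = hver[size]
        i = 0
        while True:
            l = 2 * i + 1
            r = l + 1
            top = i
            if l < size:
                if best:
                    if hmet[l] > hmet[top] or (hmet[l] == hmet[top] and hseq[l] < hseq[top]):
                        top = l
                else:
                    if hmet[l] < hmet[top] or (hmet[l] == hmet[top] and hseq[l] > hseq[top]):
                        top = l
            if r < size:
                if best:
                    if hmet[r] > hmet[top] or (hmet[r] == hmet[top] and hseq[r] < hseq[top]):
                        top = r
                else:
                    if hmet[r] < hmet[top] or (hmet[r] == hmet[top] and hseq[r] > hseq[top]):
                        top = r
            if top == i:
                break
            hmet[i], hmet[top] = hmet[top], hmet[i]
            hseq[i], hseq[top] = hseq[top], hseq[i]
            hslot[i], hslot[top] = hslot[top], hslot[i]
            hver[i], hver[top] = hver[top], hver[i]
            i = top
    return slot, ver, size


@njit(cache=True)
def _heap_compact(hmet, hseq, hslot, hver, size, nd_alive, nd_ver, best):
    """Drop stale entries and re-heapify; alive entry count is <= pool size."""
    m = 0
    for i in range(size):
        s = hslot[i]
        if nd_alive[s] == 1 and nd_ver[s] == hver[i]:
            hmet[m] = hmet[i]
            hseq[m] = hseq[i]
            hslot[m] = hslot[i]
            hver[m] = hver[i]
            m += 1
    # sift-down heapify
    for start in range(m // 2 - 1, -1, -1):
        i = start
        while True:
            l = 2 * i + 1
            r = l + 1
            top = i
            if l < m:
                if best:
                    if hmet[l] > hmet[top] or (hmet[l] == hmet[top] and hseq[l] < hseq[top]):
                        top = l
                else:
                    if hmet[l] < hmet[top] or (hmet[l] == hmet[top] and hseq[l] > hseq[top]):
                        top = l
            if r < m:
                if best:
                    if hmet[r] > hmet[top] or (hmet[r] == hmet[top] and hseq[r] < hseq[top]):
                        top = r
                else:
                    if hmet[r] < hmet[top] or (hmet[r] == hmet[top] and hseq[r] > hseq[top]):
                        top = r
            if top == i:
                break
            hmet[i], hmet[top] = hmet[top], hmet[i]
            hseq[i], hseq[top] = hseq[top], hseq[i]
            hslot[i], hslot[top] = hslot[top], hslot[i]
            hver[i], hver[top] = hver[top], hver[i]
            i = top
    return m


@njit(cache=True)
def _range_count(codes, code, length, n):
    shift = 2 * (n - length)
    lo = np.searchsorted(codes, np.uint64(code << shift))
    hi = np.searchsorted(codes, np.uint64((code + 1) << shift))
    return hi - lo


@njit(cache=True)
def _decode_kernel(codes, n, ctx_len, forb_ptr, forb_code, forb_len,
                   crc_table, win_start, win_end, y_idx,
                   framed_len, M, max_iterations, tail_slack,
                   m_match, m_sub, m_del, m_ins, use_del, use_ins,
                   merge, seen):
    ny = y_idx.shape[0]
    nwindows = win_start.shape[0]
    cap = M + 64
    nd_low = np.zeros(cap, dtype=np.int64)
    nd_high = np.zeros(cap, dtype=np.int64)
    nd_pend = np.zeros(cap, dtype=np.int64)
    nd_bitbuf = np.zeros(cap, dtype=np.int64)
    nd_bitcnt = np.zeros(cap, dtype=np.int64)
    nd_nbytes = np.zeros(cap, dtype=np.int64)
    nd_framed = np.zeros((cap, framed_len), dtype=np.uint8)
    nd_phase = np.zeros(cap, dtype=np.int64)
    nd_prefix = np.zeros(cap, dtype=np.int64)
    nd_ctx = np.zeros(cap, dtype=np.int64)
    nd_words = np.zeros(cap, dtype=np.int64)   # completed codewords so far
    nd_v = np.zeros(cap, dtype=np.int64)
    nd_metric = np.zeros(cap, dtype=np.float64)
    nd_nwin = np.zeros(cap, dtype=np.int64)
    nd_ver = np.zeros(cap, dtype=np.int64)
    nd_alive = np.zeros(cap, dtype=np.uint8)

    free = np.empty(cap, dtype=np.int64)
    for i in range(cap):
        free[i] = cap - 1 - i
    nfree = cap

    heap_cap = 8 * cap + 256
    bh_met = np.empty(heap_cap, dtype=np.float64)
    bh_seq = np.empty(heap_cap, dtype=np.int64)
    bh_slot = np.empty(heap_cap, dtype=np.int64)
    bh_ver = np.empty(heap_cap, dtype=np.int64)
    bh_size = 0
    wh_met = np.empty(heap_cap, dtype=np.float64)
    wh_seq = np.empty(heap_cap, dtype=np.int64)
    wh_slot = np.empty(heap_cap, dtype=np.int64)
    wh_ver = np.empty(heap_cap, dtype=np.int64)
    wh_size = 0

    ctx_mask = (np.int64(1) << (2 * ctx_len)) - 1 if ctx_len > 0 else np.int64(0)
    roll_mask = (np.int64(1) << (2 * (ctx_len + n))) - 1

    slot = free[nfree - 1]
    nfree -= 1
    nd_low[slot] = 0
    nd_high[slot] = _FULL - 1
    nd_ver[slot] += 1
    nd_alive[slot] = 1
    bh_size = _heap_push(bh_met, bh_seq, bh_slot, bh_ver, bh_size,
                         0.0, 0, slot, nd_ver[slot], True)
    wh_size = _heap_push(wh_met, wh_seq, wh_slot, wh_ver, wh_size,
                         0.0, 0, slot, nd_ver[slot], False)
    seq_counter = 1
    alive = 1

    iterations = 0
    crc_failures = 0
    out = np.zeros(framed_len, dtype=np.uint8)
    counts = np.empty(4, dtype=np.int64)
    newbytes = np.empty(framed_len + 8, dtype=np.uint8)
    nb_cap = framed_len + 8

    while alive > 0 and iterations < max_iterations:
        slot = -1
        while bh_size > 0:
            s, ver, bh_size = _heap_pop(bh_met, bh_seq, bh_slot, bh_ver,
                                        bh_size, True)
            if nd_alive[s] == 1 and nd_ver[s] == ver:
                slot = s
                break
        if slot < 0:
            break
        nd_alive[slot] = 0
        alive -= 1

        if nd_nbytes[slot] >= framed_len:
            if nd_v[slot] >= ny - tail_slack:
                for i in range(framed_len):
                    out[i] = nd_framed[slot, i]
                return 1, nd_metric[slot], iterations, crc_failures, out
            free[nfree] = slot
            nfree += 1
            continue

        iterations += 1
        phase = nd_phase[slot]
        prefix = nd_prefix[slot]
        shift = 2 * (n - phase - 1)
        base = prefix << 2
        prev = np.searchsorted(codes, np.uint64(base << shift))
        for b in range(4):
            nxt = np.searchsorted(codes, np.uint64((base + b + 1) << shift))
            counts[b] = nxt - prev
            prev = nxt
        if ctx_len > 0 and nd_words[slot] > 0:
            if phase == 0:
                ctx = nd_ctx[slot] & ctx_mask
                for fi in range(forb_ptr[ctx], forb_ptr[ctx + 1]):
                    fcode = forb_code[fi]
                    flen = forb_len[fi]
                    b0 = fcode >> (2 * (flen - 1))
                    counts[b0] -= _range_count(codes, fcode, flen, n)
            else:
                wctx = (nd_ctx[slot] >> (2 * phase)) & ctx_mask
                for fi in range(forb_ptr[wctx], forb_ptr[wctx + 1]):
                    fcode = forb_code[fi]
                    flen = forb_len[fi]
                    if flen > phase and (fcode >> (2 * (flen - phase))) == prefix:
                        b0 = (fcode >> (2 * (flen - phase - 1))) & 3
                        counts[b0] -= _range_count(codes, fcode, flen, n)
        total = counts[0] + counts[1] + counts[2] + counts[3]
        if total <= 0:
            free[nfree] = slot
            nfree += 1
            continue

        v = nd_v[slot]
        has_y = v < ny
        yv = y_idx[v] if has_y else np.int8(-1)
        parent_metric = nd_metric[slot]

        clo = 0
        for b in range(4):
            cb = counts[b]
            if cb == 0:
                continue
            chi = clo + cb
            span = nd_high[slot] - nd_low[slot] + 1
            high = nd_low[slot] + span * chi // total - 1
            low = nd_low[slot] + span * clo // total
            clo = chi
            pend = nd_pend[slot]
            bitbuf = nd_bitbuf[slot]
            bitcnt = nd_bitcnt[slot]
            nbytes = nd_nbytes[slot]
            nb_new = 0
            while True:
                if high < _HALF:
                    bit = 0
                    inv = 1
                elif low >= _HALF:
                    bit = 1
                    inv = 0
                    low -= _HALF
                    high -= _HALF
                elif low >= _QUARTER and high < _THREEQ:
                    pend += 1
                    low -= _QUARTER
                    high -= _QUARTER
                    low <<= 1
                    high = (high << 1) | 1
                    continue
                else:
                    break
                bitbuf = (bitbuf << 1) | bit
                bitcnt += 1
                if bitcnt == 8:
                    if nb_new < nb_cap:
                        newbytes[nb_new] = bitbuf
                        nb_new += 1
                    bitbuf = 0
                    bitcnt = 0
                while pend > 0:
                    bitbuf = (bitbuf << 1) | inv
                    bitcnt += 1
                    if bitcnt == 8:
                        if nb_new < nb_cap:
                            newbytes[nb_new] = bitbuf
                            nb_new += 1
                        bitbuf = 0
                        bitcnt = 0
                    pend -= 1
                low <<= 1
                high = (high << 1) | 1
            total_bytes = nbytes + nb_new
            if total_bytes > framed_len:
                total_bytes = framed_len  # bits beyond the frame are moot
                nb_new = total_bytes - nbytes
            nwin = nd_nwin[slot]
            ok = True
            if nb_new > 0 and nwin < nwindows:
                while nwin < nwindows and win_end[nwin] < total_bytes:
                    end = win_end[nwin]
                    reg = np.uint8(0)
                    for j in range(win_start[nwin], end):
                        byt = nd_framed[slot, j] if j < nbytes else newbytes[j - nbytes]
                        reg = crc_table[reg ^ byt]
                    crcb = nd_framed[slot, end] if end < nbytes else newbytes[end - nbytes]
                    if reg != crcb:
                        ok = False
                        break
                    nwin += 1
            if not ok:
                crc_failures += 1
                continue
            if phase == n - 1:
                cphase = 0
                cprefix = 0
                cwords = nd_words[slot] + 1
            else:
                cphase = phase + 1
                cprefix = (prefix << 2) | b
                cwords = nd_words[slot]
            cctx = ((nd_ctx[slot] << 2) | b) & roll_mask
            prior = np.log2(cb / total)

            # equivalent-state hash shared by the match/del pair (they differ
            # only in the channel position, mixed in per child below)
            h0 = _FNV_OFFSET
            if merge:
                h0 = (h0 ^ np.uint64(low)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(high)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(pend)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(bitbuf)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(bitcnt)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(cphase)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(cprefix)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(cctx & ctx_mask)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(cwords > 0)) * _FNV_PRIME
                h0 = (h0 ^ np.uint64(total_bytes)) * _FNV_PRIME
                for j in range(nbytes):
                    h0 = (h0 ^ np.uint64(nd_framed[slot, j])) * _FNV_PRIME
                for j in range(nb_new):
                    h0 = (h0 ^ np.uint64(newbytes[j])) * _FNV_PRIME

            for kind in range(2):
                if kind == 0:
                    if not has_y:
                        continue
                    delta = (m_match if b == yv else m_sub) + prior
                    cv = v + 1
                else:
                    if not use_del:
                        continue
                    delta = m_del + prior
                    cv = v
                cmetric = parent_metric + delta
                if merge:
                    hk = (h0 ^ np.uint64(cv + 1)) * _FNV_PRIME
                    if hk in seen and seen[hk] >= cmetric - 1e-12:
                        continue
                    seen[hk] = cmetric
                cs = free[nfree - 1]
                nfree -= 1
                nd_low[cs] = low
                nd_high[cs] = high
                nd_pend[cs] = pend
                nd_bitbuf[cs] = bitbuf
                nd_bitcnt[cs] = bitcnt
                for j in range(nbytes):
                    nd_framed[cs, j] = nd_framed[slot, j]
                for j in range(nb_new):
                    nd_framed[cs, nbytes + j] = newbytes[j]
                nd_nbytes[cs] = total_bytes
                nd_phase[cs] = cphase
                nd_prefix[cs] = cprefix
                nd_ctx[cs] = cctx
                nd_words[cs] = cwords
                nd_v[cs] = cv
                nd_metric[cs] = cmetric
                nd_nwin[cs] = nwin
                nd_ver[cs] += 1
                nd_alive[cs] = 1
                if bh_size + 1 >= heap_cap:
                    bh_size = _heap_compact(bh_met, bh_seq, bh_slot, bh_ver,
                                            bh_size, nd_alive, nd_ver, True)
                if wh_size + 1 >= heap_cap:
                    wh_size = _heap_compact(wh_met, wh_seq, wh_slot, wh_ver,
                                            wh_size, nd_alive, nd_ver, False)
                bh_size = _heap_push(bh_met, bh_seq, bh_slot, bh_ver, bh_size,
                                     nd_metric[cs], seq_counter, cs, nd_ver[cs], True)
                wh_size = _heap_push(wh_met, wh_seq, wh_slot, wh_ver, wh_size,
                                     nd_metric[cs], seq_counter, cs, nd_ver[cs], False)
                seq_counter += 1
                alive += 1

        ins_ok = use_ins and has_y and v + 1 < ny
        if ins_ok:
            ynext = y_idx[v + 1]
            if ynext >= 0 and counts[ynext] > 0:
                imetric = parent_metric + m_ins
                skip_ins = False
                if merge:
                    hi = _FNV_OFFSET
                    hi = (hi ^ np.uint64(nd_low[slot])) * _FNV_PRIME
                    hi = (hi ^ np.uint64(nd_high[slot])) * _FNV_PRIME
                    hi = (hi ^ np.uint64(nd_pend[slot])) * _FNV_PRIME
                    hi = (hi ^ np.uint64(nd_bitbuf[slot])) * _FNV_PRIME
                    hi = (hi ^ np.uint64(nd_bitcnt[slot])) * _FNV_PRIME
                    hi = (hi ^ np.uint64(phase)) * _FNV_PRIME
                    hi = (hi ^ np.uint64(prefix)) * _FNV_PRIME
                    hi = (hi ^ np.uint64(nd_ctx[slot] & ctx_mask)) * _FNV_PRIME
                    hi = (hi ^ np.uint64(nd_words[slot] > 0)) * _FNV_PRIME
                    hi = (hi ^ np.uint64(nd_nbytes[slot])) * _FNV_PRIME
                    for j in range(nd_nbytes[slot]):
                        hi = (hi ^ np.uint64(nd_framed[slot, j])) * _FNV_PRIME
                    hi = (hi ^ np.uint64(v + 2)) * _FNV_PRIME
                    if hi in seen and seen[hi] >= imetric - 1e-12:
                        skip_ins = True
                    else:
                        seen[hi] = imetric
            else:
                skip_ins = True
        else:
            skip_ins = True
        if not skip_ins:
                cs = free[nfree - 1]
                nfree -= 1
                nd_low[cs] = nd_low[slot]
                nd_high[cs] = nd_high[slot]
                nd_pend[cs] = nd_pend[slot]
                nd_bitbuf[cs] = nd_bitbuf[slot]
                nd_bitcnt[cs] = nd_bitcnt[slot]
                for j in range(nd_nbytes[slot]):
                    nd_framed[cs, j] = nd_framed[slot, j]
                nd_nbytes[cs] = nd_nbytes[slot]
                nd_phase[cs] = phase
                nd_prefix[cs] = prefix
                nd_ctx[cs] = nd_ctx[slot]
                nd_words[cs] = nd_words[slot]
                nd_v[cs] = v + 1
                nd_metric[cs] = parent_metric + m_ins
                nd_nwin[cs] = nd_nwin[slot]
                nd_ver[cs] += 1
                nd_alive[cs] = 1
                if bh_size + 1 >= heap_cap:
                    bh_size = _heap_compact(bh_met, bh_seq, bh_slot, bh_ver,
                                            bh_size, nd_alive, nd_ver, True)
                if wh_size + 1 >= heap_cap:
                    wh_size = _heap_compact(wh_met, wh_seq, wh_slot, wh_ver,
                                            wh_size, nd_alive, nd_ver, False)
                bh_size = _heap_push(bh_met, bh_seq, bh_slot, bh_ver, bh_size,
                                     nd_metric[cs], seq_counter, cs,
                                     nd_ver[cs], True)
                wh_size = _heap_push(wh_met, wh_seq, wh_slot, wh_ver, wh_size,
                                     nd_metric[cs], seq_counter, cs,
                                     nd_ver[cs], False)
                seq_counter += 1
                alive += 1

        free[nfree] = slot
        nfree += 1
        while alive > M:
            while wh_size > 0:
                ws, wver, wh_size = _heap_pop(wh_met, wh_seq, wh_slot, wh_ver,
                                              wh_size, False)
                if nd_alive[ws] == 1 and nd_ver[ws] == wver:
                    nd_alive[ws] = 0
                    alive -= 1
                    free[nfree] = ws
                    nfree += 1
                    break

    return 0, -1.0e300, iterations, crc_failures, out
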