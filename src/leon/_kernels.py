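"""Numba-compiled kernels shared by the counting, graph, codec and entropy layers.

Everything here operates on flat numpy buffers so that whole blocks of reads are
processed per call.  Conventions:

* bases are 2-bit codes A=0, C=1, G=2, T=3; the value 4 marks an ``N`` in raw
  code buffers (kernels that walk the graph treat 4 as A, kernels that count
  kmers skip windows containing it),
* kmers are packed into a single ``uint64`` with the leftmost base in the
  most-significant bit pair (k <= 31 on this fast path),
* Bloom positions come from two splitmix64-style base hashes combined with the
  Kirsch-Mitzenmacher scheme ``g_i = h1 + i*h2 mod m``.
"""

import numpy as np
from numba import njit

U64 = np.uint64

_C1 = U64(0x9E3779B97F4A7C15)
_C2 = U64(0xBF58476D1CE4E5B9)
_C3 = U64(0x94D049BB133111EB)

_M2 = U64(0x3333333333333333)
_M4 = U64(0x0F0F0F0F0F0F0F0F)
_M8 = U64(0x00FF00FF00FF00FF)
_M16 = U64(0x0000FFFF0000FFFF)

RC_TOP = U64(1 << 24)
RC_BOT32 = U64(0xFFFFFFFF)


@njit(cache=True, inline="always")
def _hash64(x, seed):
    z = (x + seed) * _C1
    z ^= z >> U64(30)
    z *= _C2
    z ^= z >> U64(27)
    z *= _C3
    z ^= z >> U64(31)
    return z


@njit(cache=True, inline="always")
def _revcomp(x, k):
    x = ~x
    x = ((x >> U64(2)) & _M2) | ((x & _M2) << U64(2))
    x = ((x >> U64(4)) & _M4) | ((x & _M4) << U64(4))
    x = ((x >> U64(8)) & _M8) | ((x & _M8) << U64(8))
    x = ((x >> U64(16)) & _M16) | ((x & _M16) << U64(16))
    x = (x >> U64(32)) | (x << U64(32))
    return x >> U64(64 - 2 * k)


@njit(cache=True, inline="always")
def _canon(x, k):
    y = _revcomp(x, k)
    return x if x < y else y


@njit(cache=True, inline="always")
def _bloom_get(bits, m, h, s1, s2, key):
    p = _hash64(key, s1) % m
    step = _hash64(key, s2) % m
    if step == U64(0):
        step = U64(1)
    for _ in range(h):
        if (bits[p >> U64(3)] >> (p & U64(7))) & 1 == 0:
            return False
        p = (p + step) % m
    return True


@njit(cache=True, inline="always")
def _bloom_set(bits, m, h, s1, s2, key):
    p = _hash64(key, s1) % m
    step = _hash64(key, s2) % m
    if step == U64(0):
        step = U64(1)
    for _ in range(h):
        bits[p >> U64(3)] |= np.uint8(1 << (p & U64(7)))
        p = (p + step) % m


@njit(cache=True)
def bloom_insert_many(bits, m, h, s1, s2, keys):
    for i in range(keys.size):
        _bloom_set(bits, m, h, s1, s2, keys[i])


@njit(cache=True)
def bloom_contains_many(bits, m, h, s1, s2, keys):
    out = np.empty(keys.size, np.uint8)
    for i in range(keys.size):
        out[i] = 1 if _bloom_get(bits, m, h, s1, s2, keys[i]) else 0
    return out


@njit(cache=True)
def bloom_contains_canon(bits, m, h, s1, s2, k, kmers):
    out = np.empty(kmers.size, np.uint8)
    for i in range(kmers.size):
        out[i] = 1 if _bloom_get(bits, m, h, s1, s2, _canon(kmers[i], k)) else 0
    return out


@njit(cache=True)
def extract_canonical(codes, starts, ends, k, out):
    """Emit the canonical kmer of every N-free window of every read.

    ``codes`` may contain 4 (= N); any window overlapping one is skipped.
    Returns the number of kmers written to ``out``.
    """
    n = 0
    kmask = (U64(1) << U64(2 * k)) - U64(1)
    shift_hi = U64(2 * (k - 1))
    for r in range(starts.size):
        s = starts[r]
        e = ends[r]
        if e - s < k:
            continue
        fwd = U64(0)
        rc = U64(0)
        valid = 0
        for i in range(s, e):
            c = codes[i]
            if c > 3:
                valid = 0
                continue
            cc = U64(c)
            fwd = ((fwd << U64(2)) | cc) & kmask
            rc = (rc >> U64(2)) | ((U64(3) - cc) << shift_hi)
            valid += 1
            if valid >= k:
                out[n] = fwd if fwd < rc else rc
                n += 1
    return n


@njit(cache=True)
def forward_kmers(codes, k):
    """All forward kmers of one read (N masked to A).  Requires len >= k."""
    l = codes.size
    nk = l - k + 1
    km = np.empty(nk, np.uint64)
    kmask = (U64(1) << U64(2 * k)) - U64(1)
    fwd = U64(0)
    for i in range(l):
        c = codes[i]
        if c > 3:
            c = 0
        fwd = ((fwd << U64(2)) | U64(c)) & kmask
        if i >= k - 1:
            km[i - k + 1] = fwd
    return km


@njit(cache=True)
def encode_block(codes, starts, ends, k, bits, m, h, s1, s2,
                 adict, dict_size, km,
                 mode, anchor_idx, anchor_pos,
                 rn_counts, re_counts, ln_counts, le_counts,
                 right_nucs, right_errs, left_nucs, left_errs,
                 raw_codes, new_anchors):
    """Anchor selection + bifurcation-list walk for a block of reads.

    The walk keeps a current graph-side kmer.  At each step the four successors
    (or predecessors, on the left leg) of the current kmer are probed:

    * the read's base is a present successor and it is the only one: simple
      path, nothing emitted;
    * the read's base is present among >= 2 successors: true bifurcation, the
      base alone is emitted;
    * the read's base is absent: emitted together with its read position
      (typically a sequencing error).  When exactly one successor exists the
      walk continues on that corrected graph path, so an isolated substitution
      costs a single event instead of cascading for k steps.

    Returns (dict_size, n_rn, n_re, n_ln, n_le, n_raw, n_new).
    """
    nr = starts.size
    kmask = (U64(1) << U64(2 * k)) - U64(1)
    shift_hi = U64(2 * (k - 1))
    n_rn = 0
    n_re = 0
    n_ln = 0
    n_le = 0
    n_raw = 0
    n_new = 0
    for r in range(nr):
        s = starts[r]
        e = ends[r]
        l = e - s
        rn0 = n_rn
        re0 = n_re
        ln0 = n_ln
        le0 = n_le
        anchor_idx[r] = 0
        anchor_pos[r] = 0
        rn_counts[r] = 0
        re_counts[r] = 0
        ln_counts[r] = 0
        le_counts[r] = 0
        nk = l - k + 1
        a = -1
        aidx = -1
        if l >= k:
            fwd = U64(0)
            for i in range(l):
                c = codes[s + i]
                if c > 3:
                    c = 0
                fwd = ((fwd << U64(2)) | U64(c)) & kmask
                if i >= k - 1:
                    km[i - k + 1] = fwd
            fsolid = -1
            for i in range(nk):
                key = km[i]
                if key in adict:
                    a = i
                    aidx = adict[key]
                    break
                if fsolid < 0 and _bloom_get(bits, m, h, s1, s2, _canon(key, k)):
                    fsolid = i
            if a < 0 and fsolid >= 0:
                a = fsolid
                aidx = dict_size
                adict[km[a]] = dict_size
                new_anchors[n_new] = km[a]
                n_new += 1
                dict_size += 1
        if a < 0:
            mode[r] = 1
            for i in range(s, e):
                c = codes[i]
                raw_codes[n_raw] = 0 if c > 3 else c
                n_raw += 1
            continue
        mode[r] = 0
        anchor_idx[r] = aidx
        anchor_pos[r] = a
        # right leg
        cur = km[a]
        for i in range(a, nk - 1):
            c = codes[s + i + k]
            if c > 3:
                c = 0
            base = (cur << U64(2)) & kmask
            nb = 0
            only = U64(0)
            present = False
            for b in range(4):
                succ = base | U64(b)
                if _bloom_get(bits, m, h, s1, s2, _canon(succ, k)):
                    nb += 1
                    only = succ
                    if b == c:
                        present = True
            cand = base | U64(c)
            if present:
                if nb > 1:
                    right_nucs[n_rn] = c
                    n_rn += 1
                cur = cand
            else:
                right_nucs[n_rn] = c
                n_rn += 1
                right_errs[n_re] = i + k
                n_re += 1
                cur = only if nb == 1 else cand
        # left leg
        cur = km[a]
        for j in range(a, 0, -1):
            c = codes[s + j - 1]
            if c > 3:
                c = 0
            low = cur >> U64(2)
            nb = 0
            only = U64(0)
            present = False
            for b in range(4):
                pred = (U64(b) << shift_hi) | low
                if _bloom_get(bits, m, h, s1, s2, _canon(pred, k)):
                    nb += 1
                    only = pred
                    if b == c:
                        present = True
            cand = (U64(c) << shift_hi) | low
            if present:
                if nb > 1:
                    left_nucs[n_ln] = c
                    n_ln += 1
                cur = cand
            else:
                left_nucs[n_ln] = c
                n_ln += 1
                left_errs[n_le] = j - 1
                n_le += 1
                cur = only if nb == 1 else cand
        rn_counts[r] = n_rn - rn0
        re_counts[r] = n_re - re0
        ln_counts[r] = n_ln - ln0
        le_counts[r] = n_le - le0
    return dict_size, n_rn, n_re, n_ln, n_le, n_raw, n_new


@njit(cache=True)
def decode_block(out_codes, starts, ends, k, bits, m, h, s1, s2,
                 dict_entries, mode, anchor_idx, anchor_pos,
                 re_counts, le_counts,
                 right_nucs, right_errs, left_nucs, left_errs,
                 raw_codes):
    """Mirror of :func:`encode_block`.  Returns 0 on success, >0 on corruption."""
    nr = starts.size
    kmask = (U64(1) << U64(2 * k)) - U64(1)
    shift_hi = U64(2 * (k - 1))
    rn = 0
    re = 0
    ln = 0
    le = 0
    raw = 0
    for r in range(nr):
        s = starts[r]
        e = ends[r]
        l = e - s
        if mode[r] == 1:
            if raw + l > raw_codes.size:
                return 1
            for i in range(l):
                out_codes[s + i] = raw_codes[raw + i]
            raw += l
            continue
        if l < k:
            return 2
        nk = l - k + 1
        a = anchor_pos[r]
        ai = anchor_idx[r]
        if a < 0 or a > nk - 1:
            return 3
        if ai < 0 or ai >= dict_entries.size:
            return 4
        akm = dict_entries[ai]
        for j in range(k):
            out_codes[s + a + j] = np.uint8((akm >> U64(2 * (k - 1 - j))) & U64(3))
        # right leg
        cur = akm
        er = re_counts[r]
        for i in range(a, nk - 1):
            pos = i + k
            base = (cur << U64(2)) & kmask
            nb = 0
            only = U64(0)
            onlyb = 0
            for b in range(4):
                succ = base | U64(b)
                if _bloom_get(bits, m, h, s1, s2, _canon(succ, k)):
                    nb += 1
                    only = succ
                    onlyb = b
            if er > 0 and re < right_errs.size and right_errs[re] == pos:
                if rn >= right_nucs.size:
                    return 5
                c = right_nucs[rn]
                rn += 1
                re += 1
                er -= 1
                cur = only if nb == 1 else (base | U64(c))
            elif nb == 1:
                c = onlyb
                cur = only
            elif nb > 1:
                if rn >= right_nucs.size:
                    return 5
                c = right_nucs[rn]
                rn += 1
                cur = base | U64(c)
            else:
                return 6
            out_codes[s + pos] = np.uint8(c)
        if er != 0:
            return 7
        # left leg
        cur = akm
        el = le_counts[r]
        for j in range(a, 0, -1):
            pos = j - 1
            low = cur >> U64(2)
            nb = 0
            only = U64(0)
            onlyb = 0
            for b in range(4):
                pred = (U64(b) << shift_hi) | low
                if _bloom_get(bits, m, h, s1, s2, _canon(pred, k)):
                    nb += 1
                    only = pred
                    onlyb = b
            if el > 0 and le < left_errs.size and left_errs[le] == pos:
                if ln >= left_nucs.size:
                    return 8
                c = left_nucs[ln]
                ln += 1
                le += 1
                el -= 1
                cur = only if nb == 1 else ((U64(c) << shift_hi) | low)
            elif nb == 1:
                c = onlyb
                cur = only
            elif nb > 1:
                if ln >= left_nucs.size:
                    return 8
                c = left_nucs[ln]
                ln += 1
                cur = (U64(c) << shift_hi) | low
            else:
                return 9
            out_codes[s + pos] = np.uint8(c)
        if el != 0:
            return 10
    return 0


@njit(cache=True)
def solid_coverage_block(codes, starts, ends, k, bits, m, h, s1, s2, wbuf, cov):
    """Per-base count of overlapping graph-member kmers, for a block of reads."""
    for r in range(starts.size):
        s = starts[r]
        e = ends[r]
        l = e - s
        if l < k:
            for i in range(s, e):
                cov[i] = 0
            continue
        nk = l - k + 1
        kmask = (U64(1) << U64(2 * k)) - U64(1)
        fwd = U64(0)
        wbuf[0] = 0
        for i in range(l):
            c = codes[s + i]
            if c > 3:
                c = 0
            fwd = ((fwd << U64(2)) | U64(c)) & kmask
            if i >= k - 1:
                w = 1 if _bloom_get(bits, m, h, s1, s2, _canon(fwd, k)) else 0
                wbuf[i - k + 2] = wbuf[i - k + 1] + w
        for i in range(l):
            lo = i - k + 1
            if lo < 0:
                lo = 0
            hi = i
            if hi > nk - 1:
                hi = nk - 1
            cov[s + i] = np.int32(wbuf[hi + 1] - wbuf[lo])
    return 0


# ---------------------------------------------------------------------------
# Adaptive order-0 range coder (LZMA-style 32-bit renormalization).
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _shift_low(out, opos, low, cache, csize):
    if low < U64(0xFF000000) or low > RC_BOT32:
        carry = low >> U64(32)
        out[opos] = np.uint8((cache + carry) & U64(0xFF))
        opos += 1
        while csize > 1:
            out[opos] = np.uint8((U64(0xFF) + carry) & U64(0xFF))
            opos += 1
            csize -= 1
        csize = 0
        cache = (low >> U64(24)) & U64(0xFF)
    csize += 1
    low = (low << U64(8)) & RC_BOT32
    return opos, low, cache, csize


@njit(cache=True)
def rc_encode(symbols, counts, inc, limit):
    """Adaptive order-0 range encode of ``symbols``; ``counts`` is mutated."""
    n = symbols.size
    nsym = counts.size
    out = np.empty(3 * n + 64, np.uint8)
    opos = 0
    low = U64(0)
    rng = RC_BOT32
    cache = U64(0)
    csize = 1
    total = 0
    for j in range(nsym):
        total += counts[j]
    for t in range(n):
        sym = symbols[t]
        cum = 0
        for j in range(sym):
            cum += counts[j]
        f = counts[sym]
        r = rng // U64(total)
        low = low + U64(cum) * r
        rng = U64(f) * r
        while rng < RC_TOP:
            opos, low, cache, csize = _shift_low(out, opos, low, cache, csize)
            rng = rng << U64(8)
        counts[sym] += inc
        total += inc
        if total >= limit:
            total = 0
            for j in range(nsym):
                counts[j] = (counts[j] + 1) >> 1
                total += counts[j]
    for _ in range(5):
        opos, low, cache, csize = _shift_low(out, opos, low, cache, csize)
    return out[:opos].copy()


@njit(cache=True)
def rc_decode(data, n, counts, inc, limit):
    """Inverse of :func:`rc_encode`.  Returns (symbols, bytes_consumed)."""
    nsym = counts.size
    out = np.empty(n, np.uint32)
    nd = data.size
    pos = 1  # first byte is the encoder's dummy cache byte
    code = U64(0)
    for _ in range(4):
        b = U64(data[pos]) if pos < nd else U64(0)
        code = (code << U64(8)) | b
        pos += 1
    rng = RC_BOT32
    total = 0
    for j in range(nsym):
        total += counts[j]
    for t in range(n):
        r = rng // U64(total)
        v = code // r
        if v >= U64(total):
            v = U64(total - 1)
        cum = 0
        sym = 0
        while cum + counts[sym] <= v:
            cum += counts[sym]
            sym += 1
        code = code - U64(cum) * r
        rng = U64(counts[sym]) * r
        out[t] = sym
        counts[sym] += inc
        total += inc
        if total >= limit:
            total = 0
            for j in range(nsym):
                counts[j] = (counts[j] + 1) >> 1
                total += counts[j]
        while rng < RC_TOP:
            b = U64(data[pos]) if pos < nd else U64(0)
            code = ((code << U64(8)) | b) & RC_BOT32
            rng = rng << U64(8)
            pos += 1
    return out, pos


# ---------------------------------------------------------------------------
# LEB128 varints.
# ---------------------------------------------------------------------------

@njit(cache=True)
def varint_encode(values):
    out = np.empty(10 * values.size + 1, np.uint8)
    n = 0
    for i in range(values.size):
        v = values[i]
        while True:
            b = v & 0x7F
            v >>= 7
            if v != 0:
                out[n] = np.uint8(b | 0x80)
            else:
                out[n] = np.uint8(b)
            n += 1
            if v == 0:
                break
    return out[:n].copy()


@njit(cache=True)
def varint_decode(data, n):
    """Decode ``n`` LEB128 values.  Returns (values, consumed, ok)."""
    out = np.zeros(n, np.int64)
    pos = 0
    nd = data.size
    for i in range(n):
        shift = 0
        v = 0
        while True:
            if pos >= nd or shift > 63:
                return out, pos, False
            b = data[pos]
            pos += 1
            v |= np.int64(b & 0x7F) << shift
            if b & 0x80 == 0:
                break
            shift += 7
        out[i] = v
    return out, pos, True
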