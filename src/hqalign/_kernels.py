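"""Numba kernels for minimizer extraction, anchor chaining, banded affine
alignment, and read error simulation.

All kernels are deterministic; sequences arrive as small-integer uint8
arrays so the same code serves the 4-letter nucleotide alphabet and the
L-letter quantized alphabet.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2 ** 28)

# traceback state codes
_M, _IX, _IY = 0, 1, 2
# per-base op codes emitted by traceback
OP_MATCH, OP_MISMATCH, OP_INS, OP_DEL = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _mix64(x):
    # splitmix64 finalizer (unsigned, logical shifts): invertible 64-bit hash
    z = np.uint64(x)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    # 62-bit range keeps every hash strictly below the invalid sentinel 2^62
    return np.int64(z & np.uint64(0x3FFFFFFFFFFFFFFF))


@njit(cache=True)
def minimizers(codes, k, w, alphabet_size):
    """(hashes, positions) of all window minimizers of ``codes``.

    Every window of w consecutive k-mers contributes each k-mer achieving
    the minimum hash in that window.  k-mers containing symbols outside
    the alphabet are skipped.
    """
    n = len(codes)
    nk = n - k + 1
    if nk < 1:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int32),
        )
    hashes = np.empty(nk, dtype=np.int64)
    INVALID = np.int64(2 ** 62)
    packed = np.int64(0)
    base = np.int64(alphabet_size)
    mod = base ** np.int64(k)
    bad_run = 0  # symbols >= alphabet_size within current k-mer
    for i in range(n):
        c = np.int64(codes[i])
        if c >= base:
            bad_run = k
            c = 0
        elif bad_run > 0:
            bad_run -= 1
        packed = (packed * base + c) % mod
        if i >= k - 1:
            if bad_run > 0:
                hashes[i - k + 1] = INVALID
            else:
                hashes[i - k + 1] = _mix64(packed)
    nw = nk - w + 1
    if nw < 1:
        nw = 1
    taken = np.zeros(nk, dtype=np.uint8)
    out_h = np.empty(nk, dtype=np.int64)
    out_p = np.empty(nk, dtype=np.int32)
    m = 0
    for s in range(nw):
        e = s + w
        if e > nk:
            e = nk
        mn = INVALID
        for j in range(s, e):
            if hashes[j] < mn:
                mn = hashes[j]
        if mn == INVALID:
            continue
        for j in range(s, e):
            if hashes[j] == mn and taken[j] == 0:
                taken[j] = 1
                out_h[m] = mn
                out_p[m] = j
                m += 1
    return out_h[:m], out_p[:m]


@njit(cache=True)
def chain_dp(qpos, tpos, max_gap, lookback, gap_scale, gap_cap):
    """Colinear chaining DP over anchors sorted by (tpos, qpos).

    score[i] = best chain score ending at anchor i; one point per anchor
    minus a diagonal-difference gap penalty per link.  Links require strict
    increase in both coordinates and gaps <= max_gap.
    """
    n = len(qpos)
    score = np.full(n, 1.0, dtype=np.float64)
    parent = np.full(n, -1, dtype=np.int32)
    for i in range(n):
        lo = i - lookback
        if lo < 0:
            lo = 0
        for j in range(i - 1, lo - 1, -1):
            dt = tpos[i] - tpos[j]
            dq = qpos[i] - qpos[j]
            if dt <= 0 or dq <= 0:
                continue
            if dt > max_gap or dq > max_gap:
                continue
            dd = dt - dq
            if dd < 0:
                dd = -dd
            pen = gap_scale * dd
            if pen > gap_cap:
                pen = gap_cap
            s = score[j] + 1.0 - pen
            if s > score[i]:
                score[i] = s
                parent[i] = j
    return score, parent


@njit(cache=True)
def banded_affine(q, t, lo, hi, match, mismatch, gap_open, gap_extend, row_lo, row_hi):
    """Banded Gotoh alignment of the full query against target ``t`` with
    free leading/trailing target gaps ("glocal").

    ``lo[i]``/``hi[i]`` bound (half-open) the target columns considered at
    query row i, i = 0..m.  Returns (score, t_start, t_end, ops, touched)
    where ops is the per-base op string (codes OP_*) and touched flags a
    traceback path hugging a band edge that is not a hard sequence limit,
    within rows [row_lo, row_hi] (outside the anchor-constrained stretch
    the path is free-ended and edge contact is meaningless).
    """
    m = len(q)
    nt_ = len(t)
    # row offsets into flat band storage
    offs = np.empty(m + 2, dtype=np.int64)
    offs[0] = 0
    for i in range(m + 1):
        wdt = hi[i] - lo[i]
        if wdt < 1:
            wdt = 1
        offs[i + 1] = offs[i] + wdt
    total = offs[m + 1]
    tb = np.zeros(total, dtype=np.uint8)
    # rolling score rows (only the traceback is kept for every cell)
    maxw = 1
    for i in range(m + 1):
        wdt = hi[i] - lo[i]
        if wdt > maxw:
            maxw = wdt
    prevM = np.full(maxw, NEG, dtype=np.int32)
    prevX = np.full(maxw, NEG, dtype=np.int32)
    prevY = np.full(maxw, NEG, dtype=np.int32)
    curM = np.full(maxw, NEG, dtype=np.int32)
    curX = np.full(maxw, NEG, dtype=np.int32)
    curY = np.full(maxw, NEG, dtype=np.int32)
    # row 0: free leading target gap
    for j in range(hi[0] - lo[0]):
        prevM[j] = 0
        prevX[j] = NEG
        prevY[j] = NEG
    go_ge = gap_open + gap_extend
    for i in range(1, m + 1):
        qc = q[i - 1]
        row = offs[i]
        li = lo[i]
        hi_i = hi[i]
        plo = lo[i - 1]
        phi = hi[i - 1]
        for jj in range(hi_i - li):
            j = li + jj
            # Ix: consume query only (vertical) from row i-1, same column
            best_x = NEG
            xb = np.uint8(0)
            pj = j - plo
            if 0 <= pj < phi - plo:
                a = prevM[pj] - go_ge
                b = prevX[pj] - gap_extend
                if a >= b:
                    best_x = a
                else:
                    best_x = b
                    xb = np.uint8(1)
            curX[jj] = best_x
            # Iy: consume target only (horizontal) from same row, col j-1
            best_y = NEG
            yb = np.uint8(0)
            if jj >= 1 and j >= 1:
                a = curM[jj - 1] - go_ge
                b = curY[jj - 1] - gap_extend
                if a >= b:
                    best_y = a
                else:
                    best_y = b
                    yb = np.uint8(1)
            curY[jj] = best_y
            # M: diagonal from row i-1, col j-1
            best_m = NEG
            mb = np.uint8(0)
            pj = j - 1 - plo
            if j >= 1 and 0 <= pj < phi - plo:
                a = prevM[pj]
                if prevX[pj] > a:
                    a = prevX[pj]
                    mb = np.uint8(1)
                if prevY[pj] > a:
                    a = prevY[pj]
                    mb = np.uint8(2)
                if a > NEG // 2:
                    s = match if qc == t[j - 1] else mismatch
                    best_m = a + s
            curM[jj] = best_m
            tb[row + jj] = mb | (xb << 2) | (yb << 3)
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY
    # best end state in last row (free trailing target gap); after the final
    # swap the last computed row lives in prev*
    best = NEG
    bj = lo[m]
    bstate = _M
    for jj in range(hi[m] - lo[m]):
        j = lo[m] + jj
        if prevM[jj] > best:
            best = prevM[jj]
            bj = j
            bstate = _M
        if prevX[jj] > best:
            best = prevX[jj]
            bj = j
            bstate = _IX
        if prevY[jj] > best:
            best = prevY[jj]
            bj = j
            bstate = _IY
    # traceback
    ops = np.empty(m + (nt_ if nt_ > m else m) + 4, dtype=np.uint8)
    nops = 0
    i = m
    j = bj
    state = bstate
    touched = False
    while i > 0:
        if row_lo <= i <= row_hi and (
            (j <= lo[i] and lo[i] > 0) or (j >= hi[i] - 1 and hi[i] < nt_ + 1)
        ):
            touched = True
        idx = offs[i] + (j - lo[i])
        code = tb[idx]
        if state == _M:
            ops[nops] = OP_MATCH if q[i - 1] == t[j - 1] else OP_MISMATCH
            nops += 1
            state = code & np.uint8(3)
            i -= 1
            j -= 1
        elif state == _IX:
            ops[nops] = OP_INS
            nops += 1
            state = _M if (code >> 2) & np.uint8(1) == 0 else _IX
            i -= 1
        else:
            ops[nops] = OP_DEL
            nops += 1
            state = _M if (code >> 3) & np.uint8(1) == 0 else _IY
            j -= 1
    t_start = j
    # strip trailing (query-end) deletions never produced: ends are free.
    out = ops[:nops][::-1].copy()
    return best, t_start, bj, out, touched


@njit(cache=True)
def _pack_first(codes, pos, Q):
    v = np.int64(0)
    for j in range(Q):
        v = v * 4 + np.int64(codes[pos + j])
    return v


@njit(cache=True)
def corrupt_read(
    codes,
    p_sub,
    p_ins,
    p_del,
    conf_weight,
    sub_table,
    Q,
    seed,
):
    """Apply a nanopore-like error process to an encoded read.

    Substitutions are drawn, with probability ``conf_weight``, from the
    alternatives of the current base that leave the local Q-mer (the
    window centered on the error) in the same quantization bin
    (``sub_table[qmer]`` lists those alternative center bases,
    -1-padded).  Insertions are uniform random bases; deletions drop the
    base.
    """
    np.random.seed(seed)
    n = len(codes)
    out = np.empty(n * 2 + 16, dtype=np.uint8)
    m = 0
    i = 0
    while i < n:
        if m >= len(out) - 2:
            break
        r = np.random.random()
        if r < p_del:
            i += 1
            continue
        elif r < p_del + p_ins:
            out[m] = np.uint8(np.random.randint(0, 4))
            m += 1
            continue
        elif r < p_del + p_ins + p_sub:
            old = codes[i]
            nb = -1
            c = Q // 2
            if np.random.random() < conf_weight and i - c >= 0 and i - c + Q <= n:
                w = _pack_first(codes, i - c, Q)
                nalt = 0
                for a in range(3):
                    if sub_table[w, a] >= 0:
                        nalt += 1
                if nalt > 0:
                    pick = np.random.randint(0, nalt)
                    c = 0
                    for a in range(3):
                        if sub_table[w, a] >= 0:
                            if c == pick:
                                nb = sub_table[w, a]
                                break
                            c += 1
            if nb < 0:
                nb = np.random.randint(0, 3)
                if nb >= old:
                    nb += 1
            out[m] = np.uint8(nb)
            m += 1
            i += 1
        else:
            out[m] = codes[i]
            m += 1
            i += 1
    return out[:m].copy()
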