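"""Generic minimizer seed-chain-extend aligner over a configurable finite
alphabet.

The same machinery aligns 4-letter nucleotide sequences (stage 1) and
L-letter quantized sequences (stage 2); only the alphabet size, minimizer
length and the query/reverse-query pair supplied by the caller differ.
Orientation is the caller's business: the aligner scores a forward and a
reverse query against the forward-indexed targets and reports strand per
record, because the quantized alphabet has no complement operation.

Alignment records use 0-based half-open coordinates; query coordinates
are reported on the original (forward) query orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from . import _kernels
from ._kernels import OP_DEL, OP_INS, OP_MATCH, OP_MISMATCH


class BandExceededError(RuntimeError):
    """Banded extension could not contain the optimal path within the band cap."""


@dataclass
class AlignParams:
    """Tunable knobs of the seed-chain-extend engine.

    Defaults are minimap2-like for nucleotide mode (k=15, w=10); quantized
    (ternary) mode uses k=18 with the same window.
    """

    k: int = 15
    w: int = 10
    alphabet_size: int = 4
    match: int = 2
    mismatch: int = -4
    # a high gap-open cost keeps SV-scale gaps contiguous: with a cheap
    # open, a long gap fragments around spurious few-base matches inside it
    gap_open: int = 24
    gap_extend: int = 2
    band_width: int = 50
    band_cap: int = 4096
    max_gap: int = 15000
    max_occ: int = 64
    min_chain_anchors: int = 3
    # predecessor window of the chaining DP; must be large enough to bridge
    # the dense many-to-many anchor blocks that tandem repeat arrays produce
    lookback: int = 192
    gap_scale: float = 0.01
    gap_cap: float = 2.0
    zdrop: int = 400
    zdrop_gap_cap: int = 30
    zdrop_gap_open: int = 4
    # per-base weights of the split/trim scans (decoupled from the DP
    # scoring so the same engine can align high-mismatch alphabets without
    # shredding structurally correct alignments)
    zdrop_match: float = 2.0
    zdrop_mismatch: float = -4.0
    trim_match: float = 2.0
    trim_mismatch: float = -2.0
    min_split: int = 100
    # unanchored read ends up to this long are carried through the banded
    # extension rather than soft-clipped; longer forced tails align as
    # low-identity soup and pollute the CIGAR evidence SV calling reads
    max_end_flank: int = 400
    max_records: int = 6
    max_chains: int = 10


def quantized_params(L: int = 3) -> AlignParams:
    """Parameters for quantized-domain alignment.

    The ternary minimizer length is 18.  Seeding is denser than in
    nucleotide mode (w=5, chains from 2 anchors): an error corrupts Q
    consecutive quantized symbols, so exact 18-mers survive more rarely
    than nucleotide 15-mers, and stage-2 alignment is confined to a small
    stage-1 region of interest where sparse seeds cannot be compensated by
    genome-wide context.  Scoring is rebalanced for the quantized error
    structure: a single base error corrupts up to Q quantized symbols, so a
    correct quantized alignment of a 10%-error read runs at ~30% symbol
    mismatch and must still accumulate positive score (match/mismatch
    4/-8 ~ a 2/-4 scheme scaled for the higher mismatch floor), while a
    long gap must stay cheaper per symbol than sliding through unrelated
    sequence, which in the autocorrelated ternary alphabet still agrees
    ~45% of the time (gap extend 2 < the ~2.6/symbol cost of such "soup").
    """
    return AlignParams(
        k=18,
        w=5,
        alphabet_size=L,
        min_chain_anchors=2,
        match=4,
        mismatch=-8,
        gap_open=32,
        gap_extend=2,
        # a correct quantized alignment of a very noisy read runs at ~50%
        # symbol mismatch — indistinguishable per-symbol from a wrong
        # placement — so split/trim scans are nearly inert in this mode
        # (contiguity is owed to the seeds and stage-1 guide anchors, and
        # inversions are cut out by rival chains, not score drops)
        zdrop=800,
        zdrop_mismatch=-1.5,
        trim_mismatch=-1.5,
    )


@dataclass
class Anchor:
    query_pos: int
    target_pos: int
    target_id: int = 0
    orientation: int = 0  # 0 forward, 1 reverse query


@dataclass
class Chain:
    score: float
    qpos: np.ndarray
    tpos: np.ndarray
    target_id: int = 0
    orientation: int = 0

    @property
    def n_anchors(self) -> int:
        return len(self.qpos)


@dataclass
class AlignmentRecord:
    query_name: str
    target_name: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    cigar: str
    score: int
    nm: int
    mapq: int = 0
    is_supplementary: bool = False
    domain: str = "nucleotide"
    query_length: int = 0
    n_anchors: int = 0
    # nucleotide-genome coordinates; equals (target_start, target_end) for
    # nucleotide records, back-translated for quantized records
    ref_start: int = 0
    ref_end: int = 0
    tags: dict = field(default_factory=dict)


class MinimizerIndex:
    """Sorted-array minimizer index over named integer-coded targets."""

    def __init__(self, names, target_codes, k, w, alphabet_size):
        if k < 1 or w < 1:
            raise ValueError("k and w must be >= 1")
        self.k, self.w, self.alphabet_size = k, w, alphabet_size
        self.names = list(names)
        self.targets = list(target_codes)
        self.target_lengths = np.array([len(t) for t in self.targets])
        hs, ps, ts = [], [], []
        for tid, codes in enumerate(self.targets):
            if np.any(codes >= alphabet_size) and alphabet_size == 4:
                pass  # N bases are skipped inside the kernel
            h, p = _kernels.minimizers(
                np.ascontiguousarray(codes, dtype=np.uint8), k, w, alphabet_size
            )
            hs.append(h)
            ps.append(p)
            ts.append(np.full(len(p), tid, dtype=np.int32))
        h = np.concatenate(hs) if hs else np.empty(0, dtype=np.int64)
        p = np.concatenate(ps) if ps else np.empty(0, dtype=np.int32)
        t = np.concatenate(ts) if ts else np.empty(0, dtype=np.int32)
        order = np.lexsort((p, t, h))
        self.hashes = h[order]
        self.positions = p[order]
        self.tids = t[order]

    def lookup(self, query_hashes, query_positions, max_occ):
        """Anchors (qpos, tpos, tid) for every query minimizer hit, hits of
        hashes occurring more than max_occ times dropped."""
        left = np.searchsorted(self.hashes, query_hashes, side="left")
        right = np.searchsorted(self.hashes, query_hashes, side="right")
        counts = right - left
        keep = (counts > 0) & (counts <= max_occ)
        left, right = left[keep], right[keep]
        qp = query_positions[keep]
        total = int(np.sum(right - left))
        if total == 0:
            z = np.empty(0, dtype=np.int32)
            return z, z, z
        reps = (right - left).astype(np.int64)
        qpos = np.repeat(qp, reps)
        # flat [l0..r0) ++ [l1..r1) ... without a per-hit python loop
        offsets = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
        idx = np.repeat(left, reps) + offsets
        return qpos.astype(np.int32), self.positions[idx], self.tids[idx]


def build_minimizer_index(targets, k, w, alphabet_size=4) -> MinimizerIndex:
    """Index named target sequences (dict name -> uint8 code array)."""
    return MinimizerIndex(
        list(targets.keys()), list(targets.values()), k, w, alphabet_size
    )


# ---------------------------------------------------------------------------
# chaining


def _extract_chains(qpos, tpos, score, parent, min_anchors, max_chains):
    order = np.argsort(-score, kind="stable")
    used = np.zeros(len(qpos), dtype=bool)
    chains = []
    for top in order:
        if used[top] or len(chains) >= max_chains:
            continue
        idxs = []
        i = int(top)
        while i >= 0 and not used[i]:
            idxs.append(i)
            used[i] = True
            i = int(parent[i])
        if len(idxs) < min_anchors:
            continue
        # a chain truncated at an already-claimed anchor only owns the score
        # accumulated past that anchor
        base = float(score[i]) if i >= 0 else 0.0
        idxs = idxs[::-1]
        chains.append(
            Chain(
                score=float(score[top]) - base,
                qpos=qpos[idxs],
                tpos=tpos[idxs],
            )
        )
    return chains


def chain_anchors(anchors, max_gap=15000, min_chain_anchors=3, params: AlignParams | None = None):
    """Chain a list of :class:`Anchor` (sorted by target then query position)
    into colinear scored chains, best score first."""
    p = params or AlignParams(max_gap=max_gap, min_chain_anchors=min_chain_anchors)
    if not anchors:
        return []
    qpos = np.array([a.query_pos for a in anchors], dtype=np.int32)
    tpos = np.array([a.target_pos for a in anchors], dtype=np.int32)
    order = np.lexsort((qpos, tpos))
    qpos, tpos = qpos[order], tpos[order]
    score, parent = _kernels.chain_dp(
        qpos, tpos, max_gap, p.lookback, p.gap_scale, p.gap_cap
    )
    chains = _extract_chains(qpos, tpos, score, parent, min_chain_anchors, p.max_chains)
    chains.sort(key=lambda c: (-c.score, int(c.tpos[0])))
    return chains


# ---------------------------------------------------------------------------
# banded extension


def _build_band(aq, at, m, mt, band):
    """Per-row target column bounds following the chain diagonal.

    aq/at are anchor coordinates relative to the query/target windows being
    aligned; rows 0..m (inclusive) correspond to query bases consumed.
    """
    rows = np.arange(m + 1)
    # extrapolate diagonally beyond the outermost anchors
    xs = np.concatenate(([-1], aq, [m + 1]))
    ys = np.concatenate(([at[0] - aq[0] - 1], at, [at[-1] + (m + 1 - aq[-1])]))
    c = np.interp(rows, xs, ys)
    cm1 = np.empty_like(c)
    cm1[0] = c[0]
    cm1[1:] = c[:-1]
    cp1 = np.empty_like(c)
    cp1[-1] = c[-1]
    cp1[:-1] = c[1:]
    lo = np.floor(np.minimum(np.minimum(c, cm1), cp1)).astype(np.int64) - band
    hi = np.ceil(np.maximum(np.maximum(c, cm1), cp1)).astype(np.int64) + band + 1
    # beyond the outermost anchors the diagonal is extrapolated, and e.g.
    # tandem-repeat slippage lets the true path drift; widen the band
    # proportionally to the distance from the anchored stretch
    head = aq[0] - rows
    tail = rows - aq[-1]
    extra = np.clip(np.maximum(head, tail), 0, None) // 5
    np.clip(extra, 0, 600, out=extra)
    lo -= extra
    hi += extra
    np.clip(lo, 0, mt, out=lo)
    np.clip(hi, 1, mt + 1, out=hi)
    hi = np.maximum(hi, lo + 1)
    return lo.astype(np.int64), hi.astype(np.int64)


_OP_SYM = np.array(["M", "M", "I", "D"])


def _rle(arr):
    arr = np.asarray(arr)
    if len(arr) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=arr.dtype)
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(arr)]))
    return ends - starts, arr[starts]


def _ops_to_cigar(ops):
    # match and mismatch both render as M
    sym = _OP_SYM[np.asarray(ops)]
    lens, vals = _rle(sym)
    return "".join(f"{l}{v}" for l, v in zip(lens, vals))


_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar):
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def affine_score_of_ops(ops, p: AlignParams):
    """True affine-gap score of a per-base op path."""
    opsa = np.asarray(ops)
    if len(opsa) == 0:
        return 0
    n_match = int(np.sum(opsa == OP_MATCH))
    n_mis = int(np.sum(opsa == OP_MISMATCH))
    lens, vals = _rle(opsa)
    gap_runs = int(np.sum((vals == OP_INS) | (vals == OP_DEL)))
    gap_bases = int(np.sum(lens[(vals == OP_INS) | (vals == OP_DEL)]))
    return (
        p.match * n_match
        + p.mismatch * n_mis
        - p.gap_open * gap_runs
        - p.gap_extend * gap_bases
    )


def _zdrop_scan(vals, zdrop):
    """Index of the running-max peak before the first drop of >= zdrop,
    or -1 if no such drop occurs."""
    vals = np.asarray(vals)
    peak = np.maximum.accumulate(np.maximum(vals, 0.0))
    drops = np.flatnonzero(peak - vals >= zdrop)
    if len(drops) == 0:
        return -1
    d0 = drops[0]
    return int(np.argmax(vals[: d0 + 1]))


def zdrop_split(ops, p: AlignParams):
    """Split an op path where the cumulative score collapses.

    The scan charges each gap run once, lightly and capped (at
    ``zdrop_gap_open`` + ``zdrop_gap_cap`` extension bases), so neither a
    genuine SV-scale gap nor an error burst triggers a split; a
    mismatch-dense stretch (e.g. an inverted segment aligned in the wrong
    orientation) does.  Returns a list of (start, end) op index ranges;
    length 1 means no split.
    """
    n = len(ops)
    if n == 0:
        return [(0, 0)]
    per = np.empty(n, dtype=np.float64)
    opsa = np.asarray(ops)
    per[opsa == OP_MATCH] = p.zdrop_match
    per[opsa == OP_MISMATCH] = p.zdrop_mismatch
    gap = (opsa == OP_INS) | (opsa == OP_DEL)
    per[gap] = 0.0
    # charge each gap run once, capped
    if gap.any():
        run_start = np.flatnonzero(gap & ~np.roll(gap, 1))
        if gap[0]:
            run_start = np.unique(np.concatenate(([0], run_start)))
        run_end = np.flatnonzero(gap & ~np.roll(gap, -1))
        if gap[-1]:
            run_end = np.unique(np.concatenate((run_end, [n - 1])))
        for s, e in zip(run_start, run_end):
            L = e - s + 1
            per[s] = -(p.zdrop_gap_open + p.gap_extend * min(L, p.zdrop_gap_cap))
    cum = np.cumsum(per)
    ip = _zdrop_scan(cum, p.zdrop)
    if ip < 0:
        return [(0, n)]
    rcum = np.cumsum(per[::-1])
    jp_rev = _zdrop_scan(rcum, p.zdrop)
    if jp_rev < 0:
        return [(0, n)]
    jp = n - 1 - jp_rev
    if ip + 1 >= jp:
        return [(0, n)]
    return [(0, ip + 1), (jp, n)]


def banded_extend(
    query,
    target,
    chain: Chain,
    band_width=None,
    params: AlignParams | None = None,
    q_interval=None,
):
    """Banded affine-gap extension of ``query`` against ``target`` guided by
    a chain of anchors.

    Aligns the query interval spanned by the chain (grown to the interval
    bounds when the overhang is modest) fully, with free leading/trailing
    target gaps; the band follows the chain diagonal and is widened and the
    alignment retried when the optimal path presses against a band edge,
    failing with :class:`BandExceededError` at the cap.

    Returns (score, q0, q1, t_start, t_end, ops).
    """
    p = params or AlignParams()
    band = band_width or p.band_width
    k = p.k
    n = len(query)
    ivl_lo, ivl_hi = q_interval if q_interval is not None else (0, n)
    if chain.n_anchors == 0:
        raise ValueError("empty chain")
    qf, ql = int(chain.qpos[0]), int(chain.qpos[-1]) + k
    q0 = ivl_lo if qf - ivl_lo <= p.max_end_flank else qf
    q1 = ivl_hi if ivl_hi - ql <= p.max_end_flank else ql
    q0 = min(q0, qf)
    q1 = max(q1, ql)
    while True:
        tf, tl = int(chain.tpos[0]), int(chain.tpos[-1]) + k
        t0 = max(0, tf - (qf - q0) - band - 16)
        t1 = min(len(target), tl + (q1 - ql) + band + 16)
        aq = chain.qpos.astype(np.int64) - q0
        at = chain.tpos.astype(np.int64) - t0
        m = q1 - q0
        lo, hi = _build_band(aq, at, m, t1 - t0, band)
        score, ts, te, ops, touched = _kernels.banded_affine(
            np.ascontiguousarray(query[q0:q1], dtype=np.uint8),
            np.ascontiguousarray(target[t0:t1], dtype=np.uint8),
            lo,
            hi,
            p.match,
            p.mismatch,
            p.gap_open,
            p.gap_extend,
            qf - q0 + 1,
            ql - q0 - 1,
        )
        if not touched:
            return int(score), q0, q1, t0 + int(ts), t0 + int(te), ops
        if band >= p.band_cap:
            raise BandExceededError(
                f"band {band} insufficient for chain spanning "
                f"q[{qf},{ql}) t[{tf},{tl})"
            )
        band = min(band * 4, p.band_cap)


# ---------------------------------------------------------------------------
# scoring helpers


def edit_distance(a, b) -> int:
    """Unit-cost Levenshtein distance (edlib, global mode)."""
    a = _as_str(a)
    b = _as_str(b)
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _as_str(s):
    if isinstance(s, str):
        return s
    arr = np.asarray(s)
    return "".join(chr(48 + int(v)) for v in arr)


def levels_to_str(levels) -> str:
    """Render a level array as a digit string (for edlib and FASTA output)."""
    return _as_str(levels)


def compute_mapq(best_score, second_best_score, chain_anchor_count) -> int:
    """Mapping quality from chain-score competition: 60 when unique,
    otherwise 40*(1 - second/best) scaled down for thin chains."""
    if best_score <= 0:
        raise ValueError("best_score must be > 0")
    if second_best_score <= 0:
        return 60
    frac = 1.0 - second_best_score / best_score
    q = round(40.0 * frac * min(1.0, chain_anchor_count / 10.0))
    return int(max(0, min(60, q)))


# ---------------------------------------------------------------------------
# the per-read engine


def _query_minimizers(codes, p: AlignParams):
    return _kernels.minimizers(
        np.ascontiguousarray(codes, dtype=np.uint8), p.k, p.w, p.alphabet_size
    )


def _collect_chains(codes, orient, index: MinimizerIndex, p: AlignParams, extra=None):
    """Seed-and-chain one query orientation; ``extra`` optionally supplies
    additional (qpos, tpos) anchors on target 0 (e.g. guide anchors carried
    over from a previous alignment stage)."""
    qh, qp = _query_minimizers(codes, p)
    if len(qh) == 0 and not extra:
        return []
    if len(qh):
        qpos, tpos, tids = index.lookup(qh, qp, p.max_occ)
    else:
        qpos = tpos = tids = np.empty(0, dtype=np.int32)
    if extra is not None and len(extra[0]):
        eq = np.asarray(extra[0], dtype=np.int32)
        et = np.asarray(extra[1], dtype=np.int32)
        qpos = np.concatenate([qpos, eq])
        tpos = np.concatenate([tpos, et])
        tids = np.concatenate([tids, np.zeros(len(eq), dtype=np.int32)])
    chains = []
    for tid in np.unique(tids):
        sel = tids == tid
        q, t = qpos[sel], tpos[sel]
        order = np.lexsort((q, t))
        q, t = q[order], t[order]
        score, parent = _kernels.chain_dp(
            q, t, p.max_gap, p.lookback, p.gap_scale, p.gap_cap
        )
        for c in _extract_chains(
            q, t, score, parent, p.min_chain_anchors, p.max_chains
        ):
            c.target_id = int(tid)
            c.orientation = orient
            chains.append(c)
    return chains


def _orig_interval(lo, hi, orient, n):
    """Map an orientation-frame query interval to original-read coordinates."""
    if orient == 0:
        return lo, hi
    return n - hi, n - lo


def _chain_hull(c: Chain, k, n):
    return _orig_interval(int(c.qpos[0]), int(c.qpos[-1]) + k, c.orientation, n)


def _anchors_in(c: Chain, k, n, interval):
    lo, hi = interval
    a, b = _chain_hull(c, k, n)
    # anchor midpoints in original coords
    if c.orientation == 0:
        mid = c.qpos + k // 2
    else:
        mid = n - (c.qpos + k // 2)
    return int(np.sum((mid >= lo) & (mid < hi)))


def _trim_range(opsa, p: AlignParams):
    """Trim mismatch-dense segments off both ends of an op path.

    Each end is cut back to its maximum-cumulative-score point under a
    fixed +2/-2 match/mismatch scale (break-even at 50% identity, the
    boundary between a noisy-but-correct stretch and unrelated "soup"),
    with gap bases scored zero: unanchored tails forced through the band
    align as low-identity soup and are clipped, while a genuine SV gap run
    (deletion run or trailing insertion of novel sequence) is
    score-neutral and survives.  Ties prefer the longer extent.
    """
    per = np.zeros(len(opsa), dtype=np.float64)
    per[opsa == OP_MATCH] = p.trim_match
    per[opsa == OP_MISMATCH] = p.trim_mismatch
    cum = np.cumsum(per)
    # right trim: last index of the running maximum of cum
    peaks = np.maximum.accumulate(cum)
    right = int(np.flatnonzero(cum == peaks[-1])[-1]) + 1 if peaks[-1] > 0 else 0
    if right == 0:
        right = len(opsa) if cum[-1] >= 0 else 0
    # left trim: same scan from the right end
    rcum = np.cumsum(per[::-1])
    rpeaks = np.maximum.accumulate(rcum)
    lcut = int(np.flatnonzero(rcum == rpeaks[-1])[-1]) + 1 if rpeaks[-1] > 0 else 0
    left = len(opsa) - lcut if lcut > 0 else (0 if rcum[-1] >= 0 else len(opsa))
    if left >= right:
        return 0, 0
    return left, right


def _diag_extend(query, target, pos_q, pos_t, direction, p: AlignParams, limit=500):
    """Greedy gap-free extension from an alignment end, stopped at the
    maximum-cumulative-score point under the trim scale.

    Rescues reference span that the affine DP trades away as a terminal
    query gap when the end of the read is unusually noisy.  Returns the
    per-base ops of the extension (ordered moving away from the record).
    """
    score = best = 0.0
    best_j = 0
    ops = []
    j = 0
    while j < limit:
        qi = pos_q + direction * j + (0 if direction > 0 else -1)
        ti = pos_t + direction * j + (0 if direction > 0 else -1)
        if not (0 <= qi < len(query) and 0 <= ti < len(target)):
            break
        if query[qi] == target[ti]:
            score += p.trim_match
            ops.append(OP_MATCH)
        else:
            score += p.trim_mismatch
            ops.append(OP_MISMATCH)
        j += 1
        if score > best:
            best, best_j = score, j
        elif best - score > 8 * p.trim_match:
            break
    return ops[:best_j]


def _piece_records(
    query_name,
    n,
    orient,
    q0,
    t_start,
    ops,
    pieces,
    p: AlignParams,
    target_name,
    chain,
    query=None,
    target=None,
):
    """Turn op-path pieces into alignment records (orientation-frame CIGAR,
    original-frame query coordinates)."""
    opsa = np.asarray(ops)
    qcons = np.isin(opsa, (OP_MATCH, OP_MISMATCH, OP_INS)).astype(np.int64)
    tcons = np.isin(opsa, (OP_MATCH, OP_MISMATCH, OP_DEL)).astype(np.int64)
    cq = np.concatenate(([0], np.cumsum(qcons)))
    ct = np.concatenate(([0], np.cumsum(tcons)))
    out = []
    for (s, e) in pieces:
        piece = opsa[s:e]
        tl, tr = _trim_range(piece, p)
        if tr <= tl:
            continue
        s, e = s + tl, s + tr
        piece = opsa[s:e]
        # trim flanking indels so pieces start/end on aligned bases
        keep = np.flatnonzero((piece == OP_MATCH) | (piece == OP_MISMATCH))
        if len(keep) == 0:
            continue
        s2, e2 = s + int(keep[0]), s + int(keep[-1]) + 1
        piece = opsa[s2:e2]
        qs_o = q0 + int(cq[s2])
        qe_o = q0 + int(cq[e2])
        ts = t_start + int(ct[s2])
        te = t_start + int(ct[e2])
        if qe_o <= qs_o or te <= ts:
            continue
        if query is not None and target is not None:
            head = _diag_extend(query, target, qs_o, ts, -1, p)
            tail = _diag_extend(query, target, qe_o, te, +1, p)
            if head or tail:
                piece = np.concatenate(
                    [np.array(head[::-1], dtype=piece.dtype), piece,
                     np.array(tail, dtype=piece.dtype)]
                )
                qs_o -= len(head)
                ts -= len(head)
                qe_o += len(tail)
                te += len(tail)
        nm = int(np.sum(piece != OP_MATCH))
        score = affine_score_of_ops(piece, p)
        cig_core = _ops_to_cigar(piece)
        lead, trail = qs_o, n - qe_o
        cigar = (f"{lead}S" if lead else "") + cig_core + (f"{trail}S" if trail else "")
        qs, qe = _orig_interval(qs_o, qe_o, orient, n)
        out.append(
            AlignmentRecord(
                query_name=query_name,
                target_name=target_name,
                query_start=qs,
                query_end=qe,
                target_start=ts,
                target_end=te,
                strand="+" if orient == 0 else "-",
                cigar=cigar,
                score=score,
                nm=nm,
                query_length=n,
                n_anchors=chain.n_anchors,
            )
        )
    return out


def _subtract_intervals(full, covered, min_len):
    """Uncovered sub-intervals of ``full`` of length >= min_len."""
    lo, hi = full
    cov = sorted(covered)
    out = []
    cur = lo
    for a, b in cov:
        if a > cur:
            out.append((cur, min(a, hi)))
        cur = max(cur, b)
        if cur >= hi:
            break
    if cur < hi:
        out.append((cur, hi))
    return [(a, b) for a, b in out if b - a >= min_len]


def align_queries(
    query_name,
    fwd_codes,
    rev_codes,
    index: MinimizerIndex,
    params: AlignParams | None = None,
    domain="nucleotide",
    seed_anchors=None,
):
    """Align a query (both orientations supplied by the caller) against the
    index: seed, chain, extend the best chain, split on score collapses,
    and re-align leftover query intervals as supplementary records.

    ``seed_anchors`` maps orientation (0/1) to extra (qpos, tpos) anchor
    arrays on target 0, used to guide chaining.

    Returns records sorted with the primary (best score) first.
    """
    p = params or AlignParams()
    n = len(fwd_codes)
    sa = seed_anchors or {}
    chains = _collect_chains(fwd_codes, 0, index, p, sa.get(0)) + _collect_chains(
        rev_codes, 1, index, p, sa.get(1)
    )
    if not chains:
        return []
    chains.sort(key=lambda c: (-c.score, int(c.tpos[0]), c.target_id, c.orientation))
    records = []
    covered = []
    used = [False] * len(chains)

    def restrict(c, interval_orig):
        """Sub-chain with anchors inside the original-frame interval."""
        lo, hi = interval_orig
        if c.orientation == 0:
            mid = c.qpos + p.k // 2
        else:
            mid = n - (c.qpos + p.k // 2)
        keep = (mid >= lo) & (mid < hi)
        if not keep.any():
            return None
        return Chain(
            score=c.score * float(keep.sum()) / max(c.n_anchors, 1),
            qpos=c.qpos[keep],
            tpos=c.tpos[keep],
            target_id=c.target_id,
            orientation=c.orientation,
        )

    def extend_chain(ci, interval_orig):
        c = chains[ci]
        used[ci] = True
        if interval_orig != (0, n):
            c = restrict(c, interval_orig)
            if c is None:
                return []
        ivl = (
            interval_orig
            if c.orientation == 0
            else _orig_interval(interval_orig[0], interval_orig[1], 1, n)
        )
        query = fwd_codes if c.orientation == 0 else rev_codes
        try:
            score, q0, q1, ts, te, ops = banded_extend(
                query, index.targets[c.target_id], c, params=p, q_interval=ivl
            )
        except BandExceededError:
            return []
        pieces = zdrop_split(ops, p)
        recs = _piece_records(
            query_name, n, c.orientation, q0, ts, ops, pieces, p,
            index.names[c.target_id], c,
            query=query, target=index.targets[c.target_id],
        )
        for r in recs:
            r.domain = domain
            r.ref_start, r.ref_end = r.target_start, r.target_end
            r.mapq = _record_mapq(r, c, ci)
            covered.append((r.query_start, r.query_end))
        return recs

    def _record_mapq(rec, c, ci):
        best = c.score
        second = 0.0
        for cj, other in enumerate(chains):
            if cj == ci:
                continue
            ain = _anchors_in(other, p.k, n, (rec.query_start, rec.query_end))
            if ain >= max(p.min_chain_anchors, 0.5 * c.n_anchors):
                s = other.score * ain / max(other.n_anchors, 1)
                second = max(second, s)
        if best <= 0:
            return 0
        return compute_mapq(best, second, c.n_anchors)

    # an opposite-orientation chain nested strictly inside the primary's
    # query span marks an inverted segment: the primary would absorb it as
    # a mismatch-dense stretch, so the query is split around it up front
    # and each part aligned in its own orientation
    prim = chains[0]
    ph = _chain_hull(prim, p.k, n)
    rival = None
    for ci, c in enumerate(chains[1:], 1):
        if c.orientation == prim.orientation or c.target_id != prim.target_id:
            continue
        h = _chain_hull(c, p.k, n)
        if (
            h[0] >= ph[0] + 30
            and h[1] <= ph[1] - 30
            and c.n_anchors >= 5
            and h[1] - h[0] >= p.min_split
        ):
            rival = (ci, h)
            break
    if rival is not None:
        rci, (a, b) = rival
        if a > 0:
            records.extend(extend_chain(0, (0, a)))
        records.extend(extend_chain(rci, (a, b)))
        if b < n:
            records.extend(extend_chain(0, (b, n)))
    else:
        records.extend(extend_chain(0, (0, n)))
    # leftover intervals -> supplementary alignments
    for _ in range(p.max_records):
        if len(records) >= p.max_records:
            break
        leftovers = _subtract_intervals((0, n), covered, p.min_split)
        if not leftovers:
            break
        progressed = False
        for ivl in leftovers:
            best_ci, best_key = -1, None
            for ci, c in enumerate(chains):
                if used[ci]:
                    continue
                ain = _anchors_in(c, p.k, n, ivl)
                if ain < p.min_chain_anchors or ain < 0.6 * c.n_anchors:
                    continue
                key = (-c.score, int(c.tpos[0]), c.target_id, c.orientation)
                if best_key is None or key < best_key:
                    best_ci, best_key = ci, key
            if best_ci >= 0:
                recs = extend_chain(best_ci, ivl)
                records.extend(recs)
                if recs:
                    progressed = True
        if not progressed:
            break
    if not records:
        return []
    # primary = the record explaining the most of the read: error-adjusted
    # aligned span, not raw DP score, which under the high-mismatch
    # quantized scoring can rank a short clean shard above a long noisy
    # (but structurally correct) alignment
    records.sort(
        key=lambda r: (
            -((r.query_end - r.query_start) - r.nm),
            -r.score,
            r.target_start,
            r.target_name,
        )
    )
    for r in records[1:]:
        r.is_supplementary = True
    return records


def validate_record(rec: AlignmentRecord, target_length=None):
    """Check CIGAR/coordinate consistency; raises AssertionError on failure."""
    qspan = sum(l for l, op in parse_cigar(rec.cigar) if op in "MIS=X")
    qcons = sum(l for l, op in parse_cigar(rec.cigar) if op in "MI=X")
    tcons = sum(l for l, op in parse_cigar(rec.cigar) if op in "MD=XN")
    assert qspan == rec.query_length, (qspan, rec.query_length)
    assert qcons == rec.query_end - rec.query_start
    assert tcons == rec.target_end - rec.target_start
    assert 0 <= rec.query_start < rec.query_end <= rec.query_length
    assert 0 <= rec.target_start < rec.target_end
    if target_length is not None:
        assert rec.target_end <= target_length
    assert 0 <= rec.mapq <= 60
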