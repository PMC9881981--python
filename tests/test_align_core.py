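"""align_core against independent brute-force oracles."""

import functools

import numpy as np
import pytest

from hqalign import _kernels
from hqalign.align_core import (
    AlignParams,
    Anchor,
    Chain,
    banded_extend,
    build_minimizer_index,
    chain_anchors,
    compute_mapq,
    edit_distance,
    parse_cigar,
    validate_record,
)
from hqalign.qmer_model import encode

MASK = (1 << 64) - 1


def splitmix64(x):
    # pure-python reimplementation, independent of the numba kernel
    x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & MASK
    x = (x ^ (x >> 27)) * 0x94D049BB133111EB & MASK
    x ^= x >> 31
    return x & 0x3FFFFFFFFFFFFFFF


def brute_minimizers(codes, k, w, alphabet_size):
    """Naive double-loop minimizer set: every window of w consecutive
    k-mers contributes each k-mer achieving the minimum hash."""
    n = len(codes)
    hashes = {}
    for i in range(n - k + 1):
        kmer = codes[i : i + k]
        if max(kmer) >= alphabet_size:
            continue
        v = 0
        for c in kmer:
            v = v * alphabet_size + int(c)
        hashes[i] = splitmix64(v)
    out = set()
    nk = n - k + 1
    for s in range(max(nk - w + 1, 1)):
        window = {j: h for j, h in hashes.items() if s <= j < min(s + w, nk)}
        if not window:
            continue
        m = min(window.values())
        for j, h in window.items():
            if h == m:
                out.add((h, j))
    return out


class TestMinimizers:
    def test_single_kmer_everywhere(self):
        idx = build_minimizer_index({"t": encode("AAAA")}, k=2, w=1, alphabet_size=4)
        assert sorted(idx.positions.tolist()) == [0, 1, 2]

    def test_identical_targets_identical_lists(self):
        t = encode("ACGTACGTGGTACC")
        idx = build_minimizer_index({"a": t, "b": t.copy()}, k=3, w=2, alphabet_size=4)
        a = sorted(idx.positions[idx.tids == 0].tolist())
        b = sorted(idx.positions[idx.tids == 1].tolist())
        assert a == b

    @pytest.mark.parametrize("k,w,asize", [(5, 4, 4), (3, 5, 4), (4, 3, 3)])
    def test_matches_brute_force(self, rng, k, w, asize):
        codes = rng.integers(0, asize, 200).astype(np.uint8)
        h, p = _kernels.minimizers(codes, k, w, asize)
        got = set(zip(h.tolist(), p.tolist()))
        assert got == brute_minimizers(codes, k, w, asize)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            build_minimizer_index({"t": encode("ACGT")}, k=0, w=1, alphabet_size=4)


def oracle_best_chain(anchors, max_gap, p: AlignParams):
    """Exhaustive search over all increasing anchor subsequences."""
    n = len(anchors)
    best = 0.0
    for mask in range(1, 1 << n):
        sel = [anchors[i] for i in range(n) if mask >> i & 1]
        sel.sort(key=lambda a: (a.target_pos, a.query_pos))
        ok = True
        score = 1.0
        for a, b in zip(sel, sel[1:]):
            dq = b.query_pos - a.query_pos
            dt = b.target_pos - a.target_pos
            if dq <= 0 or dt <= 0 or dq > max_gap or dt > max_gap:
                ok = False
                break
            score += 1.0 - min(p.gap_scale * abs(dt - dq), p.gap_cap)
        if ok:
            best = max(best, score)
    return best


class TestChaining:
    def test_colinear_single_chain(self):
        anchors = [Anchor(i * 10, i * 10) for i in range(8)]
        chains = chain_anchors(anchors, max_gap=100, min_chain_anchors=3)
        assert len(chains) == 1
        assert chains[0].n_anchors == 8

    def test_gap_splits_chain(self):
        anchors = [Anchor(i * 10, i * 10) for i in range(5)] + [
            Anchor(1000 + i * 10, 5000 + i * 10) for i in range(5)
        ]
        chains = chain_anchors(anchors, max_gap=100, min_chain_anchors=3)
        assert len(chains) == 2

    def test_empty(self):
        assert chain_anchors([]) == []

    def test_matches_exhaustive_search(self, rng):
        p = AlignParams()
        for _ in range(8):
            anchors = [
                Anchor(int(q), int(t))
                for q, t in zip(rng.integers(0, 300, 12), rng.integers(0, 300, 12))
            ]
            chains = chain_anchors(anchors, max_gap=120, min_chain_anchors=1, params=p)
            got = chains[0].score if chains else 0.0
            assert got == pytest.approx(oracle_best_chain(anchors, 120, p))


def oracle_glocal_affine(q, t, p: AlignParams):
    """Full-matrix Gotoh with free leading/trailing target gaps."""
    NEG = -(10 ** 9)
    m, n = len(q), len(t)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0
    for i in range(1, m + 1):
        for j in range(n + 1):
            X[i][j] = max(M[i - 1][j] - p.gap_open - p.gap_extend, X[i - 1][j] - p.gap_extend)
            if j >= 1:
                Y[i][j] = max(M[i][j - 1] - p.gap_open - p.gap_extend, Y[i][j - 1] - p.gap_extend)
                s = p.match if q[i - 1] == t[j - 1] else p.mismatch
                prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if prev > NEG // 2:
                    M[i][j] = prev + s
    return max(max(M[m]), max(X[m]), max(Y[m]))


def _mutate(rng, s, n_edits):
    s = list(s)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, max(len(s), 1)))
        if op == 0 and s:
            s[pos] = int(rng.integers(0, 4))
        elif op == 1:
            s.insert(pos, int(rng.integers(0, 4)))
        elif s:
            del s[pos]
    return np.array(s, dtype=np.uint8)


def _seed_chain(q, t, k=5):
    """First exact k-mer shared by query and target, as a one-anchor chain."""
    tstr = t.tobytes()
    for i in range(len(q) - k + 1):
        j = tstr.find(q[i : i + k].tobytes())
        if j >= 0:
            return Chain(score=1.0, qpos=np.array([i]), tpos=np.array([j]))
    return None


class TestBandedExtend:
    def test_identity(self, rng):
        p = AlignParams()
        t = rng.integers(0, 4, 40).astype(np.uint8)
        chain = Chain(score=1.0, qpos=np.array([0]), tpos=np.array([4]))
        score, q0, q1, ts, te, ops = banded_extend(t[4:20], t, chain, params=p)
        assert score == 16 * p.match
        assert (ts, te) == (4, 20)
        assert all(o == _kernels.OP_MATCH for o in ops)

    def test_single_substitution(self, rng):
        p = AlignParams()
        t = rng.integers(0, 4, 30).astype(np.uint8)
        q = t[2:18].copy()
        q[8] = (q[8] + 1) % 4
        chain = Chain(score=1.0, qpos=np.array([0]), tpos=np.array([2]))
        score, q0, q1, ts, te, ops = banded_extend(q, t, chain, params=p)
        assert int(np.sum(np.asarray(ops) == _kernels.OP_MISMATCH)) == 1
        assert te - ts == 16

    def test_matches_unbanded_oracle(self, rng):
        """Generous-band extension equals full-matrix affine DP."""
        p = AlignParams(band_width=64)
        checked = 0
        while checked < 30:
            t = rng.integers(0, 4, int(rng.integers(20, 40))).astype(np.uint8)
            q = _mutate(rng, t.tolist(), int(rng.integers(0, 5)))
            if len(q) < 8:
                continue
            chain = _seed_chain(q, t)
            if chain is None:
                continue
            score, *_ = banded_extend(q, t, chain, params=p)
            assert score == oracle_glocal_affine(q.tolist(), t.tolist(), p)
            checked += 1


def recursive_edit_distance(a, b):
    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


class TestEditDistance:
    def test_empty_vs_s(self):
        assert edit_distance("", "ACGT") == 4

    def test_identity(self):
        assert edit_distance("ACGTA", "ACGTA") == 0

    def test_matches_recursive_oracle(self, rng):
        for _ in range(50):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(0, 20)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(0, 20)))
            assert edit_distance(a, b) == recursive_edit_distance(a, b)
            assert edit_distance(a, b) == edit_distance(b, a)


class TestMapq:
    def test_unique_hit(self):
        assert compute_mapq(100, 0, 5) == 60

    def test_tied_hit(self):
        assert compute_mapq(100, 100, 20) == 0

    def test_formula(self):
        assert compute_mapq(100, 50, 10) == 20

    def test_monotone_in_second(self):
        vals = [compute_mapq(100, s, 10) for s in range(0, 101, 10)]
        assert vals == sorted(vals, reverse=True)

    def test_invalid_best(self):
        with pytest.raises(ValueError):
            compute_mapq(0, 0, 5)


def test_cigar_parse_round_trip():
    assert parse_cigar("12M3I4D5S") == [(12, "M"), (3, "I"), (4, "D"), (5, "S")]
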