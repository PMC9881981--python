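"""Q-mer current model and sequence quantization.

A nanopore measures ionic current over a pore occupied by Q consecutive
bases (Q = 6 for R9.4-style chemistry), so the observable signal is a
function of Q-mers, not single bases.  The *Q-mer map* assigns every
Q-mer its median current level (pA).  Translating a basecalled nucleotide
sequence through the map and hard-thresholding the currents into a small
number of levels L (L = 3, the "HQ3" alphabet) yields a *quantized
sequence*: two nucleotide sequences whose windows are confusable in
current space become identical after quantization, which is exactly the
error structure of nanopore basecalls.

Because current levels have no complement structure, the quantization of
the reverse complement cannot be derived from the forward quantized
sequence; :func:`quantize_revcomp` computes it from the nucleotide
sequence directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class QmerMapError(ValueError):
    """Base class for malformed Q-mer model tables."""


class MissingQmerError(QmerMapError):
    pass


class DuplicateQmerError(QmerMapError):
    pass


class NonNumericCurrentError(QmerMapError):
    pass


class WrongKmerLengthError(QmerMapError):
    pass


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def all_qmers(Q: int):
    """All 4**Q Q-mers in lexicographic (A<C<G<T) order."""
    return ("".join(p) for p in itertools.product(BASES, repeat=Q))


@dataclass
class QmerMap:
    """Total map from every Q-mer over {A,C,G,T} to a median current (pA)."""

    Q: int
    currents: dict
    sds: dict | None = None
    # currents of the i-th lexicographic Q-mer, index == packed base-4 code
    current_array: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        n = 4 ** self.Q
        if len(self.currents) != n:
            missing = next(
                (q for q in all_qmers(self.Q) if q not in self.currents), None
            )
            if missing is not None:
                raise MissingQmerError(
                    f"Q-mer map incomplete: {len(self.currents)} of {n} entries; "
                    f"e.g. missing {missing!r}"
                )
            raise QmerMapError(f"expected {n} entries, got {len(self.currents)}")
        arr = np.empty(n, dtype=np.float64)
        for kmer, cur in self.currents.items():
            if len(kmer) != self.Q:
                raise WrongKmerLengthError(
                    f"k-mer {kmer!r} has length {len(kmer)}, expected {self.Q}"
                )
            code = 0
            for ch in kmer:
                code = code * 4 + BASES.index(ch)
            arr[code] = cur
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise QmerMapError("all currents must be finite and > 0")
        self.current_array = arr


@dataclass
class QuantizerConfig:
    """Hard-thresholding rule: L levels separated by L-1 ascending cutoffs."""

    L: int
    thresholds: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if len(self.thresholds) != self.L - 1:
            raise ValueError("need exactly L-1 thresholds")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class QuantizedSequence:
    """Finite-alphabet translation of a nucleotide sequence.

    ``levels[p]`` is the quantization level of the Q-mer window starting at
    nucleotide position ``p``; there are ``max(n - Q + 1, 0)`` windows.
    """

    levels: np.ndarray
    source_length: int
    Q: int

    def __post_init__(self):
        assert len(self.levels) == max(self.source_length - self.Q + 1, 0)

    def __len__(self):
        return len(self.levels)


def load_qmer_map(path, Q: int) -> QmerMap:
    """Read an ONT-style model table (TSV: kmer, level_mean[, level_stdv]).

    A header line starting with a non-ACGT token is skipped.  Row order is
    irrelevant; lexicographic completeness over {A,C,G,T}**Q is enforced.
    """
    currents: dict = {}
    sds: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            kmer = parts[0]
            if lineno == 1 and any(c not in BASES for c in kmer.upper()):
                continue  # header
            kmer = kmer.upper()
            if any(c not in BASES for c in kmer):
                raise QmerMapError(f"line {lineno}: bad k-mer {parts[0]!r}")
            if len(kmer) != Q:
                raise WrongKmerLengthError(
                    f"line {lineno}: k-mer {kmer!r} length {len(kmer)} != Q={Q}"
                )
            if kmer in currents:
                raise DuplicateQmerError(f"duplicate Q-mer {kmer!r}")
            try:
                cur = float(parts[1])
            except ValueError as e:
                raise NonNumericCurrentError(
                    f"line {lineno}: non-numeric current {parts[1]!r}"
                ) from e
            currents[kmer] = cur
            if len(parts) > 2:
                try:
                    sds[kmer] = float(parts[2])
                except ValueError:
                    pass
    return QmerMap(Q=Q, currents=currents, sds=sds or None)


def synthesize_qmer_map(
    Q: int, seed: int, current_range: tuple = (60.0, 120.0)
) -> QmerMap:
    """Deterministic synthetic Q-mer map (stand-in for a real pore model).

    Currents are drawn independently and uniformly on ``current_range``;
    one pair of distinct Q-mers is forced within 0.5 pA of each other so
    confusability exists even for small alphabets.  (A real pore model has
    additional similarity structure - similar Q-mers tend toward similar
    currents - which makes quantization forgiving of substitutions; an
    independent map is the conservative choice for benchmarking, since it
    grants the quantized alphabet no free error tolerance.)
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = current_range
    vals = rng.uniform(lo, hi, size=4 ** Q)
    if len(vals) >= 2:
        i, j = rng.choice(len(vals), size=2, replace=False)
        vals[j] = np.clip(vals[i] + rng.uniform(-0.5, 0.5), lo, hi)
    currents = {q: v for q, v in zip(all_qmers(Q), vals)}
    return QmerMap(Q=Q, currents=currents)


def compute_thresholds(qmap: QmerMap, L: int = 3) -> QuantizerConfig:
    """Equal-occupancy thresholds: empirical quantiles of the model currents
    at fractions j/L.  With distinct currents the L levels receive equal
    (±1) numbers of Q-mers, which maximizes the entropy of the quantized
    alphabet."""
    if L < 2:
        raise ValueError("L must be >= 2")
    if L > 4 ** qmap.Q:
        raise ValueError("more levels than Q-mers")
    qs = np.arange(1, L) / L
    thr = np.quantile(qmap.current_array, qs)
    if np.any(np.diff(thr) <= 0):  # massive ties; nudge to keep validity
        thr = np.maximum.accumulate(thr + np.arange(L - 1) * 1e-9)
    return QuantizerConfig(L=L, thresholds=thr)


def level_table(qmap: QmerMap, cfg: QuantizerConfig) -> np.ndarray:
    """Per-Q-mer level, indexed by packed base-4 code.

    A current exactly equal to a threshold is assigned the lower level
    (level = number of thresholds strictly below the current).
    """
    return np.searchsorted(cfg.thresholds, qmap.current_array, side="left").astype(
        np.uint8
    )


def _window_codes(codes: np.ndarray, Q: int):
    """Packed base-4 code of each Q-window plus a mask of windows containing
    non-ACGT bases."""
    n = len(codes)
    nw = max(n - Q + 1, 0)
    if nw == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, Q)
    bad = (windows >= 4).any(axis=1)
    safe = np.where(windows >= 4, 0, windows).astype(np.int64)
    powers = 4 ** np.arange(Q - 1, -1, -1, dtype=np.int64)
    return safe @ powers, bad


def to_current_levels(seq: str, qmap: QmerMap) -> np.ndarray:
    """Sliding-window translation of a nucleotide sequence to currents (pA).

    Windows containing non-ACGT characters yield NaN.
    """
    idx, bad = _window_codes(encode(seq), qmap.Q)
    out = qmap.current_array[idx]
    out[bad] = np.nan
    return out

def quantize_codes(
    codes: np.ndarray, qmap: QmerMap, cfg: QuantizerConfig, table: np.ndarray | None = None
) -> np.ndarray:
    """Quantize pre-encoded uint8 nucleotide codes to a uint8 level array."""
    if table is None:
        table = level_table(qmap, cfg)
    idx, bad = _window_codes(codes, qmap.Q)
    levels = table[idx]
    levels[bad] = cfg.L // 2  # windows touching N get the middle level
    return levels


def quantize(seq: str, qmap: QmerMap, cfg: QuantizerConfig) -> QuantizedSequence:
    """Quantized forward sequence x^q."""
    return QuantizedSequence(
        levels=quantize_codes(encode(seq), qmap, cfg),
        source_length=len(seq),
        Q=qmap.Q,
    )


def quantize_revcomp(seq: str, qmap: QmerMap, cfg: QuantizerConfig) -> QuantizedSequence:
    """Quantized reverse complement x̄^q = quantize(revcomp(x)).

    Not derivable from quantize(x): the Q-mer map has no complement
    symmetry, so this is computed from the nucleotide sequence.
    """
    return quantize(reverse_complement(seq), qmap, cfg)
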