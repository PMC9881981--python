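"""Synthetic genomes, planted structural variants, and nanopore-like reads.

The generators emulate the experimental setting the pipeline targets
without any external simulator: a random genome seasoned with VNTR-style
tandem repeat arrays, non-overlapping INS/DEL/INV variants with lengths
uniform on a configurable range, and reads with log-normal lengths and a
configurable error rate whose substitutions can be biased toward Q-mer
confusability — substitutions chosen so the local Q-mer stays in the same
quantization bin, mimicking the dominant error mode of a nanopore
basecaller.  Reads are simulated from the mutated genome and aligned back
to the original, which is the discovery direction of SV calling.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import qmer_model as qm
from ._kernels import corrupt_read
from .sv_eval import SVCall

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


@dataclass
class SimulatedGenome:
    name: str
    sequence: str
    repeat_intervals: list  # [(start, end), ...] of tandem-array bases


@dataclass
class SimulatedRead:
    name: str
    sequence: str
    chrom: str
    start: int  # source interval on the genome the read was drawn from
    end: int
    strand: str


def _random_seq(rng, length):
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def generate_genome(
    length: int,
    repeat_fraction: float = 0.2,
    vntr_unit_range: tuple = (5, 50),
    seed: int = 0,
    name: str = "chr1",
) -> SimulatedGenome:
    """Random genome with ~``repeat_fraction`` of bases in tandem arrays
    whose unit length is uniform on ``vntr_unit_range``; GC ~ 0.5
    elsewhere."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0 <= repeat_fraction <= 0.9:
        raise ValueError("repeat_fraction must be in [0, 0.9]")
    rng = np.random.default_rng(seed)
    target_repeat = repeat_fraction * length
    arrays = []
    total = 0
    while total < target_repeat:
        unit_len = int(rng.integers(vntr_unit_range[0], vntr_unit_range[1] + 1))
        copies = int(rng.integers(5, 31))
        span = min(unit_len * copies, 3000)
        unit = _random_seq(rng, unit_len)
        arr = (unit * (span // unit_len + 1))[:span]
        arrays.append(arr)
        total += span
    n_arr = len(arrays)
    background = max(length - total, 0)
    # distribute background around the arrays
    if n_arr:
        cuts = np.sort(rng.integers(0, background + 1, size=n_arr))
        seg_lens = np.diff(np.concatenate(([0], cuts, [background])))
    else:
        seg_lens = np.array([background])
    parts = []
    intervals = []
    pos = 0
    for i, seg in enumerate(seg_lens):
        parts.append(_random_seq(rng, int(seg)))
        pos += int(seg)
        if i < n_arr:
            intervals.append((pos, pos + len(arrays[i])))
            parts.append(arrays[i])
            pos += len(arrays[i])
    seq = "".join(parts)[:length]
    intervals = [(s, min(e, length)) for s, e in intervals if s < length]
    return SimulatedGenome(name=name, sequence=seq, repeat_intervals=intervals)


def plant_svs(
    genome,
    n_indel: int,
    n_inv: int,
    len_low: int = 50,
    len_high: int = 10000,
    seed: int = 0,
    min_gap: int = 1000,
    chrom: str | None = None,
):
    """Plant non-overlapping INS/DEL/INV variants (INDELs split evenly
    between INS and DEL; lengths uniform on [len_low, len_high]).

    Returns (mutated sequence, truth calls); truth coordinates refer to the
    ORIGINAL genome.  A ``min_gap`` spacing between variants keeps their
    breakpoints unambiguous.
    """
    if isinstance(genome, SimulatedGenome):
        chrom = chrom or genome.name
        seq = genome.sequence
    else:
        seq = genome
        chrom = chrom or "chr1"
    rng = np.random.default_rng(seed)
    n_ins = n_indel // 2 + (n_indel % 2 and rng.random() < 0.5)
    n_del = n_indel - n_ins
    types = rng.permutation(["INS"] * n_ins + ["DEL"] * n_del + ["INV"] * n_inv)
    n_sv = len(types)
    lengths = rng.integers(len_low, len_high + 1, size=n_sv)
    footprints = np.where(types == "INS", 1, lengths)
    if footprints.sum() >= len(seq) / 2:
        raise ValueError("total SV footprint exceeds half the genome")
    slack = len(seq) - int(footprints.sum()) - (n_sv + 1) * min_gap
    if slack < 0:
        raise ValueError("cannot place SVs without overlap")
    offsets = np.sort(rng.integers(0, slack + 1, size=n_sv))
    positions = offsets + min_gap * np.arange(1, n_sv + 1) + np.concatenate(
        ([0], np.cumsum(footprints[:-1]))
    )
    truth = []
    parts = []
    cursor = 0
    for i in range(n_sv):
        pos, L, svtype = int(positions[i]), int(lengths[i]), str(types[i])
        parts.append(seq[cursor:pos])
        if svtype == "INS":
            parts.append(_random_seq(rng, L))
            cursor = pos
            end = pos
        elif svtype == "DEL":
            cursor = pos + L
            end = pos + L
        else:  # INV
            parts.append(qm.reverse_complement(seq[pos : pos + L]))
            cursor = pos + L
            end = pos + L
        truth.append(
            SVCall(
                chrom=chrom,
                start=pos,
                end=end,
                type=svtype,
                length=L,
                id=f"truth_{svtype.lower()}_{i}",
                origin="truth",
            )
        )
    parts.append(seq[cursor:])
    truth.sort(key=lambda c: (c.chrom, c.start))
    return "".join(parts), truth


def confusable_sub_table(qmap: qm.QmerMap, cfg: qm.QuantizerConfig) -> np.ndarray:
    """For each packed Q-mer, the alternative *center* bases that leave the
    Q-mer in the same quantization bin (-1 padded, up to 3 per row).

    The center position is where the pore is most sensitive, so a
    substitution that keeps the centered window in its bin is one the
    sequencer genuinely confuses."""
    table = qm.level_table(qmap, cfg)
    n = len(table)
    Q = qmap.Q
    c = Q // 2
    stride = 4 ** (Q - 1 - c)
    codes = np.arange(n)
    center = (codes // stride) % 4
    base_code = codes - center * stride
    out = np.full((n, 3), -1, dtype=np.int8)
    counts = np.zeros(n, dtype=np.int64)
    for b in range(4):
        ok = (table[base_code + b * stride] == table) & (center != b)
        rows = np.flatnonzero(ok)
        out[rows, counts[rows]] = b
        counts[rows] += 1
    return out


def simulate_reads(
    genome: str,
    coverage: float = 40.0,
    mean_len: float = 14000.0,
    median_len: float | None = None,
    error_rate: float = 0.1,
    qmap: qm.QmerMap | None = None,
    cfg: qm.QuantizerConfig | None = None,
    confusion_weight: float = 0.5,
    seed: int = 0,
    max_len: int = 50000,
    min_len: int = 200,
    error_split: tuple = (0.4, 0.3, 0.3),
    error_rate_sd: float | None = None,
    chrom: str = "chr1",
):
    """Reads with log-normal lengths (fit to mean and median), drawn from
    either strand, with errors split sub/ins/del by ``error_split``.
    ``error_rate`` is the cohort average; each read draws its own rate
    from a normal with spread ``error_rate_sd`` (default 0.3x the mean,
    clipped to [0.02, 0.3]) — real runs mix clean and dirty reads rather
    than erring uniformly.  With probability ``confusion_weight`` a
    substitution is chosen among bases keeping the local Q-mer in its
    quantization bin.
    """
    if not 0 <= error_rate <= 0.3:
        raise ValueError("error_rate must be in [0, 0.3]")
    if error_rate_sd is None:
        error_rate_sd = 0.3 * error_rate
    if isinstance(genome, SimulatedGenome):
        chrom = genome.name
        genome = genome.sequence
    G = len(genome)
    if median_len is None:
        median_len = mean_len * 4.5 / 14.0  # nanopore-like mean/median ratio
    mu = math.log(median_len)
    sigma = math.sqrt(max(2.0 * math.log(mean_len / median_len), 1e-12))
    rng = np.random.default_rng(seed)
    codes = qm.encode(genome)
    sub_table = np.full((1, 3), -1, dtype=np.int8)
    conf = 0.0
    if qmap is not None and confusion_weight > 0 and error_rate > 0:
        cfg = cfg or qm.compute_thresholds(qmap, 3)
        sub_table = confusable_sub_table(qmap, cfg)
        conf = confusion_weight
    Q = qmap.Q if qmap is not None else 6
    target_bases = coverage * G
    reads = []
    total = 0
    i = 0
    while total < target_bases:
        L = int(np.clip(rng.lognormal(mu, sigma), min_len, min(max_len, G)))
        start = int(rng.integers(0, G - L + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        frag = codes[start : start + L]
        if strand == "-":
            frag = qm.encode(qm.reverse_complement(decode(frag)))
        if error_rate > 0:
            rate = float(
                np.clip(rng.normal(error_rate, error_rate_sd), 0.02, 0.3)
            )
            frag = corrupt_read(
                np.ascontiguousarray(frag),
                rate * error_split[0],
                rate * error_split[1],
                rate * error_split[2],
                conf,
                sub_table,
                Q,
                int(rng.integers(0, 2 ** 31 - 1)),
            )
        reads.append(
            SimulatedRead(
                name=f"read{i}",
                sequence=decode(frag),
                chrom=chrom,
                start=start,
                end=start + L,
                strand=strand,
            )
        )
        total += L
        i += 1
    return reads
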