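"""SV benchmarking: truth/call matching, breakpoint and length-similarity
scores, precision/recall/F1, the union model, and complementary-call
classification.

The breakpoint score of a call against its truth entry is
``(|i' - i| + |j' - j|) / 2`` (mean absolute offset of the two
breakpoints; lower is better).  Length similarity is
``min(L_t, L_c) / max(L_t, L_c)``.  Matching requires same type and
chromosome, breakpoint score within ``refdist`` and length similarity at
least ``min_len_sim`` (0.7, the usual Truvari default), assigned
one-to-one greedily by ascending breakpoint score.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SVCall:
    chrom: str
    start: int
    end: int
    type: str  # INS | DEL | INV
    length: int
    id: str = ""
    origin: str = ""

    def __post_init__(self):
        if self.type == "INS":
            self.end = self.start  # END is degenerate for insertions
        if self.start > self.end:
            raise ValueError("start > end")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass
class SVMatch:
    truth: SVCall
    call: SVCall
    bp_score: float
    len_sim: float


@dataclass
class BenchResult:
    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self):
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        pr = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / pr if pr > 0 else 0.0


def breakpoint_score(truth: SVCall, call: SVCall) -> float:
    """Mean absolute breakpoint offset; for INS both ends sit at the
    insertion point, so this reduces to |Δstart|."""
    if truth.chrom != call.chrom:
        raise ValueError("chromosome mismatch")
    return (abs(call.start - truth.start) + abs(call.end - truth.end)) / 2.0


def length_similarity(truth: SVCall, call: SVCall) -> float:
    if truth.length < 1 or call.length < 1:
        raise ValueError("zero-length SV")
    lo, hi = sorted((truth.length, call.length))
    return lo / hi


def match_calls(truth_set, call_set, refdist=500, min_len_sim=0.7):
    """One-to-one greedy truth/call matching.

    Returns (matches, BenchResult); unmatched calls count as FP, unmatched
    truth entries as FN.
    """
    candidates = []
    for ti, t in enumerate(truth_set):
        for ci, c in enumerate(call_set):
            if t.type != c.type or t.chrom != c.chrom:
                continue
            bp = breakpoint_score(t, c)
            if bp > refdist:
                continue
            ls = length_similarity(t, c)
            if ls < min_len_sim:
                continue
            candidates.append((bp, t.start, c.start, ti, ci, ls))
    candidates.sort()
    used_t, used_c = set(), set()
    matches = []
    for bp, _, _, ti, ci, ls in candidates:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matches.append(SVMatch(truth_set[ti], call_set[ci], bp, ls))
    result = BenchResult(
        tp=len(matches),
        fp=len(call_set) - len(matches),
        fn=len(truth_set) - len(matches),
    )
    return matches, result


def union_model(calls_a, calls_b, refdist=500, min_len_sim=0.7):
    """Deduplicated union: every call of A, plus each call of B with no
    A-counterpart under the matching gate (A's record kept for duplicates)."""
    matches, _ = match_calls(calls_a, calls_b, refdist, min_len_sim)
    matched_b = {id(m.call) for m in matches}
    return list(calls_a) + [c for c in calls_b if id(c) not in matched_b]


def classify_complementary(only_in_a, calls_b, relaxed_min_len_sim=0.0, refdist=500):
    """Partition calls unique to method A at the default gate into those
    captured by method B at a relaxed length-similarity threshold and those
    genuinely unique."""
    matches, _ = match_calls(
        only_in_a, calls_b, refdist=refdist, min_len_sim=relaxed_min_len_sim
    )
    captured_ids = {id(m.truth) for m in matches}
    captured = [c for c in only_in_a if id(c) in captured_ids]
    unique = [c for c in only_in_a if id(c) not in captured_ids]
    return {"captured_at_lower_similarity": captured, "unique": unique}


def filter_bed(calls, intervals_by_chrom, exclude=True):
    """Keep (or drop) calls overlapping the given intervals
    ({chrom: [(start, end), ...]}), e.g. a centromere mask."""
    from intervaltree import IntervalTree

    trees = {
        chrom: IntervalTree.from_tuples((s, max(e, s + 1)) for s, e in ivls)
        for chrom, ivls in intervals_by_chrom.items()
    }
    out = []
    for c in calls:
        tree = trees.get(c.chrom)
        hit = bool(tree.overlap(c.start, max(c.end, c.start + 1))) if tree else False
        if hit != exclude:
            out.append(c)
    return out


def read_bed(path):
    intervals = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e = line.split()[:3]
            intervals.setdefault(chrom, []).append((int(s), int(e)))
    return intervals


def read_vcf(path, origin=""):
    """Read SV calls from a VCF 4.2 with SVTYPE/SVLEN/END info keys (or
    symbolic ALTs)."""
    import pysam

    calls = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = rec.info
            svtype = info.get("SVTYPE")
            if svtype is None and rec.alts:
                alt = rec.alts[0]
                if alt.startswith("<") and alt.endswith(">"):
                    svtype = alt[1:-1]
            if svtype not in ("INS", "DEL", "INV"):
                continue
            svlen = info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            end = rec.stop
            start = rec.pos - 1  # to 0-based
            if svlen is None:
                svlen = end - start if svtype != "INS" else 0
            length = abs(int(svlen))
            if length < 1:
                length = max(end - start, 1)
            calls.append(
                SVCall(
                    chrom=rec.chrom,
                    start=start,
                    end=start if svtype == "INS" else end,
                    type=svtype,
                    length=length,
                    id=rec.id or f"{origin}_{len(calls)}",
                    origin=origin,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def write_vcf(calls, path, contigs, genome=None):
    """Write a minimal VCF 4.2 with symbolic ALTs and SVTYPE/SVLEN/END."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(sorted(calls, key=lambda c: (c.chrom, c.start))):
            ref = "N"
            if genome is not None:
                seq = genome[c.chrom] if isinstance(genome, dict) else genome.sequences[c.chrom]
                if 0 <= c.start < len(seq):
                    ref = seq[c.start]
            svlen = -c.length if c.type == "DEL" else c.length
            end = c.start + c.length if c.type in ("DEL", "INV") else c.start + 1
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t{c.id or 'sv%d' % i}\t{ref}\t<{c.type}>\t.\tPASS\t"
                f"SVTYPE={c.type};SVLEN={svlen};END={end}\n"
            )
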