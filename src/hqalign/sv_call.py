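"""Minimal structural-variant caller from alignment records.

Deliberately the simplest caller sufficient for benchmarking on simulated
data — not a reimplementation of a production caller.  Signature sources:

* CIGAR: insertion/deletion runs within one alignment.  Runs of at least
  ``min_run`` bases separated by fewer than ``merge_gap`` aligned bases
  are merged first (long gaps fragment around chance matches, especially
  inside tandem repeats); the ``min_run`` floor keeps ubiquitous 1-3 base
  error indels out of the merge.
* split reads, opposite strand: a (+, -) record pair adjacent in query
  order brackets an inversion ending at the - segment's end (interval
  [end(+), end(-))); a (-, +) pair brackets one starting at the -
  segment's start ([start(-), start(+))).  A full +/-/+ triple yields the
  same interval from both of its pairs.  Junction pairs matter because an
  inversion longer than a read is only ever seen one junction at a time.
* split reads, same strand: a query gap much smaller than the reference
  gap is a deletion; much larger, an insertion.  This recovers SVs whose
  gap did not survive inside a single CIGAR.

Signatures from records below ``min_mapq`` are dropped.  Clustered
signatures (same type, within ``merge_window`` on a chromosome) emit one
call at the median position/length when supported by at least
``min_support`` distinct reads.  Two noise filters target tandem-repeat
slippage, the dominant artifact of noisy long reads in VNTR arrays:

* allele fraction: germline calls should be supported by most reads whose
  alignments span the locus; clusters with support below ``min_af`` of
  the spanning reads are slippage of a minority of reads.
* balanced pairs: a nearby INS/DEL call pair of similar small lengths is
  repeat-phase slippage, not two independent SVs.

All positions are nucleotide genome coordinates (``ref_start`` etc. of
the records), so the caller is domain-agnostic: for quantized records
CIGAR runs are in quantized symbols, which advance 1:1 with nucleotide
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align_core import AlignmentRecord, parse_cigar
from .sv_eval import SVCall


@dataclass
class SVSignature:
    read_name: str
    chrom: str
    position: int
    type: str  # INS | DEL | INV
    length: int
    source: str  # cigar | split
    # a gap run touching a read end observes only part of the event; its
    # length is a lower bound and is kept out of the cluster length median
    truncated: bool = False

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")


def _cigar_signatures(rec: AlignmentRecord, min_sv_len, merge_gap=500, min_run=20):
    raw = []
    ref = rec.ref_start
    for length, op in parse_cigar(rec.cigar):
        if op in ("M", "=", "X"):
            ref += length
        elif op == "D":
            if length >= min_run:
                raw.append(("DEL", ref, length))
            ref += length
        elif op == "I":
            if length >= min_run:
                raw.append(("INS", ref, length))
    merged = []
    for k, (svtype, pos, length) in enumerate(raw):
        if (
            merged
            and merged[-1][0] == svtype
            and pos - (merged[-1][1] + (merged[-1][2] if svtype == "DEL" else 0))
            <= merge_gap
        ):
            prev = merged[-1]
            merged[-1] = (svtype, prev[1], prev[2] + length, prev[3] or k == len(raw) - 1)
        else:
            merged.append((svtype, pos, length, k in (0, len(raw) - 1)))
    first_t = rec.ref_start
    last_t = rec.ref_end
    out = []
    for svtype, pos, length, edge in merged:
        if length < min_sv_len:
            continue
        trunc = svtype == "INS" and edge and (pos - first_t < 30 or last_t - pos < 30)
        out.append(
            SVSignature(
                rec.query_name, rec.target_name, pos, svtype, length, "cigar", trunc
            )
        )
    return out


def _split_signatures(
    records,
    min_sv_len,
    max_inv_len=50000,
    max_query_gap=500,
    max_del_len=50000,
    min_split_indel=200,
):
    out = []
    recs = sorted(records, key=lambda r: r.query_start)
    for a, b in zip(recs, recs[1:]):
        if a.target_name != b.target_name:
            continue
        # a large query gap between opposite-strand pieces is chimeric junk,
        # but between same-strand pieces it is exactly the split-read
        # insertion signal, so it is only bounded for the inversion case
        dq = b.query_start - a.query_end
        if a.strand != b.strand:
            if dq > max_query_gap:
                continue
            if a.strand == "+":
                start, end = a.ref_end, b.ref_end
            else:
                start, end = a.ref_start, b.ref_start
            length = end - start
            if min_sv_len <= length <= max_inv_len:
                out.append(
                    SVSignature(a.query_name, a.target_name, start, "INV", length, "split")
                )
            continue
        # same strand: reference gap vs query gap imbalance; record boundaries
        # carry ~10-100 bp of fuzz, so split evidence is only trusted for
        # events where that fuzz is relatively small
        min_len = max(min_sv_len, min_split_indel)
        if a.strand == "+":
            dt = b.ref_start - a.ref_end
            junction = a.ref_end
        else:
            dt = a.ref_start - b.ref_end
            junction = b.ref_end
        if dt - dq >= min_len and dt - dq <= max_del_len and dt >= 0:
            out.append(
                SVSignature(
                    a.query_name, a.target_name, junction, "DEL", dt - dq, "split"
                )
            )
        elif dq - dt >= min_len and dq >= 0:
            out.append(
                SVSignature(
                    a.query_name, a.target_name, max(junction + min(dt, 0), 0),
                    "INS", dq - dt, "split",
                )
            )
    # one signature per (read, rough interval): a +/-/+ triple reports its
    # inversion twice
    seen = set()
    uniq = []
    for s in out:
        key = (s.read_name, s.type, s.position // 100, s.length // 100)
        if key not in seen:
            seen.add(key)
            uniq.append(s)
    return uniq


def extract_signatures(records_by_read, min_sv_len=50, min_mapq=20):
    """SV signatures from per-read alignment records
    ({read name: [AlignmentRecord]})."""
    sigs = []
    for _, records in records_by_read.items():
        usable = [r for r in records if r.mapq >= min_mapq]
        for rec in usable:
            sigs.extend(_cigar_signatures(rec, min_sv_len))
        if len(usable) >= 2:
            sigs.extend(_split_signatures(usable, min_sv_len))
    return sigs


def _record_spans(records_by_read, min_mapq):
    """Per-record reference spans with read ids, per chromosome.

    Used for local spanning-read counts (allele fraction) and for
    coverage-inside-deletion checks.  Individual records, not per-read
    hulls: a hull can be inflated by a stray supplementary placement.
    """
    per: dict = {}
    for ridx, (_, records) in enumerate(records_by_read.items()):
        for rec in records:
            if rec.mapq < min_mapq:
                continue
            s, e, i = per.setdefault(rec.target_name, ([], [], []))
            s.append(rec.ref_start)
            e.append(rec.ref_end)
            i.append(ridx)
    return {
        chrom: (np.array(s), np.array(e), np.array(i))
        for chrom, (s, e, i) in per.items()
    }


def _length_modes(cluster):
    """Split a positional cluster into length-consistent sub-clusters.

    One locus can carry evidence at several scales at once — e.g. a large
    insertion plus small junction-fuzz indels from the same region; a
    single median over such a mixture lands between the modes.  Sorted
    lengths are broken where the next length exceeds 1.8x the previous
    plus 50 bp; end-truncated signatures (length lower bounds) join the
    largest mode as support.
    """
    full = sorted((s for s in cluster if not s.truncated), key=lambda s: s.length)
    trunc = [s for s in cluster if s.truncated]
    if not full:
        return [trunc] if trunc else []
    modes = [[full[0]]]
    for s in full[1:]:
        if s.length > modes[-1][-1].length * 1.8 + 50:
            modes.append([s])
        else:
            modes[-1].append(s)
    if trunc:
        modes[-1].extend(trunc)
    return modes


def _emit_call(
    chrom, svtype, mode, min_support, spans, min_af, span_margin, max_len_cv, max_cv_len
):
    support = {c.read_name for c in mode}
    if len(support) < min_support:
        return None
    pos = int(round(float(np.median([c.position for c in mode]))))
    full = [c.length for c in mode if not c.truncated]
    lens = np.array(full or [c.length for c in mode], dtype=float)
    length = int(round(float(np.median(lens))))
    # short calls with inconsistent lengths are repeat slippage; true short
    # SVs are reproduced near-exactly by every supporting read
    if length <= max_cv_len and np.std(lens) / max(length, 1) > max_len_cv:
        return None
    end = pos + length if svtype in ("DEL", "INV") else pos
    if spans is not None and chrom in spans:
        starts, ends, rids = spans[chrom]
        sel = (starts <= pos - span_margin) & (ends >= end + span_margin)
        n_span = len(np.unique(rids[sel]))
        if len(support) < min_af * n_span:
            return None
        if svtype == "DEL" and length >= 1000:
            # a real deletion leaves (almost) no reads mapping inside it;
            # split-read pairs bridging repeat copies fabricate deletions
            # over normally covered sequence
            inside = (starts >= pos + span_margin) & (ends <= end - span_margin)
            n_inside = len(np.unique(rids[inside]))
            flank = (starts <= pos - 3 * span_margin) & (ends >= pos - span_margin)
            n_flank = len(np.unique(rids[flank]))
            if n_inside >= 0.35 * max(n_flank, 1):
                return None
    return SVCall(
        chrom=chrom,
        start=pos,
        end=end,
        type=svtype,
        length=max(length, 1),
        id=f"{svtype.lower()}_{chrom}_{pos}",
        origin="call",
    )


def cluster_and_call(
    signatures,
    min_support=3,
    merge_window=500,
    records_by_read=None,
    min_af=0.6,
    min_mapq=20,
    span_margin=300,
    balanced_window=800,
    balanced_sim=0.5,
    balanced_max_len=1000,
    max_len_cv=0.35,
    max_cv_len=500,
):
    """Single-linkage clustering by position within (chrom, type); clusters
    supported by >= min_support distinct reads emit one call with median
    position and length.  Output is independent of input order.

    When ``records_by_read`` is given, calls supported by fewer than
    ``min_af`` of the reads spanning the locus are dropped (slippage
    filter), and nearby small INS/DEL pairs of similar length are removed
    as balanced slippage artifacts.
    """
    # coverage counts use all records regardless of mapping quality: a locus
    # buried in repeats is still covered, and slippage support must be
    # measured against true local depth
    spans = (
        _record_spans(records_by_read, 0) if records_by_read is not None else None
    )
    by_group: dict = {}
    for s in signatures:
        by_group.setdefault((s.chrom, s.type), []).append(s)
    calls = []
    for (chrom, svtype), group in sorted(by_group.items()):
        group.sort(key=lambda s: (s.position, s.length, s.read_name))
        cluster = []
        for s in group + [None]:
            if s is not None and (
                not cluster or s.position - cluster[-1].position <= merge_window
            ):
                cluster.append(s)
                continue
            # one germline event per locus: length modes are tried in order
            # of support x median length and the first one that passes the
            # filters is the locus call.  Weighting by length matters: a
            # large event is always accompanied by small junction-fuzz
            # evidence, often from more reads than can span the event
            # itself, and raw support would elect the fuzz.
            def _mode_weight(m):
                full = [c.length for c in m if not c.truncated] or [
                    c.length for c in m
                ]
                return len({c.read_name for c in m}) * float(np.median(full))

            modes = sorted(
                _length_modes(cluster), key=lambda m: (-_mode_weight(m), -len(m))
            )
            for mode in modes:
                call = _emit_call(
                    chrom, svtype, mode, min_support, spans, min_af,
                    span_margin, max_len_cv, max_cv_len,
                )
                if call is not None:
                    calls.append(call)
                    break
            cluster = [s] if s is not None else []
    # small INS/DEL calls near an inversion breakpoint are split-alignment
    # junction debris of the inversion, not independent events; the debris
    # zone extends a few hundred bases on either side of each breakpoint
    inv_bps = [
        (c.chrom, bp) for c in calls if c.type == "INV" for bp in (c.start, c.end)
    ]
    calls = [
        c
        for c in calls
        if not (
            c.type in ("INS", "DEL")
            and c.length < 1000
            and any(ch == c.chrom and abs(c.start - bp) < 800 for ch, bp in inv_bps)
        )
    ]
    if spans is not None:
        drop = set()
        for i, a in enumerate(calls):
            for j in range(i + 1, len(calls)):
                b = calls[j]
                if (
                    {a.type, b.type} == {"INS", "DEL"}
                    and a.chrom == b.chrom
                    and abs(a.start - b.start) <= balanced_window
                    and max(a.length, b.length) <= balanced_max_len
                    and min(a.length, b.length) / max(a.length, b.length)
                    >= balanced_sim
                ):
                    drop.add(i)
                    drop.add(j)
        calls = [c for i, c in enumerate(calls) if i not in drop]
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def call_svs(records_by_read, min_sv_len=50, min_support=3, merge_window=500, min_mapq=20):
    """Convenience: extract signatures and cluster into calls with the
    slippage filters enabled."""
    sigs = extract_signatures(records_by_read, min_sv_len=min_sv_len, min_mapq=min_mapq)
    return cluster_and_call(
        sigs,
        min_support=min_support,
        merge_window=merge_window,
        records_by_read=records_by_read,
        min_mapq=min_mapq,
    )
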