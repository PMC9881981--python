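"""Alignment-quality metrics.

A read is *well-aligned* when its primary alignment spans at least 90% of
the read (in the record's own domain) with mapping quality above 20.  The
*normalized edit distance* of an alignment is the nucleotide Levenshtein
distance between the full read and the genome slice at the alignment's
coordinates, divided by the read length — for quantized records only the
coordinates come from the quantized alignment (back-translated); the edit
distance itself is always computed on nucleotide sequences.  The
*normalized alignment length* is the target span over the read length in
the matching domain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align_core import AlignmentRecord, edit_distance


def domain_read_length(record: AlignmentRecord, n: int, Q: int = 6) -> int:
    return n if record.domain == "nucleotide" else max(n - Q + 1, 0)


def is_well_aligned(record: AlignmentRecord, read_length_in_domain: int) -> bool:
    span = record.target_end - record.target_start
    return span >= 0.9 * read_length_in_domain and record.mapq > 20


def normalized_edit_distance(read_seq: str, target_seq: str, start: int, end: int) -> float:
    """edit_distance(read, target[start:end]) / len(read), both nucleotide."""
    if not read_seq:
        raise ValueError("empty read")
    if not (0 <= start < end <= len(target_seq)):
        raise ValueError(f"bad slice [{start}, {end})")
    return edit_distance(read_seq, target_seq[start:end]) / len(read_seq)


def record_ned(record: AlignmentRecord, read_seq: str, genome) -> float:
    """Normalized edit distance of a record, using nucleotide coordinates
    for nucleotide records and back-translated coordinates for quantized
    records.  Reverse-strand reads are compared in their aligned
    orientation."""
    from .qmer_model import reverse_complement

    target = genome.sequences[record.target_name]
    if record.strand == "-":
        read_seq = reverse_complement(read_seq)
    return normalized_edit_distance(read_seq, target, record.ref_start, record.ref_end)


def normalized_alignment_length(start: int, end: int, read_length_in_domain: int) -> float:
    if start > end:
        raise ValueError("start > end")
    if read_length_in_domain <= 0:
        raise ValueError("read length must be positive")
    return (end - start) / read_length_in_domain


def ols_fit(x, y):
    """Closed-form ordinary least squares y = a*x + b; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    xm, ym = x.mean(), y.mean()
    var = np.sum((x - xm) ** 2)
    if var == 0:
        raise ValueError("degenerate x")
    slope = np.sum((x - xm) * (y - ym)) / var
    return float(slope), float(ym - slope * xm)


def primary_record(records):
    """Representative record of a read: highest mapq, then score."""
    prim = [r for r in records if not r.is_supplementary] or records
    return max(prim, key=lambda r: (r.mapq, r.score)) if prim else None


def summarize_cohort(records_a, records_b, reads, genome, Q: int = 6) -> dict:
    """Cohort comparison of two alignment methods.

    ``records_a``/``records_b`` map read name -> records.  Returns percent
    well-aligned per method and the OLS regression (slope, intercept) of
    method-B normalized edit distance against method A over reads aligned
    by both.
    """
    seqs = {r.name: r.sequence for r in reads}
    rows = []
    for name, seq in seqs.items():
        ra = primary_record(records_a.get(name, []))
        rb = primary_record(records_b.get(name, []))
        wa = (
            is_well_aligned(ra, domain_read_length(ra, len(seq), Q)) if ra else False
        )
        wb = (
            is_well_aligned(rb, domain_read_length(rb, len(seq), Q)) if rb else False
        )
        na = record_ned(ra, seq, genome) if ra else np.nan
        nb = record_ned(rb, seq, genome) if rb else np.nan
        rows.append((name, wa, wb, na, nb))
    df = pd.DataFrame(
        rows, columns=["read", "well_a", "well_b", "ned_a", "ned_b"]
    ).set_index("read")
    common = df.dropna(subset=["ned_a", "ned_b"])
    if len(common) >= 2:
        slope, intercept = ols_fit(common["ned_a"], common["ned_b"])
    else:
        raise ValueError("fewer than 2 reads aligned by both methods")
    return {
        "pct_well_aligned_a": 100.0 * df["well_a"].mean(),
        "pct_well_aligned_b": 100.0 * df["well_b"].mean(),
        "n_reads": len(df),
        "n_common": len(common),
        "slope": slope,
        "intercept": intercept,
        "table": df,
    }
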