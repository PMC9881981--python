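"""Two-stage hybrid alignment.

Stage 1 aligns the nucleotide read to the nucleotide genome to locate
regions of interest (ROIs).  Each ROI is extended on both sides by
``b_i = max(1 - f_i, 0.25) * n`` bases, where ``f_i`` is the fraction of
the read covered by the stage-1 alignment, then the quantized read and
its quantized reverse complement are both re-aligned to the quantized
extended target slice.  Both orientations must be aligned explicitly:
quantization has no complement operation, so the reverse-complement
query cannot be derived from the forward quantized sequence.  Scoring
both inside one ROI is what lets a single read produce the +/-/+
split-alignment signature over an inverted segment.

Quantized records carry their coordinates in the quantized frame
(``target_start``/``target_end``) and back-translated nucleotide genome
coordinates (``ref_start``/``ref_end``): a quantized symbol at position p
covers nucleotide bases p..p+Q-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import qmer_model as qm
from .align_core import (
    AlignParams,
    AlignmentRecord,
    MinimizerIndex,
    align_queries,
    build_minimizer_index,
    compute_mapq,
    quantized_params,
)

logger = logging.getLogger(__name__)


@dataclass
class Read:
    name: str
    sequence: str

    @property
    def n(self) -> int:
        return len(self.sequence)


class ReferenceGenome:
    """Ordered named nucleotide sequences with cached integer encodings."""

    def __init__(self, sequences: dict):
        if not sequences:
            raise ValueError("empty genome")
        self.names = list(sequences.keys())
        self.sequences = dict(sequences)
        self.codes = {n: qm.encode(s) for n, s in sequences.items()}
        self.lengths = {n: len(s) for n, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path):
        from .io_utils import read_fasta

        return cls(read_fasta(path))


@dataclass
class RegionOfInterest:
    """A stage-1 hit [s, e) on a target, with extension to [s_q, e_q)."""

    index: int
    target_name: str
    s: int
    e: int
    f: float
    b: int = 0
    s_q: int = 0
    e_q: int = 0


def extend_roi(roi: RegionOfInterest, n: int, target_length: int) -> RegionOfInterest:
    """Extension rule: b = round(max(1 - f, 0.25) * n), clamped to the
    target; f is clamped to [0, 1] first (stage-1 spans can exceed the read
    length across deletions)."""
    f = min(max(roi.f, 0.0), 1.0)
    b = int(round(max(1.0 - f, 0.25) * n))
    roi.b = b
    roi.s_q = max(roi.s - b, 0)
    roi.e_q = min(roi.e + b, target_length)
    return roi


def map_quantized_to_nucleotide(qstart: int, qend: int, roi_offset, Q: int):
    """Back-translate quantized-frame coordinates to nucleotide coordinates.

    A quantized symbol at p covers bases p..p+Q-1, so the half-open
    nucleotide span of quantized [qstart, qend) is
    [offset + qstart, offset + qend + Q - 1).
    """
    if isinstance(roi_offset, RegionOfInterest):
        roi_offset = roi_offset.s_q
    if qstart < 0 or qend <= qstart:
        raise ValueError("need 0 <= qstart < qend")
    return roi_offset + qstart, roi_offset + qend + Q - 1


def merge_rois(rois):
    """Merge extended ROIs overlapping on the same target."""
    out = []
    for roi in sorted(rois, key=lambda r: (r.target_name, r.s_q)):
        if out and out[-1].target_name == roi.target_name and roi.s_q <= out[-1].e_q:
            prev = out[-1]
            prev.e_q = max(prev.e_q, roi.e_q)
            prev.s = min(prev.s, roi.s)
            prev.e = max(prev.e, roi.e)
        else:
            out.append(roi)
    return out


@dataclass
class PipelineStats:
    reads: int = 0
    unmapped: int = 0
    orientations_scored: int = 0
    rois: int = 0


class HybridAligner:
    """Reusable two-stage aligner bound to one reference genome."""

    def __init__(
        self,
        genome: ReferenceGenome,
        qmap: qm.QmerMap,
        cfg: qm.QuantizerConfig | None = None,
        nt_params: AlignParams | None = None,
        q_params: AlignParams | None = None,
        max_rois: int = 4,
    ):
        self.genome = genome
        self.qmap = qmap
        self.cfg = cfg or qm.compute_thresholds(qmap, 3)
        self.nt_params = nt_params or AlignParams()
        self.q_params = q_params or quantized_params(self.cfg.L)
        self.max_rois = max_rois
        self.stats = PipelineStats()
        self._level_table = qm.level_table(qmap, self.cfg)
        self.nt_index = build_minimizer_index(
            genome.codes,
            self.nt_params.k,
            self.nt_params.w,
            self.nt_params.alphabet_size,
        )
        # whole-genome quantized levels per chromosome (slices of this are
        # exactly the quantization of the corresponding nucleotide slices)
        self._qlevels = {
            name: qm.quantize_codes(codes, qmap, self.cfg, self._level_table)
            for name, codes in genome.codes.items()
        }

    # -- stage 1 ------------------------------------------------------------

    def stage1_records(self, read: Read):
        fwd = qm.encode(read.sequence)
        rev = qm.encode(qm.reverse_complement(read.sequence))
        self.stats.orientations_scored += 2
        return align_queries(
            read.name, fwd, rev, self.nt_index, self.nt_params, domain="nucleotide"
        )

    def stage1_align(self, read: Read, records=None):
        """Regions of interest from stage-1 alignment (one per retained
        record), extended and merged."""
        records = self.stage1_records(read) if records is None else records
        rois = []
        n = read.n
        for i, rec in enumerate(records[: self.max_rois]):
            roi = RegionOfInterest(
                index=i,
                target_name=rec.target_name,
                s=rec.target_start,
                e=rec.target_end,
                f=(rec.target_end - rec.target_start) / n,
            )
            extend_roi(roi, n, self.genome.lengths[rec.target_name])
            rois.append(roi)
        return merge_rois(rois)

    # -- stage 2 ------------------------------------------------------------

    def _guide_anchors(self, records, roi, n_read):
        """Sparse (qpos, tpos) guide anchors in the quantized frame, sampled
        from stage-1 match runs.

        Quantized seeds alone can be ambiguous (tandem-repeat phase) or
        absent (error clusters corrupt Q consecutive symbols); carrying the
        stage-1 correspondence into stage-2 chaining keeps the quantized
        re-alignment anchored to the nucleotide placement while its own
        seeds decide everywhere they exist.  Record CIGARs are stored in
        the aligned orientation, which is exactly the frame of the matching
        quantized query, so offsets carry over directly.
        """
        from .align_core import parse_cigar

        Q = self.qmap.Q
        step = 256
        out = {0: ([], []), 1: ([], [])}
        for rec in records:
            if rec.target_name != roi.target_name:
                continue
            if rec.ref_end <= roi.s_q or rec.ref_start >= roi.e_q:
                continue
            orient = 0 if rec.strand == "+" else 1
            q, t = 0, rec.target_start
            for length, op in parse_cigar(rec.cigar):
                if op == "S":
                    q += length
                elif op == "M":
                    offsets = list(range(0, length, step))
                    if length - 1 not in offsets:
                        offsets.append(length - 1)  # pin the run's far end
                    for off in offsets:
                        qq, tt = q + off, t + off
                        if roi.s_q <= tt < roi.e_q - Q and qq < n_read - Q:
                            out[orient][0].append(qq)
                            out[orient][1].append(tt - roi.s_q)
                    q += length
                    t += length
                elif op == "I":
                    q += length
                elif op == "D":
                    t += length
        return out

    def stage2_align(self, read: Read, rois, stage1_records=()):
        """Quantized re-alignment of the read (both orientations) inside
        each extended ROI."""
        Q = self.qmap.Q
        if read.n < Q:
            return []
        qx = qm.quantize_codes(
            qm.encode(read.sequence), self.qmap, self.cfg, self._level_table
        )
        qxr = qm.quantize_codes(
            qm.encode(qm.reverse_complement(read.sequence)),
            self.qmap,
            self.cfg,
            self._level_table,
        )
        all_records = []
        for roi in rois:
            span = roi.e_q - roi.s_q
            if span < Q + self.q_params.k:
                logger.warning(
                    "ROI %s:%d-%d shorter than a quantized seed; skipped",
                    roi.target_name,
                    roi.s_q,
                    roi.e_q,
                )
                continue
            slice_levels = self._qlevels[roi.target_name][
                roi.s_q : roi.e_q - Q + 1
            ]
            index = MinimizerIndex(
                [roi.target_name],
                [slice_levels],
                self.q_params.k,
                self.q_params.w,
                self.q_params.alphabet_size,
            )
            self.stats.orientations_scored += 2
            guides = self._guide_anchors(stage1_records, roi, read.n)
            recs = align_queries(
                read.name, qx, qxr, index, self.q_params, domain="quantized",
                seed_anchors=guides,
            )
            n_dom = len(qx)
            tlen = self.genome.lengths[roi.target_name]
            for rec in recs:
                rec.target_start += roi.s_q
                rec.target_end += roi.s_q
                rec.ref_start, rec.ref_end = map_quantized_to_nucleotide(
                    rec.target_start - roi.s_q, rec.target_end - roi.s_q, roi.s_q, Q
                )
                # a single base error at a read end corrupts every window
                # covering it, so the quantized alignment is blind to the
                # outermost few bases; extrapolate short unaligned
                # remainders diagonally (capped at 2Q) when estimating the
                # nucleotide span
                head, tail = rec.query_start, n_dom - rec.query_end
                if rec.strand == "-":
                    head, tail = tail, head
                rec.ref_start = max(rec.ref_start - min(head, 2 * Q), 0)
                rec.ref_end = min(rec.ref_end + min(tail, 2 * Q), tlen)
                rec.tags["roi"] = (roi.s_q, roi.e_q)
            all_records.extend(recs)
        if not all_records:
            return []
        all_records.sort(
            key=lambda r: (
                -((r.query_end - r.query_start) - r.nm),
                -r.score,
                r.target_start,
                r.target_name,
                r.strand,
            )
        )
        # re-rank primary across ROIs; penalize mapq when another ROI offers
        # a comparable-scoring home for the same query interval
        best = all_records[0]
        best.is_supplementary = False
        second = 0
        for rec in all_records[1:]:
            rec.is_supplementary = True
            qov = min(best.query_end, rec.query_end) - max(
                best.query_start, rec.query_start
            )
            if qov >= 0.5 * (best.query_end - best.query_start):
                second = max(second, rec.score)
        if second > 0 and best.score > 0:
            best.mapq = min(
                best.mapq, compute_mapq(best.score, second, best.n_anchors)
            )
        return all_records

    # -- end to end ----------------------------------------------------------

    def align_read(self, read: Read):
        """(stage-1 nucleotide records, stage-2 quantized records)."""
        self.stats.reads += 1
        s1 = self.stage1_records(read)
        if not s1:
            self.stats.unmapped += 1
            return [], []
        rois = self.stage1_align(read, records=s1)
        self.stats.rois += len(rois)
        s2 = self.stage2_align(read, rois, stage1_records=s1)
        return s1, s2


def run_hqalign(reads, genome, qmap, cfg=None, out_sam=None, **kwargs):
    """Align reads end to end; returns {read name: quantized records} and
    optionally writes a SAM file (unmapped reads included as unmapped
    records)."""
    aligner = HybridAligner(genome, qmap, cfg, **kwargs)
    results = {}
    for read in reads:
        _, s2 = aligner.align_read(read)
        results[read.name] = s2
    if out_sam is not None:
        from .io_utils import write_sam

        write_sam(out_sam, genome, reads, results, Q=qmap.Q)
    return results, aligner.stats
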