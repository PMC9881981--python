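"""FASTA/FASTQ/SAM I/O glue (Biopython and pysam under the hood)."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import qmer_model as qm
from .align_core import parse_cigar


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict):
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path):
    """Reads from FASTA or FASTQ, sniffed by the first character."""
    from .hybrid_pipeline import Read

    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def quantized_fasta(path, names_to_levels: dict):
    """Quantized sequences as FASTA over the digit alphabet 0..L-1."""
    from .align_core import levels_to_str

    with open(path, "w") as fh:
        for name, levels in names_to_levels.items():
            fh.write(f">{name}\n{levels_to_str(levels)}\n")


def _sam_cigar_for(rec, Q):
    """Quantized CIGARs are padded by Q-1 M so spans match the nucleotide
    reference frame (a quantized symbol covers Q bases)."""
    if rec.domain != "quantized" or Q <= 1:
        return rec.cigar
    ops = parse_cigar(rec.cigar)
    # grow the last reference-consuming run
    for i in range(len(ops) - 1, -1, -1):
        if ops[i][1] == "M":
            ops[i] = (ops[i][0] + Q - 1, "M")
            break
    return "".join(f"{l}{op}" for l, op in ops)


def write_sam(path, genome, reads, records_by_read: dict, Q: int = 6):
    """Emit records as SAM (1-based on output; NM/AS tags; quantized-frame
    coordinates preserved in the XQ tag)."""
    import pysam

    header = pysam.AlignmentHeader.from_references(
        list(genome.names), [genome.lengths[n] for n in genome.names]
    )
    ref_ids = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            recs = records_by_read.get(read.name, [])
            if not recs:
                a = pysam.AlignedSegment(header)
                a.query_name = read.name
                a.flag = 4
                a.query_sequence = read.sequence
                out.write(a)
                continue
            for rec in recs:
                a = pysam.AlignedSegment(header)
                a.query_name = read.name
                flag = 0
                if rec.strand == "-":
                    flag |= 16
                if rec.is_supplementary:
                    flag |= 2048
                a.flag = flag
                a.reference_id = ref_ids[rec.target_name]
                a.reference_start = rec.ref_start
                a.mapping_quality = rec.mapq
                seq = read.sequence
                if rec.strand == "-":
                    seq = qm.reverse_complement(seq)
                a.query_sequence = seq
                a.cigarstring = _sam_cigar_for(rec, Q)
                a.set_tag("NM", rec.nm)
                a.set_tag("AS", rec.score)
                if rec.domain == "quantized":
                    a.set_tag("XQ", f"{rec.target_start},{rec.target_end}")
                out.write(a)


def read_sam(path):
    """SAM records back as AlignmentRecords ({read name: [records]});
    quantized coordinates are recovered from the XQ tag when present."""
    import pysam

    from .align_core import AlignmentRecord

    out: dict = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            out.setdefault(a.query_name, [])
            if a.is_unmapped:
                continue
            qlen = a.infer_read_length() or len(a.query_sequence or "")
            qs = a.query_alignment_start
            qe = a.query_alignment_end
            if a.is_reverse:
                qs, qe = qlen - a.query_alignment_end, qlen - a.query_alignment_start
            domain = "quantized" if a.has_tag("XQ") else "nucleotide"
            if domain == "quantized":
                ts, te = (int(v) for v in a.get_tag("XQ").split(","))
            else:
                ts, te = a.reference_start, a.reference_end
            out.setdefault(a.query_name, []).append(
                AlignmentRecord(
                    query_name=a.query_name,
                    target_name=a.reference_name,
                    query_start=qs,
                    query_end=qe,
                    target_start=ts,
                    target_end=te,
                    strand="-" if a.is_reverse else "+",
                    cigar=a.cigarstring or "",
                    score=int(a.get_tag("AS")) if a.has_tag("AS") else 0,
                    nm=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                    mapq=a.mapping_quality,
                    is_supplementary=a.is_supplementary,
                    domain=domain,
                    query_length=qlen,
                    ref_start=a.reference_start,
                    ref_end=a.reference_end,
                )
            )
    return out
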