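import numpy as np
import pytest

from hqalign import qmer_model as qm
from hqalign import synthetic_data as sd
from hqalign.align_core import validate_record
from hqalign.hybrid_pipeline import (
    HybridAligner,
    Read,
    ReferenceGenome,
    RegionOfInterest,
    extend_roi,
    map_quantized_to_nucleotide,
    merge_rois,
    run_hqalign,
)


@pytest.fixture(scope="module")
def setup():
    qmap = qm.synthesize_qmer_map(6, seed=11)
    cfg = qm.compute_thresholds(qmap, 3)
    g = sd.generate_genome(60_000, repeat_fraction=0.1, seed=12)
    genome = ReferenceGenome({g.name: g.sequence})
    return qmap, cfg, g, genome, HybridAligner(genome, qmap, cfg)


class TestExtendRoi:
    def _roi(self, s, e, f):
        return RegionOfInterest(0, "chr1", s, e, f)

    def test_full_alignment_quarter_extension(self):
        roi = extend_roi(self._roi(10_000, 11_000, 1.0), n=1000, target_length=50_000)
        assert roi.b == 250
        assert (roi.s_q, roi.e_q) == (9750, 11250)

    def test_half_alignment(self):
        roi = extend_roi(self._roi(10_000, 10_500, 0.5), n=1000, target_length=50_000)
        assert roi.b == 500

    def test_clamped_at_zero(self):
        roi = extend_roi(self._roi(100, 1100, 1.0), n=1000, target_length=50_000)
        assert roi.s_q == 0

    def test_f_above_one_clamped(self):
        roi = extend_roi(self._roi(0, 5000, 2.5), n=1000, target_length=50_000)
        assert roi.b == 250  # f clamps to 1 -> the 0.25n floor applies


class TestCoordinateBackTranslation:
    def test_single_window_covers_q_bases(self):
        assert map_quantized_to_nucleotide(0, 1, 0, 6) == (0, 6)

    def test_offset_arithmetic(self):
        assert map_quantized_to_nucleotide(10, 20, 100, 6) == (110, 125)

    def test_full_read_span(self):
        n, Q = 800, 6
        start, end = map_quantized_to_nucleotide(0, n - Q + 1, 0, Q)
        assert end - start == n

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            map_quantized_to_nucleotide(5, 5, 0, 6)


def test_merge_rois_overlapping():
    a = RegionOfInterest(0, "chr1", 100, 200, 1.0, s_q=50, e_q=260)
    b = RegionOfInterest(1, "chr1", 240, 400, 1.0, s_q=200, e_q=450)
    c = RegionOfInterest(2, "chr1", 5000, 5200, 1.0, s_q=4900, e_q=5300)
    merged = merge_rois([a, b, c])
    assert len(merged) == 2
    assert (merged[0].s_q, merged[0].e_q) == (50, 450)


class TestStage1:
    def test_exact_read_single_roi(self, setup):
        _, _, g, _, al = setup
        read = Read("r", g.sequence[20_000:23_000])
        rois = al.stage1_align(read)
        assert len(rois) == 1
        assert rois[0].s <= 20_000 < 23_000 <= rois[0].e + 1
        assert rois[0].f == pytest.approx(1.0, abs=0.01)

    def test_foreign_read_unmapped(self, setup):
        _, _, _, _, al = setup
        rng = np.random.default_rng(99)
        read = Read("r", "".join("ACGT"[i] for i in rng.integers(0, 4, 800)))
        assert al.stage1_align(read) == []


class TestStage2:
    def test_error_free_forward(self, setup):
        _, _, g, _, al = setup
        read = Read("r", g.sequence[20_000:23_000])
        s1, s2 = al.align_read(read)
        primary = s2[0]
        assert primary.strand == "+"
        assert primary.nm == 0
        assert primary.domain == "quantized"
        assert (primary.ref_start, primary.ref_end) == (20_000, 23_000)

    def test_reverse_complement_read(self, setup):
        _, _, g, _, al = setup
        read = Read("r", qm.reverse_complement(g.sequence[20_000:23_000]))
        _, s2 = al.align_read(read)
        assert s2[0].strand == "-"
        assert s2[0].nm == 0

    def test_both_orientations_scored(self, setup):
        qmap, cfg, g, genome, _ = setup
        al = HybridAligner(genome, qmap, cfg)
        before = al.stats.orientations_scored
        al.align_read(Read("r", g.sequence[10_000:12_000]))
        # one stage-1 call plus at least one ROI in stage 2
        assert al.stats.orientations_scored >= before + 4

    def test_records_validate(self, setup):
        _, _, g, _, al = setup
        rng = np.random.default_rng(7)
        reads = sd.simulate_reads(
            g.sequence, coverage=0.3, mean_len=2000, error_rate=0.1,
            qmap=al.qmap, cfg=al.cfg, seed=13,
        )
        for rd in reads:
            s1, s2 = al.align_read(Read(rd.name, rd.sequence))
            for rec in s1:
                validate_record(rec, target_length=len(g.sequence))
            for rec in s2:
                validate_record(rec)

    def test_back_translation_consistency(self, setup):
        """Re-quantizing the nucleotide slice at the back-translated
        coordinates reproduces the aligned quantized target segment."""
        qmap, cfg, g, _, al = setup
        read = Read("r", g.sequence[30_000:32_000])
        _, s2 = al.align_read(read)
        rec = s2[0]
        nslice = g.sequence[rec.ref_start : rec.ref_end]
        requant = qm.quantize(nslice, qmap, cfg).levels
        stored = al._qlevels[rec.target_name][rec.target_start : rec.target_end]
        assert requant.tolist() == stored.tolist()


class TestInversionSignature:
    def test_split_alignment_flips_orientation(self, setup):
        """A read over an inverted segment yields the +/-/+ split pattern
        in one region of interest — the capability quantized-only
        alignment lacks without an explicit reverse-complement query."""
        qmap, cfg, g, genome, al = setup
        inv_start, inv_len = 25_000, 400
        seq = g.sequence
        mutated = (
            seq[:inv_start]
            + qm.reverse_complement(seq[inv_start : inv_start + inv_len])
            + seq[inv_start + inv_len :]
        )
        read = Read("r", mutated[24_000:26_500])
        _, s2 = al.align_read(read)
        strands = [r.strand for r in sorted(s2, key=lambda r: r.query_start)]
        assert "-" in strands
        assert strands.count("+") >= 2
        minus = [r for r in s2 if r.strand == "-"][0]
        assert abs(minus.ref_start - inv_start) < 50
        assert abs(minus.ref_end - (inv_start + inv_len)) < 50


class TestRunHqalign:
    def test_error_free_cohort_all_perfect(self, setup):
        qmap, cfg, g, genome, _ = setup
        reads = [
            Read(f"r{i}", g.sequence[s : s + 1500])
            for i, s in enumerate(range(1000, 41_000, 4000))
        ]
        results, stats = run_hqalign(reads, genome, qmap, cfg)
        assert stats.unmapped == 0
        for name, recs in results.items():
            assert recs[0].nm == 0

    def test_empty_read_set(self, setup, tmp_path):
        qmap, cfg, _, genome, _ = setup
        out = tmp_path / "empty.sam"
        results, _ = run_hqalign([], genome, qmap, cfg, out_sam=out)
        text = out.read_text()
        assert text.startswith("@")
        assert results == {}

    def test_sam_round_trip(self, setup, tmp_path):
        import pysam

        qmap, cfg, g, genome, _ = setup
        reads = [Read("r0", g.sequence[5000:8000])]
        out = tmp_path / "out.sam"
        run_hqalign(reads, genome, qmap, cfg, out_sam=out)
        with pysam.AlignmentFile(str(out)) as sam:
            recs = list(sam)
        assert recs[0].query_name == "r0"
        assert recs[0].reference_start == 5000
        assert recs[0].infer_read_length() == 3000
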