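import itertools
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hqalign import qmer_model as qm
from hqalign.qmer_model import (
    DuplicateQmerError,
    MissingQmerError,
    NonNumericCurrentError,
    QmerMap,
    QuantizerConfig,
    WrongKmerLengthError,
    compute_thresholds,
    level_table,
    load_qmer_map,
    quantize,
    quantize_revcomp,
    reverse_complement,
    synthesize_qmer_map,
    to_current_levels,
)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=40)


def write_model(tmp_path, rows, header=True):
    path = tmp_path / "model.tsv"
    lines = ["kmer\tlevel_mean\tlevel_stdv"] if header else []
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def lexicographic_2mer_rows():
    return [
        (kmer, 80 + i, 1.5)
        for i, kmer in enumerate("".join(p) for p in itertools.product("ACGT", repeat=2))
    ]


class TestLoadQmerMap:
    def test_full_table_round_trip(self, tmp_path, qmap6):
        rows = [(k, v) for k, v in qmap6.currents.items()]
        path = write_model(tmp_path, rows)
        loaded = load_qmer_map(path, 6)
        assert len(loaded.currents) == 4096
        assert np.allclose(loaded.current_array, qmap6.current_array)

    def test_lexicographic_fixture(self, tmp_path):
        path = write_model(tmp_path, lexicographic_2mer_rows())
        m = load_qmer_map(path, 2)
        assert m.currents["AA"] == 80
        assert m.currents["TT"] == 95

    def test_missing_qmer_named(self, tmp_path):
        rows = [r for r in lexicographic_2mer_rows() if r[0] != "CG"]
        path = write_model(tmp_path, rows)
        with pytest.raises(MissingQmerError, match="CG"):
            load_qmer_map(path, 2)

    def test_duplicate_qmer(self, tmp_path):
        rows = lexicographic_2mer_rows() + [("AA", 99)]
        with pytest.raises(DuplicateQmerError):
            load_qmer_map(write_model(tmp_path, rows), 2)

    def test_non_numeric_current(self, tmp_path):
        rows = lexicographic_2mer_rows()
        rows[3] = ("AT", "not-a-number")
        with pytest.raises(NonNumericCurrentError):
            load_qmer_map(write_model(tmp_path, rows), 2)

    def test_wrong_kmer_length(self, tmp_path):
        rows = lexicographic_2mer_rows()
        rows[0] = ("AAA", 80)
        with pytest.raises(WrongKmerLengthError):
            load_qmer_map(write_model(tmp_path, rows), 2)


class TestSynthesize:
    def test_deterministic(self):
        a = synthesize_qmer_map(2, seed=7)
        b = synthesize_qmer_map(2, seed=7)
        assert a.currents == b.currents

    def test_range(self):
        m = synthesize_qmer_map(6, seed=1, current_range=(60, 120))
        assert len(m.currents) == 4096
        assert all(60 <= v <= 120 for v in m.currents.values())

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            synthesize_qmer_map(0, seed=1)

    def test_confusable_pair_shares_tertile(self):
        m = synthesize_qmer_map(3, seed=3)
        cfg = compute_thresholds(m, 3)
        levels = level_table(m, cfg)
        counts = np.bincount(levels, minlength=3)
        assert counts.max() >= 2  # some bin holds at least two 3-mers


class TestThresholds:
    def test_toy_equal_occupancy(self):
        toy = SimpleNamespace(Q=3, current_array=np.array([1.0, 2, 3, 4, 5, 6]))
        cfg = compute_thresholds(toy, 3)
        levels = np.searchsorted(cfg.thresholds, toy.current_array, side="left")
        assert np.bincount(levels, minlength=3).tolist() == [2, 2, 2]

    def test_l2_is_median(self, qmap6):
        cfg = compute_thresholds(qmap6, 2)
        assert cfg.thresholds[0] == pytest.approx(np.median(qmap6.current_array))

    def test_l1_rejected(self, qmap6):
        with pytest.raises(ValueError):
            compute_thresholds(qmap6, 1)

    def test_occupancy_balance_l3(self, qmap6):
        cfg = compute_thresholds(qmap6, 3)
        counts = np.bincount(level_table(qmap6, cfg), minlength=3)
        assert counts.max() - counts.min() <= 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            QuantizerConfig(L=3, thresholds=np.array([5.0, 5.0]))


class TestTranslation:
    def test_single_window(self, qmap2):
        seq = "AC"
        assert to_current_levels(seq, qmap2).tolist() == [qmap2.currents["AC"]]

    def test_too_short(self, qmap2):
        assert len(to_current_levels("A", qmap2)) == 0

    def test_sliding_lookup(self, tmp_path):
        path = write_model(tmp_path, lexicographic_2mer_rows())
        m = load_qmer_map(path, 2)
        out = to_current_levels("AAC", m)
        assert out.tolist() == [m.currents["AA"], m.currents["AC"]]


class TestQuantize:
    def test_all_below_first_threshold(self, qmap2):
        cfg = QuantizerConfig(L=3, thresholds=np.array([1e6, 2e6]))
        q = quantize("ACGTACGT", qmap2, cfg)
        assert set(q.levels.tolist()) == {0}

    def test_identical_quantization_exists(self, qmap2):
        """Distinct 8-mers whose windows share bins quantize identically."""
        cfg = compute_thresholds(qmap2, 3)
        rng = np.random.default_rng(0)
        seen = {}
        for _ in range(5000):
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
            key = tuple(quantize(s, qmap2, cfg).levels.tolist())
            if key in seen and seen[key] != s:
                assert quantize(seen[key], qmap2, cfg).levels.tolist() == list(key)
                return
            seen[key] = s
        pytest.fail("no confusable 8-mer pair found")

    def test_n_window_gets_middle_level(self, qmap6, cfg6):
        q = quantize("ACGTAN" + "ACGTAC", qmap6, cfg6)
        assert q.levels[0] == cfg6.L // 2  # window covers the N

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(DNA)
    def test_length_law(self, s):
        m = synthesize_qmer_map(2, seed=7)
        cfg = compute_thresholds(m, 3)
        assert len(quantize(s, m, cfg)) == max(len(s) - 1, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(DNA)
    def test_bin_consistency(self, s):
        """Every level equals the count of thresholds strictly below the
        window current (recomputed from the raw current translation)."""
        m = synthesize_qmer_map(2, seed=7)
        cfg = compute_thresholds(m, 3)
        levels = quantize(s, m, cfg).levels
        currents = to_current_levels(s, m)
        expect = np.searchsorted(cfg.thresholds, currents, side="left")
        assert levels.tolist() == expect.tolist()


class TestRevcomp:
    def test_definition(self, qmap2):
        cfg = compute_thresholds(qmap2, 3)
        s = "ACGTTGCAAC"
        assert (
            quantize_revcomp(s, qmap2, cfg).levels.tolist()
            == quantize(reverse_complement(s), qmap2, cfg).levels.tolist()
        )

    def test_same_length_as_forward(self, qmap2):
        cfg = compute_thresholds(qmap2, 3)
        s = "ACGTTGCA"
        assert len(quantize_revcomp(s, qmap2, cfg)) == len(quantize(s, qmap2, cfg))

    def test_involution(self, qmap2):
        cfg = compute_thresholds(qmap2, 3)
        s2 = reverse_complement("ACGTTGCAAC")
        assert (
            quantize_revcomp(s2, qmap2, cfg).levels.tolist()
            == quantize("ACGTTGCAAC", qmap2, cfg).levels.tolist()
        )

    def test_not_derivable_from_forward(self, qmap2):
        """There are sequences whose quantized reverse complement differs
        from the reversed forward quantization: the transform needs the
        nucleotide sequence, which is the reason stage 2 aligns both
        orientations explicitly."""
        cfg = compute_thresholds(qmap2, 3)
        found = False
        for codes in range(4 ** 5):
            s = "".join("ACGT"[(codes >> (2 * i)) & 3] for i in range(5))
            if (
                quantize_revcomp(s, qmap2, cfg).levels.tolist()
                != quantize(s, qmap2, cfg).levels[::-1].tolist()
            ):
                found = True
                break
        assert found
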