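"""Run detection against a brute-force oracle, spectrum semantics, tail
trimming, composition, CPM and positional frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drtkit import read_profiles as rp
from drtkit.seqio import ReadRecord


def brute_force_runs(seq: str, min_len: int):
    """Quadratic enumeration of maximal A/C/G/T runs (independent oracle)."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if seq[i] in "ACGT" and j - i >= min_len:
            runs.append(rp.Run(seq[i], i, j - i))
        i = j
    return runs


dna = st.text(alphabet="ACGTN", min_size=0, max_size=120)


class TestFindRuns:
    def test_single_run(self):
        assert rp.find_runs("AAAAA", 5) == [rp.Run("A", 0, 5)]

    def test_n_breaks_and_never_forms_runs(self):
        assert rp.find_runs("ACGTN", 2) == []
        assert rp.find_runs("AANAA", 2) == [rp.Run("A", 0, 2), rp.Run("A", 3, 2)]
        assert rp.find_runs("NNNNN", 1) == []

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            rp.find_runs("ACGT", 0)

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACGTN"))
        # skew toward long runs and N-rich content
        probs = np.array([0.45, 0.15, 0.1, 0.15, 0.15])
        for _ in range(1000):
            seq = "".join(rng.choice(alphabet, size=100, p=probs))
            for min_len in (1, 3, 5):
                assert rp.find_runs(seq, min_len) == \
                    brute_force_runs(seq, min_len)

    @settings(derandomize=True, max_examples=200)
    @given(seq=dna, min_len=st.integers(1, 10))
    def test_property_equals_oracle(self, seq, min_len):
        assert rp.find_runs(seq, min_len) == brute_force_runs(seq, min_len)


class TestSpectrum:
    def test_two_read_example(self):
        reads = [ReadRecord("a", "AAAAA"), ReadRecord("c", "CCCCC")]
        spec = rp.homopolymer_spectrum(reads, thresholds=[5])
        assert spec.cell("A", 5) == 50.0
        assert spec.cell("C", 5) == 50.0
        assert spec.cell("G", 5) == 0.0
        assert spec.cell("T", 5) == 0.0

    def test_read_counts_once_per_cell(self):
        # two A-runs of 10 in one read still count the read once
        reads = [ReadRecord("a", "A" * 10 + "C" + "A" * 10)]
        spec = rp.homopolymer_spectrum(reads, thresholds=[5, 10])
        assert spec.cell("A", 5) == 100.0
        assert spec.cell("A", 10) == 100.0
        run_level = rp.homopolymer_spectrum(reads, thresholds=[5, 10],
                                            count_runs=True)
        assert run_level.cell("A", 10) == 200.0

    def test_monotone_in_threshold(self, study_readset):
        spec = rp.homopolymer_spectrum(study_readset.reads[:2000])
        for base in "ACGT":
            row = spec.percent.loc[base].to_numpy()
            assert (np.diff(row) <= 1e-12).all()

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            rp.homopolymer_spectrum([])


class TestTrim:
    def test_simple_tail_removed(self):
        read = ReadRecord("r", "ACGTACGTCCCCC")
        trimmed, removed = rp.trim_polyc_tail(read, min_tail=5, max_mismatch=0)
        assert trimmed.seq == "ACGTACGT"
        assert removed == 5

    def test_untailed_read_unchanged(self):
        read = ReadRecord("r", "ACGTACGT")
        trimmed, removed = rp.trim_polyc_tail(read)
        assert trimmed == read and removed == 0

    def test_mismatch_budget_spans_noise_inside_tail(self):
        read = ReadRecord("r", "ACGTCCCTCCCC")
        trimmed, removed = rp.trim_polyc_tail(read, min_tail=5, max_mismatch=1)
        assert trimmed.seq == "ACGT"
        assert removed == 8

    def test_boundary_base_never_eaten(self):
        # window must be C-delimited: the last core A survives
        read = ReadRecord("r", "AAAAACCCCC")
        trimmed, removed = rp.trim_polyc_tail(read, min_tail=5, max_mismatch=1)
        assert trimmed.seq == "AAAAA"
        assert removed == 5

    def test_all_tail_read_dropped(self):
        read = ReadRecord("r", "CCCCCCC")
        trimmed, removed = rp.trim_polyc_tail(read)
        assert trimmed is None and removed == 7

    def test_five_prime_mode(self):
        read = ReadRecord("r", "CCCCCAGTT")
        trimmed, removed = rp.trim_polyc_tail(read, end="5p")
        assert trimmed.seq == "AGTT" and removed == 5

    def test_qualities_trimmed_with_sequence(self):
        read = ReadRecord("r", "ACGTCCCCC", "IIIIJJJJJ")
        trimmed, _ = rp.trim_polyc_tail(read)
        assert trimmed.qual == "IIII"

    @settings(derandomize=True, max_examples=300)
    @given(seq=st.text(alphabet="ACGTN", min_size=1, max_size=60))
    def test_idempotent(self, seq):
        if not seq:
            return
        read = ReadRecord("r", seq)
        once, _ = rp.trim_polyc_tail(read)
        if once is None:
            return
        twice, removed_again = rp.trim_polyc_tail(once)
        assert removed_again == 0
        assert twice == once

    def test_idempotent_on_simulated_tailed_reads(self, study_readset):
        reads = study_readset.reads[:1000]
        trimmed, _ = rp.trim_reads(reads)
        retrimmed, report = rp.trim_reads(trimmed)
        assert report.reads_trimmed == 0
        assert report.bases_removed == 0
        assert [r.seq for r in retrimmed] == [r.seq for r in trimmed]

    def test_trimming_reduces_pooled_c_on_tailed_set(self, study_readset):
        products = [
            r for r, t in zip(study_readset.reads, study_readset.truth)
            if t.label == "product"
        ]
        _, report = rp.trim_reads(products)
        assert report.composition_after["C"] < report.composition_before["C"]
        assert report.bases_removed >= report.reads_trimmed * rp.DEFAULT_MIN_TAIL

    def test_untailed_set_untouched(self):
        reads = [ReadRecord(f"r{i}", "ACGTACGTAG") for i in range(10)]
        out, report = rp.trim_reads(reads)
        assert report.reads_trimmed == 0 and report.bases_removed == 0
        assert [r.seq for r in out] == [r.seq for r in reads]


class TestComposition:
    def test_uniform(self):
        comp = rp.base_composition([ReadRecord("a", "AC"), ReadRecord("b", "GT")])
        assert comp == {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25, "N": 0.0}

    def test_pooled_weighting(self):
        # pooling weights by base count, not by read: A = 1/5
        comp = rp.base_composition([ReadRecord("a", "A"), ReadRecord("b", "CCCC")])
        assert comp["A"] == pytest.approx(0.2)
        assert comp["C"] == pytest.approx(0.8)

    def test_composition_sums_to_one(self, study_readset):
        comp = rp.base_composition(study_readset.reads[:500])
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)


class TestNCpm:
    def test_arithmetic(self):
        reads = [ReadRecord(f"r{i}", "ACGT") for i in range(995)]
        reads += [ReadRecord(f"n{i}", "NACG") for i in range(5)]
        report = rp.n_count_cpm(reads)
        assert report.total_n == 5
        assert report.cpm == pytest.approx(5000.0)

    def test_zero_iff_no_n(self):
        assert rp.n_count_cpm([ReadRecord("r", "ACGT")]).cpm == 0.0

    def test_invariant_under_duplication(self, study_readset):
        reads = study_readset.reads[:800]
        doubled = reads + [
            ReadRecord(r.id + "_dup", r.seq, r.qual) for r in reads
        ]
        assert rp.n_count_cpm(doubled).cpm == \
            pytest.approx(rp.n_count_cpm(reads).cpm)


class TestPositional:
    def test_identical_reads(self):
        reads = [ReadRecord(f"r{i}", "ACGT") for i in range(3)]
        mat = rp.positional_frequency(reads, max_pos=6)
        assert mat.freq.loc[1, "A"] == 1.0
        assert mat.freq.loc[4, "T"] == 1.0
        assert mat.coverage.loc[4] == 3
        assert mat.coverage.loc[5] == 0

    def test_mixed_position(self):
        reads = [ReadRecord("a", "AA"), ReadRecord("b", "AC")]
        mat = rp.positional_frequency(reads, max_pos=2)
        assert mat.freq.loc[2, "A"] == 0.5
        assert mat.freq.loc[2, "C"] == 0.5

    def test_columns_sum_to_one_where_covered(self, study_readset):
        mat = rp.positional_frequency(study_readset.reads[:3000])
        covered = mat.coverage > 0
        sums = mat.freq[covered.to_numpy()].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
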