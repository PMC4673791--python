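"""k-mer counting against a naive oracle, frequencies, and the matrix."""

import warnings

import numpy as np
import pytest

import kmerlogic as kl
from kmerlogic.errors import ParameterError, ValidationError


def naive_count(sequence: str, k: int, strand_mode: str) -> tuple[dict, int]:
    """Independent O(n*k) substring-scan oracle."""
    counts: dict[str, int] = {}
    valid = 0
    strands = [sequence]
    if strand_mode == "both":
        strands.append(kl.reverse_complement(sequence))
    for s in strands:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
            valid += 1
    return counts, valid


class TestCountKmers:
    @pytest.mark.parametrize(
        "seq,k,mode,expected,windows",
        [
            ("AAAA", 3, "forward", {"AAA": 2}, 2),
            ("ACGT", 2, "both", {"AC": 2, "CG": 2, "GT": 2}, 6),
            ("ANAA", 2, "forward", {"AA": 1}, 1),
        ],
    )
    def test_examples(self, seq, k, mode, expected, windows):
        c = kl.count_kmers(seq, k, mode)
        assert c.counts == expected
        assert c.valid_windows == windows

    def test_matches_naive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 1001))
            seq = "".join(rng.choice(list("ACGTN"), n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            k = int(rng.integers(3, 7))
            mode = ["forward", "both"][int(rng.integers(2))]
            if k > n:
                continue
            got = kl.count_kmers(seq, k, mode)
            expected, valid = naive_count(seq, k, mode)
            assert got.counts == expected
            assert got.valid_windows == valid

    def test_counts_sum_to_valid_windows(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), 500))
        c = kl.count_kmers(seq, 4, "both")
        assert sum(c.counts.values()) == c.valid_windows

    def test_k_longer_than_sequence_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            c = kl.count_kmers("ACG", 5)
        assert c.counts == {} and c.valid_windows == 0

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            kl.count_kmers("ACGT", 0)
        with pytest.raises(ParameterError):
            kl.count_kmers("ACGT" * 10, 13)


class TestToFrequencies:
    def test_single_word(self):
        fv = kl.to_frequencies(kl.count_kmers("AAAA", 3))
        assert fv.get("AAA") == 1.0 and fv.get("AAC") == 0.0

    def test_sum_is_one(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), 400))
            c = kl.count_kmers(seq, 4, "both")
            if c.valid_windows == 0:
                continue
            assert abs(sum(kl.to_frequencies(c).values.values()) - 1.0) < 1e-9

    def test_zero_windows_warns(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = kl.count_kmers("NNNN", 3)
        with pytest.warns(UserWarning, match="no valid windows"):
            fv = kl.to_frequencies(c)
        assert fv.values == {}

    def test_strand_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 600))
        fv = kl.to_frequencies(kl.count_kmers(seq, 4, "both"))
        for kmer in kl.all_kmers(4):
            assert fv.get(kmer) == fv.get(kl.reverse_complement(kmer))


class TestBuildMatrix:
    def test_shape_and_order(self, rng):
        recs = [
            kl.GenomeRecord(id=f"g{i}", sequence="".join(rng.choice(list("ACGT"), 300)))
            for i in range(4)
        ]
        m = kl.build_matrix(recs, k=4)
        assert m.values.shape == (256, 4)
        assert m.feature_order[:3] == ["AAAA", "AAAC", "AAAG"]
        m3 = kl.build_matrix(recs[:2], k=3)
        assert m3.values.shape == (64, 2)
        assert m3.feature_order[0] == "AAA"

    def test_columns_equal_frequency_vectors(self, rng):
        recs = [
            kl.GenomeRecord(id=f"g{i}", sequence="".join(rng.choice(list("ACGT"), 300)))
            for i in range(3)
        ]
        m = kl.build_matrix(recs, k=4, strand_mode="both")
        for j, rec in enumerate(recs):
            fv = kl.to_frequencies(kl.count_kmers(rec, 4, "both"))
            np.testing.assert_array_equal(m.values[:, j], fv.dense())

    def test_labels_copied(self):
        recs = [
            kl.GenomeRecord(id="a", sequence="ACGTACGT", lineage={"species": "x", "phylum": "p"}),
            kl.GenomeRecord(id="b", sequence="ACGTACGT", lineage={"species": "y"}),
        ]
        m = kl.build_matrix(recs, k=3)
        assert m.labels["species"] == ["x", "y"]
        assert m.labels["phylum"] == ["p", None]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            kl.build_matrix([], k=4)


class TestFilterRareClasses:
    def _matrix(self, sizes: dict[str, int]) -> kl.FeatureMatrix:
        labels = [c for c, n in sizes.items() for _ in range(n)]
        n = len(labels)
        return kl.FeatureMatrix(
            k=3,
            feature_order=kl.all_kmers(3),
            sample_ids=[f"s{i}" for i in range(n)],
            values=np.zeros((64, n)),
            labels={"species": labels},
        )

    def test_boundary_at_nine(self):
        m = self._matrix({"a": 8, "b": 9})
        out = kl.filter_rare_classes(m, "species")
        assert set(out.labels["species"]) == {"b"} and out.n_samples == 9

    def test_no_op_when_all_large(self):
        m = self._matrix({"a": 9, "b": 10})
        assert kl.filter_rare_classes(m, "species").n_samples == 19

    def test_mixed_sizes(self):
        m = self._matrix({"a": 10, "b": 9, "c": 2})
        out = kl.filter_rare_classes(m, "species")
        assert out.n_samples == 19
        assert set(out.labels["species"]) == {"a", "b"}

    def test_everything_filtered_errors(self):
        m = self._matrix({"a": 3})
        with pytest.raises(ValidationError):
            kl.filter_rare_classes(m, "species")


class TestMatrixRoundTrip:
    def test_tsv_round_trip(self, tmp_path, small_benchmark):
        _, _, _, matrix = small_benchmark
        path = tmp_path / "m.tsv"
        kl.write_matrix(matrix, path)
        back = kl.read_matrix(path)
        assert back.sample_ids == matrix.sample_ids
        assert back.feature_order == matrix.feature_order
        assert back.labels == matrix.labels
        np.testing.assert_allclose(back.values, matrix.values, rtol=1e-11)
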