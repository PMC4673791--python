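"""RIPPER- and PART-style learners on separable, degenerate, and XOR data."""

import json

import numpy as np
import pytest

import kmerlogic as kl
from kmerlogic.errors import ValidationError
from kmerlogic.rules import model_to_dict

from conftest import make_separable_matrix


def exhaustive_single_literal_zero_error(matrix, rank):
    """Oracle: does any one-literal decision list achieve zero training error?"""
    y = np.asarray(matrix.labels[rank], dtype=object)
    for fi in range(matrix.n_features):
        v = matrix.values[fi]
        for t in np.unique(v):
            above = v >= t
            for mask in (above, ~above):
                if mask.all() or not mask.any():
                    continue
                inside = set(y[mask])
                outside = set(y[~mask])
                if len(inside) == 1 and len(outside) == 1 and inside != outside:
                    return True
    return False


def training_predictions(model, matrix):
    fidx = matrix.feature_index()
    return [
        model.predict({f: matrix.values[fidx[f], j] for f in fidx})
        for j in range(matrix.n_samples)
    ]


class TestRipper:
    def test_separable_single_rule(self):
        m = make_separable_matrix()
        assert exhaustive_single_literal_zero_error(m, "species")
        model = kl.ripper_fit(m, "species", seed=0)
        assert len(model.rules) == 1
        assert len(model.rules[0].literals) == 1
        assert model.rules[0].literals[0].feature == "ACG"
        y = m.labels["species"]
        assert training_predictions(model, m) == y

    def test_separable_zero_training_error_matches_oracle(self, rng):
        # several random separable layouts: whenever the exhaustive oracle
        # finds a perfect one-literal list, the learner attains zero error
        for seed in range(5):
            m = make_separable_matrix(n_per_class=8, seed=seed)
            assert exhaustive_single_literal_zero_error(m, "species")
            model = kl.ripper_fit(m, "species", seed=seed)
            assert training_predictions(model, m) == m.labels["species"]

    def test_single_class_default_only(self):
        m = make_separable_matrix()
        m.labels["species"] = ["same"] * m.n_samples
        with pytest.warns(UserWarning, match="single class"):
            model = kl.ripper_fit(m, "species")
        assert model.rules == [] and model.default_class == "same"

    def test_empty_matrix_rejected(self):
        m = make_separable_matrix()
        empty = m.subset_samples([])
        with pytest.raises(ValidationError):
            kl.ripper_fit(empty, "species")

    def test_coverage_bookkeeping_replays_exactly(self, small_benchmark):
        _, _, _, matrix = small_benchmark
        model = kl.ripper_fit(matrix, "species", seed=3)
        y = np.asarray(matrix.labels["species"], dtype=object)
        fidx = matrix.feature_index()
        for rule in model.rules:
            m = np.ones(matrix.n_samples, dtype=bool)
            for lit in rule.literals:
                v = matrix.values[fidx[lit.feature]]
                m &= np.array([lit.matches(x) for x in v])
            p = int((m & (y == rule.conclusion)).sum())
            n = int(m.sum()) - p
            assert rule.coverage == (p, n)

    def test_seeded_determinism(self, small_benchmark):
        _, _, _, matrix = small_benchmark
        a = kl.ripper_fit(matrix, "species", seed=7)
        b = kl.ripper_fit(matrix, "species", seed=7)
        assert json.dumps(model_to_dict(a), sort_keys=True) == json.dumps(
            model_to_dict(b), sort_keys=True
        )


def make_xor_matrix() -> kl.FeatureMatrix:
    """Two informative features; class = parity of their (low, high) cells.

    One cell is slightly over-represented so the first greedy split has
    positive gain (exact XOR has zero single-feature information).
    """
    cells = [(0, 0, 3), (0, 1, 3), (1, 0, 3), (1, 1, 4)]
    values = []
    labels = []
    rng = np.random.default_rng(0)
    for a, b, reps in cells:
        for _ in range(reps):
            row = np.zeros(64)
            row[0] = 0.2 + 0.6 * a + rng.uniform(0, 0.05)
            row[1] = 0.2 + 0.6 * b + rng.uniform(0, 0.05)
            values.append(row)
            labels.append("odd" if a != b else "even")
    values = np.array(values).T
    return kl.FeatureMatrix(
        k=3,
        feature_order=kl.all_kmers(3),
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        values=values,
        labels={"species": labels},
    )


class TestPart:
    def test_separable_equivalent_to_ripper(self):
        m = make_separable_matrix()
        rip = kl.ripper_fit(m, "species", seed=0)
        prt = kl.part_fit(m, "species", seed=0)
        assert len(prt.rules) == 1
        assert training_predictions(prt, m) == training_predictions(rip, m)

    def test_pure_class_default_only(self):
        m = make_separable_matrix()
        m.labels["species"] = ["same"] * m.n_samples
        with pytest.warns(UserWarning, match="single class"):
            model = kl.part_fit(m, "species")
        assert model.rules == [] and model.default_class == "same"

    def test_xor_needs_two_features(self):
        m = make_xor_matrix()
        assert not exhaustive_single_literal_zero_error(m, "species")
        model = kl.part_fit(
            m, "species", seed=0, discretizer="equal_frequency", n_intervals=2
        )
        assert len(model.rules) >= 2
        assert training_predictions(model, m) == m.labels["species"]

    def test_seeded_determinism(self, small_benchmark):
        _, _, _, matrix = small_benchmark
        a = kl.part_fit(matrix, "species", seed=5)
        b = kl.part_fit(matrix, "species", seed=5)
        assert json.dumps(model_to_dict(a), sort_keys=True) == json.dumps(
            model_to_dict(b), sort_keys=True
        )


class TestPlantedSignatureRecovery:
    def test_rules_reference_planted_kmers(self, small_benchmark):
        # five-species variant of the planted benchmark: every learned
        # literal should point at a planted signature word (or its
        # reverse complement), and rules should stay short
        spec = kl.SimSpec(
            seed=21,
            n_phyla=1,
            taxa_per_level={"class": 1, "order": 1, "genus": 1, "species": 5},
            genome_length=20_000,
        )
        records, signatures = kl.simulate_dataset(spec)
        matrix = kl.build_matrix(records, k=4, strand_mode="both")
        lidx = kl.lineage_index(records)
        model = kl.ripper_fit(matrix, "species", seed=21)
        assert model.rules, "expected rules on separable planted data"
        score = kl.recovery_score(model, signatures, lidx)
        assert score >= 0.8
        comp = kl.model_complexity(model)
        assert comp["mean_literals_per_rule"] <= 3
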