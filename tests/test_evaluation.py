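"""Accuracy, stratified folds, cross-validation bookkeeping, reports."""

import numpy as np
import pytest

import kmerlogic as kl
from kmerlogic.errors import UndefinedMetricError, ValidationError

from conftest import make_separable_matrix


class TestAccuracy:
    @pytest.mark.parametrize("c,t,expected", [(100, 100, 1.0), (0, 50, 0.0), (97, 100, 0.97)])
    def test_quotient(self, c, t, expected):
        assert kl.accuracy(c, t) == expected

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedMetricError):
            kl.accuracy(0, 0)

    def test_bounds_checked(self):
        with pytest.raises(ValidationError):
            kl.accuracy(5, 3)


class TestStratifiedFolds:
    def test_partition(self):
        labels = ["a"] * 13 + ["b"] * 17
        folds = kl.stratified_folds(labels, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx.tolist()) == list(range(30))

    def test_two_classes_of_ten_in_ten_folds(self):
        labels = ["a"] * 10 + ["b"] * 10
        folds = kl.stratified_folds(labels, 10, seed=1)
        for f in folds:
            assert len(f) == 2
            assert {labels[j] for j in f} == {"a", "b"}

    def test_class_sizes_differ_by_at_most_one(self):
        labels = ["a"] * 23 + ["b"] * 9
        folds = kl.stratified_folds(labels, 5, seed=2)
        for cls in ("a", "b"):
            sizes = [sum(1 for j in f if labels[j] == cls) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_matches_sklearn_stratification_arithmetic(self):
        # cross-check per-fold class counts against the reference splitter
        from sklearn.model_selection import StratifiedKFold

        labels = ["a"] * 14 + ["b"] * 21 + ["c"] * 10
        ours = kl.stratified_folds(labels, 5, seed=3)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        X = np.zeros((len(labels), 1))
        ref = [test for _, test in skf.split(X, labels)]
        count = lambda fold: sorted(
            (cls, sum(1 for j in fold if labels[j] == cls)) for cls in "abc"
        )
        assert sorted(map(count, ours)) == sorted(map(count, ref))


class TestStratifiedKFoldCV:
    def test_separable_data_perfect_accuracy(self):
        m = make_separable_matrix(n_per_class=10)
        res = kl.stratified_kfold_cv(m, "species", learner="ripper", n_folds=5, seed=0)
        assert res.accuracy == 1.0
        assert res.confusion.sum() == m.n_samples

    def test_pooled_accuracy_identity(self, small_benchmark):
        _, _, _, matrix = small_benchmark
        res = kl.stratified_kfold_cv(matrix, "phylum", n_folds=5, seed=0, keep_models=False)
        weighted = np.average(res.fold_accuracies, weights=res.fold_test_sizes)
        assert res.accuracy == pytest.approx(weighted, abs=1e-12)
        assert res.confusion.sum() == matrix.n_samples

    def test_reproducible_with_same_seed(self, small_benchmark):
        _, _, _, matrix = small_benchmark
        a = kl.stratified_kfold_cv(matrix, "genus", n_folds=5, seed=4, keep_models=False)
        b = kl.stratified_kfold_cv(matrix, "genus", n_folds=5, seed=4, keep_models=False)
        assert a.to_json() == b.to_json()

    def test_singletons_excluded_with_warning(self):
        m = make_separable_matrix(n_per_class=6)
        labels = list(m.labels["species"])
        labels[0] = "lonely"
        m.labels["species"] = labels
        with pytest.warns(UserWarning, match="singleton"):
            res = kl.stratified_kfold_cv(m, "species", n_folds=5, seed=0, keep_models=False)
        assert res.excluded_ids == [m.sample_ids[0]]
        assert res.confusion.sum() == m.n_samples - 1

    def test_folds_reduced_to_smallest_class(self):
        m = make_separable_matrix(n_per_class=4)
        with pytest.warns(UserWarning, match="reducing n_folds"):
            res = kl.stratified_kfold_cv(m, "species", n_folds=10, seed=0, keep_models=False)
        assert res.n_folds == 4

    def test_discretization_is_fold_local(self, monkeypatch, small_benchmark):
        # the harness must fit cut points on strictly fewer samples than the
        # full matrix (training part only)
        _, _, _, matrix = small_benchmark
        seen = []
        import kmerlogic.evaluation as ev

        original = ev.fit_cutpoints

        def spy(values, labels, **kw):
            seen.append(values.shape[1])
            return original(values, labels, **kw)

        monkeypatch.setattr(ev, "fit_cutpoints", spy)
        kl.stratified_kfold_cv(matrix, "phylum", n_folds=5, seed=0, keep_models=False)
        assert seen and all(n < matrix.n_samples for n in seen)


class TestPermutationNull:
    def test_chance_level_with_permuted_labels(self):
        spec = kl.SimSpec(
            seed=2,
            n_phyla=1,
            taxa_per_level={"class": 1, "order": 1, "genus": 1, "species": 5},
            genome_length=10_000,
        )
        matrix, _ = kl.benchmark_suite(spec)
        rng = np.random.default_rng(7)
        perm = rng.permutation(matrix.n_samples)
        matrix.labels["species"] = [matrix.labels["species"][j] for j in perm]
        res = kl.stratified_kfold_cv(
            matrix, "species", learner="ripper", n_folds=10, seed=2, keep_models=False
        )
        se = np.sqrt(0.2 * 0.8 / matrix.n_samples)
        assert abs(res.accuracy - 0.2) <= 3 * se


class TestPerRankReport:
    def test_shape_and_avg(self, small_benchmark):
        _, records, _, matrix = small_benchmark
        report = kl.per_rank_report(
            records, ranks=["species", "phylum"], learners=["ripper", "part"],
            matrix=matrix, n_folds=5, seed=0,
        )
        assert list(report.index) == ["species", "phylum"]
        assert list(report.columns) == ["ripper", "part", "avg", "std"]
        row = report.loc["phylum"]
        assert row["avg"] == pytest.approx((row["ripper"] + row["part"]) / 2, abs=0.01)

    def test_unusable_rank_marked_dash(self):
        m = make_separable_matrix(n_per_class=10)
        labels = [f"single_{j}" for j in range(m.n_samples)]  # all singletons
        m.labels["species"] = labels
        recs = None
        report = kl.per_rank_report(
            recs, ranks=["species"], learners=["ripper"], matrix=m, n_folds=5, seed=0
        )
        assert report.loc["species", "ripper"] == "-"
        assert report.loc["species", "avg"] == "-"
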