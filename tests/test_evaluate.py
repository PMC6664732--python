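"""Cross-validation, metrics and the method-comparison harness."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from fatiguenet import (
    ClassifierSpec,
    ConfigurationError,
    CvSpec,
    DegenerateInputError,
    compare_methods,
    cross_validate,
    paired_ttest,
    roc_auc,
)
from fatiguenet.evaluate import _binary_labels
from fatiguenet.pcanet import PCANetSpec


def _separable_features(rng, n_per_class=120, dims=10, distance=50.0):
    a = rng.standard_normal((n_per_class, dims))
    b = rng.standard_normal((n_per_class, dims)) + distance
    X = np.vstack([a, b])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestCrossValidate:
    def test_fold_partition_arithmetic(self, rng):
        X, y = _separable_features(rng)
        rep = cross_validate(X, y, CvSpec(folds=10, shuffle_seed=0))
        assert len(rep.fold_accuracies) == 10  # 240 samples, 24 per fold

    @pytest.mark.parametrize("family", ["svm", "knn"])
    def test_separable_clusters_near_perfect(self, rng, family):
        X, y = _separable_features(rng)
        rep = cross_validate(X, y, CvSpec(folds=5, shuffle_seed=1),
                             ClassifierSpec(family=family))
        assert rep.mean_accuracy >= 0.99
        assert rep.auc >= 0.99

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(DegenerateInputError):
            cross_validate(X, np.zeros(20, dtype=int), CvSpec(folds=2))

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.array([0, 1] * 20)
        r1 = cross_validate(X, y, CvSpec(folds=4, shuffle_seed=3))
        r2 = cross_validate(X, y, CvSpec(folds=4, shuffle_seed=3))
        assert r1.fold_accuracies == r2.fold_accuracies

    def test_no_leakage_canary(self, rng):
        """The extractor factory must be fitted on training folds only:
        a recording extractor never sees its fold's test indices, and
        corrupting held-out epochs does not change the fitted model."""
        n = 24
        epochs = [rng.standard_normal((4, 8)) for _ in range(n)]
        y = np.array([0, 1] * (n // 2))
        seen = []

        class RecordingExtractor:
            def fit(self, items):
                seen.append({id(e) for e in items})
                return self

            def transform(self, items):
                return np.stack([e.mean(axis=1) for e in items])

            def fit_transform(self, items):
                return self.fit(items).transform(items)

        cross_validate(epochs, y, CvSpec(folds=4, shuffle_seed=0),
                       extractor_factory=RecordingExtractor)
        all_ids = {id(e) for e in epochs}
        assert len(seen) == 4
        for train_ids in seen:
            assert len(all_ids - train_ids) == 6  # each fold holds out 6

        from fatiguenet import ModifiedPCANetExtractor, Epoch, ReductionSpec

        train = [Epoch(data=rng.standard_normal((8, 40)), rate=200.0)
                 for _ in range(6)]
        held_out = [Epoch(data=rng.standard_normal((8, 40)), rate=200.0)
                    for _ in range(2)]
        spec = PCANetSpec(k1=3, k2=3, L1=2, L2=2, block_h=2, block_w=2)
        red = ReductionSpec(fixed_r=5)
        m1 = ModifiedPCANetExtractor(red, spec).fit(train).model
        for e in held_out:
            e.data *= 1e6  # corrupt what was never shown to fit
        m2 = ModifiedPCANetExtractor(red, spec).fit(train).model
        for a, b in zip(m1.bank1.filters, m2.bank1.filters):
            np.testing.assert_array_equal(a, b)


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0

    def test_hand_counted_pairs(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_ties_count_half(self):
        assert roc_auc([1.0, 1.0], [0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_matches_mann_whitney_normalization(self, rng):
        """Property over 100 random instances: rank AUC equals both the
        normalized Mann-Whitney U and sklearn's trapezoid ROC area."""
        for _ in range(100):
            n = rng.integers(4, 40)
            scores = rng.normal(size=n)
            scores[rng.random(n) < 0.3] = rng.choice(scores)  # inject ties
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            got = roc_auc(scores, y)
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0],
                                   alternative="two-sided").statistic
            assert got == pytest.approx(
                u / ((y == 1).sum() * (y == 0).sum()), abs=1e-12
            )
            assert got == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


class TestPairedTtest:
    def test_identical_vectors_degenerate(self):
        res = paired_ttest([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference(self):
        res = paired_ttest([1.0, 1.0], [0.5, 0.5])
        assert res.t == np.inf and res.p == 0.0

    def test_textbook_formula(self):
        """Differences [1, 2, 3]: t = 2/(1/sqrt(3)), p from the t CDF."""
        res = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        t_expected = 2.0 / (1.0 / np.sqrt(3.0))
        p_expected = 2.0 * stats.t.sf(t_expected, df=2)
        assert res.t == pytest.approx(t_expected, abs=1e-10)
        assert res.p == pytest.approx(p_expected, abs=1e-10)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1 = paired_ttest(a, b)
        r2 = paired_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_matches_reference_on_random_vectors(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=10), rng.normal(size=10)
            res = paired_ttest(a, b)
            t_ref, p_ref = stats.ttest_rel(a, b)
            assert res.t == pytest.approx(float(t_ref), abs=1e-10)
            assert res.p == pytest.approx(float(p_ref), abs=1e-10)


class TestCompareMethods:
    def test_report_and_comparison_combinatorics(self, rng):
        from conftest import make_tiny_epochs

        dataset = {
            f"S{i}": make_tiny_epochs(rng, n_per_class=4)
            for i in range(2)
        }
        spec = PCANetSpec(k1=3, k2=3, L1=2, L2=2, block_h=4, block_w=16)
        reports, comps = compare_methods(
            dataset,
            methods=("wpd", "psd", "modified_pcanet", "pcanet_raw"),
            cv=CvSpec(folds=2, shuffle_seed=0),
            pcanet_spec=spec,
        )
        assert len(reports) == 8  # 2 subjects x 4 methods
        assert len(comps) == 6  # all unordered pairs
        assert all(r.feature_time is not None for r in reports)
        assert all(0 <= r.mean_accuracy <= 1 for r in reports)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            compare_methods({"a": ([], []), "b": ([], [])},
                            methods=("nope",))

    def test_binary_label_mapping(self):
        y = _binary_labels(["awake", "fatigue", "awake"])
        np.testing.assert_array_equal(y, [0, 1, 0])
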