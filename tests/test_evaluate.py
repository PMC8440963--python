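import numpy as np
import pytest
from scipy import stats as sstats

from eegrefine.evaluate import (
    cohen_kappa,
    confusion_matrix,
    crossvalidate,
    make_folds,
    paired_ttest,
)
from eegrefine.network import default_spec
from eegrefine.synth import SimConfig, simulate


class TestMakeFolds:
    def test_576_trials_split_58x6_57x4(self):
        eset = simulate(SimConfig(n_trials_per_class=144, duration=0.1, seed=0))
        assert len(eset) == 576
        folds = make_folds(eset, 10, seed=1)
        sizes = sorted(np.bincount(list(folds.fold_of_trial.values()), minlength=10))
        assert sizes == [57] * 4 + [58] * 6

    def test_ten_trials_ten_singleton_folds(self, small_set):
        folds = make_folds(small_set.subset(range(10)), 10, seed=0)
        sizes = np.bincount(list(folds.fold_of_trial.values()), minlength=10)
        assert (sizes == 1).all()

    def test_deterministic_given_seed(self, small_set):
        a = make_folds(small_set, 4, seed=5).fold_of_trial
        b = make_folds(small_set, 4, seed=5).fold_of_trial
        assert a == b

    def test_partition_property(self, small_set):
        folds = make_folds(small_set, 5, seed=2)
        indices = folds.fold_indices(small_set)
        flat = np.concatenate(indices)
        assert sorted(flat) == list(range(len(small_set)))

    def test_too_few_trials(self, small_set):
        with pytest.raises(ValueError):
            make_folds(small_set.subset(range(5)), 10, seed=0)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([10, 20, 30, 40])) == 1.0

    def test_chance_agreement_balanced_uniform(self):
        assert cohen_kappa(np.full((4, 4), 25)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        cm = np.array([[40, 10, 0, 0], [10, 40, 0, 0], [0, 0, 50, 0], [0, 0, 0, 50]])
        assert cohen_kappa(cm) == pytest.approx((0.9 - 0.25) / 0.75, abs=1e-9)

    def test_balanced_identity_and_sklearn_cross_check(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(20):
            y_true = np.repeat(np.arange(4), 25)
            y_pred = rng.integers(0, 4, size=100)
            cm = confusion_matrix(y_true, y_pred)
            ours = cohen_kappa(cm)
            assert ours == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((4, 4)))


class TestPairedTTest:
    def test_identical_scores(self):
        r = paired_ttest([1, 2, 3], [1, 2, 3])
        assert (r.t_statistic, r.p_value) == (0.0, 1.0)

    def test_constant_nonzero_difference_flagged(self):
        r = paired_ttest([2, 2, 2, 2], [1, 1, 1, 1])
        assert r.degenerate
        assert r.p_value < 1e-12

    def test_closed_form_toy_vectors(self):
        r = paired_ttest([1, 2, 3], [0, 0, 0])
        assert r.t_statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert r.p_value == pytest.approx(0.0742, abs=5e-4)
        sp = sstats.ttest_rel([1, 2, 3], [0, 0, 0])
        assert r.t_statistic == pytest.approx(sp.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    def test_sign_antisymmetry(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        fwd = paired_ttest(a, b)
        rev = paired_ttest(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)


@pytest.fixture(scope="module")
def easy_set():
    # four spectrally distinct classes, low noise: trivially decodable
    bands = {0: (8.0, 12.0, ("C3",)), 1: (13.0, 12.0, ("C4",)),
             2: (21.0, 12.0, ("Cz",)), 3: (27.0, 12.0, ("Fz",))}
    return simulate(SimConfig(n_trials_per_class=20, duration=1.0,
                              class_bands=bands, noise_scale=0.3,
                              burst_ms=(700.0, 900.0), burst_onset_s=(0.0, 0.1),
                              interference=[], seed=11))


class TestCrossvalidate:
    def test_separable_data_scores_high(self, easy_set):
        spec = default_spec((6, 7, 250), seed=1, epochs=15)
        report = crossvalidate(easy_set, spec, make_folds(easy_set, 3, seed=1))
        assert report.mean_accuracy > 0.9
        assert report.mean_accuracy == pytest.approx(
            np.mean([fr.accuracy for fr in report.fold_results]))

    def test_shuffled_labels_score_at_chance(self, easy_set):
        rng = np.random.default_rng(0)
        labels = rng.permutation([e.label for e in easy_set])
        import dataclasses
        shuffled = dataclasses.replace(
            easy_set,
            epochs=[dataclasses.replace(e, label=int(l))
                    for e, l in zip(easy_set.epochs, labels)],
        )
        spec = default_spec((6, 7, 250), seed=1, epochs=8)
        report = crossvalidate(shuffled, spec, make_folds(shuffled, 3, seed=1))
        assert abs(report.mean_accuracy - 0.25) < 0.2
        assert abs(report.mean_kappa) < 0.3

    def test_confusion_rows_match_class_counts(self, easy_set):
        spec = default_spec((6, 7, 250), seed=2, epochs=2)
        report = crossvalidate(easy_set, spec, make_folds(easy_set, 4, seed=2))
        pooled = np.sum([fr.confusion for fr in report.fold_results], axis=0)
        np.testing.assert_array_equal(pooled.sum(axis=1),
                                      np.bincount(easy_set.labels, minlength=4))
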