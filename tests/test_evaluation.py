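import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathobrain import evaluation as ev
from pathobrain import ppca as ppca_mod
from pathobrain.config import PipelineConfig

P, N = "pathological", "normal"


class TestConfusion:
    def test_all_correct(self):
        cm = ev.confusion([P, P, P, N, N], [P, P, P, N, N])
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (3, 2, 0, 0)

    def test_all_pathological_missed(self):
        cm = ev.confusion([P, P, P, N], [N, N, N, N])
        assert cm.FN == 3 and cm.TP == 0

    def test_mixed_enumeration(self):
        cm = ev.confusion([P, P, N], [P, N, P])
        assert (cm.TP, cm.FN, cm.FP, cm.TN) == (1, 1, 1, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion([P, N], [P])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionMatrix(TP=-1, FN=0, FP=0, TN=2)


class TestMetrics:
    def test_reference_comparison_row(self):
        # 450-case benchmark row: 388 successes, reconstructed counts
        cm = ev.ConfusionMatrix(TP=374, FN=51, FP=11, TN=14)
        assert ev.metrics(cm).percentages() == (88.00, 56.00, 97.14, 86.22)

    def test_perfect_classifier_scores_hundred(self):
        cm = ev.ConfusionMatrix(TP=7, FN=0, FP=0, TN=5)
        assert ev.metrics(cm).percentages() == (100.0, 100.0, 100.0, 100.0)

    def test_undefined_sensitivity_flagged(self):
        rep = ev.metrics(ev.ConfusionMatrix(TP=0, FN=0, FP=2, TN=3))
        assert math.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined

    @pytest.mark.parametrize(
        "successes, expected_accuracy", [(388, 86.22), (413, 91.78), (450, 100.0)]
    )
    def test_accuracy_equals_successes_over_total(self, successes, expected_accuracy):
        cm = ev.ConfusionMatrix(TP=successes - 10, FN=450 - successes, FP=0, TN=10)
        assert ev.metrics(cm).percentages()[3] == expected_accuracy

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from([P, N]), min_size=2, max_size=50).filter(
        lambda y: len(set(y)) == 2))
    def test_self_prediction_is_perfect(self, y):
        assert ev.metrics(ev.confusion(y, y)).percentages() == (100.0, 100.0, 100.0, 100.0)


class TestStratifiedKFold:
    def test_255_samples_5_folds_gives_51_validation(self):
        labels = np.array([P] * 220 + [N] * 35)
        plan = ev.stratified_kfold(labels, 5, seed=0)
        for f in range(5):
            assert len(plan.validation_indices(0, f)) == 51

    def test_66_samples_6_folds_gives_11_validation_55_training(self):
        labels = np.array([P] * 48 + [N] * 18)
        plan = ev.stratified_kfold(labels, 6, seed=0)
        for f in range(6):
            assert len(plan.validation_indices(0, f)) == 11
            assert len(plan.training_indices(0, f)) == 55

    def test_perfect_stratification_small(self):
        labels = np.array([P] * 5 + [N] * 5)
        plan = ev.stratified_kfold(labels, 5, seed=3)
        for f in range(5):
            va = labels[plan.validation_indices(0, f)]
            assert list(va).count(P) == 1 and list(va).count(N) == 1

    def test_fold_and_class_balance_invariants(self):
        rng = np.random.default_rng(1)
        labels = np.array([P] * 37 + [N] * 16)
        plan = ev.stratified_kfold(labels, 5, seed=7)
        sizes = [len(plan.validation_indices(0, f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        for cls in (P, N):
            per_fold = [
                np.sum(labels[plan.validation_indices(0, f)] == cls) for f in range(5)
            ]
            assert max(per_fold) - min(per_fold) <= 1
        assert sorted(np.concatenate(
            [plan.validation_indices(0, f) for f in range(5)]
        ).tolist()) == list(range(53))

    def test_reproducible_from_seed(self):
        labels = np.array([P] * 20 + [N] * 10)
        a = ev.stratified_kfold(labels, 5, seed=9)
        b = ev.stratified_kfold(labels, 5, seed=9)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError):
            ev.stratified_kfold([P, P, P, N, N], 3, seed=0)


@pytest.fixture(scope="module")
def latent_data():
    # well-separated latent scores: the cascade should be near-perfect
    rng = np.random.default_rng(0)
    n = 40
    X = rng.standard_normal((n, 20))
    X[: n // 2] += 3.0
    y = np.array([P] * (n // 2) + [N] * (n // 2))
    return X, y


class TestRunCV:
    def _config(self):
        # subspaces of 3 of the 4 latent dims: every member keeps enough of
        # the (rank-1) class separation to vote correctly
        return PipelineConfig(ppca_k=4, n_members=10, subspace_dim=3, seed=0)

    def test_report_shape_and_accuracy(self, latent_data):
        X, y = latent_data
        plan = ev.make_cv_plan(y, 5, 5, seed=0)
        res = ev.run_cv(X, y, self._config(), plan)
        assert len(res.rows) == 25
        assert res.mean_accuracy > 95.0
        assert len(res.per_repeat_accuracy) == 5

    def test_single_repeat_consistency(self, latent_data):
        X, y = latent_data
        single = ev.stratified_kfold(y, 5, seed=0)
        multi = ev.make_cv_plan(y, 5, 1, seed=0)
        assert np.array_equal(single.fold_assignments, multi.fold_assignments)
        a = ev.run_cv(X, y, self._config(), single)
        b = ev.run_cv(X, y, self._config(), multi)
        assert a.rows.equals(b.rows)

    def test_models_fitted_per_training_fold_only(self, latent_data, monkeypatch):
        X, y = latent_data
        plan = ev.make_cv_plan(y, 5, 2, seed=0)
        fitted_sizes = []
        original = ppca_mod.fit_ppca

        def spy(Xf, *args, **kwargs):
            fitted_sizes.append(len(Xf))
            return original(Xf, *args, **kwargs)

        monkeypatch.setattr(ev.ppca_mod, "fit_ppca", spy)
        ev.run_cv(X, y, self._config(), plan)
        assert len(fitted_sizes) == 10  # one fit per repeat x fold
        assert all(size == 32 for size in fitted_sizes)  # training portion only

    def test_plan_sample_mismatch_rejected(self, latent_data):
        X, y = latent_data
        plan = ev.make_cv_plan(y[:-2], 5, 1, seed=0)
        with pytest.raises(ValueError):
            ev.run_cv(X, y, self._config(), plan)
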