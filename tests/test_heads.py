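"""Heads, fold plans, cross-validation, ensembling and metrics."""

import numpy as np
import pandas as pd
import pytest

from histotx.heads import (
    FoldError,
    HeadConfig,
    MetricError,
    auc,
    balanced_accuracy,
    cross_validate,
    cross_validate_head,
    ensemble_inference,
    f1_macro,
    stratified_patient_folds,
    train_head,
)


class TestMetrics:
    def test_auc_pairwise_concordance_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_majority_predictor_balanced_accuracy_half(self):
        y = np.r_[np.zeros(90), np.ones(10)]
        assert balanced_accuracy(y, np.zeros(100)) == pytest.approx(0.5)

    def test_perfect_predictions_all_ones(self):
        y = np.array([0, 1, 0, 1])
        assert auc(y, y.astype(float)) == 1.0
        assert balanced_accuracy(y, y) == 1.0
        assert f1_macro(y, y) == 1.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.normal(0, 1, 50)
        assert auc(y, s) == pytest.approx(auc(y, np.exp(3 * s)))

    def test_single_class_errors(self):
        with pytest.raises(MetricError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestFoldPlan:
    def test_balanced_ten_patients(self):
        labels = pd.Series([1] * 5 + [0] * 5, index=[f"P{i}" for i in range(10)])
        plan = stratified_patient_folds(labels, k=5, seed=0)
        for fold in range(5):
            members = [p for p, f in plan.assignment.items() if f == fold]
            assert len(members) == 2
            assert sum(labels[m] for m in members) == 1

    def test_discovery_sized_cohort_fold_positives(self):
        # 246 patients, 90 positive, 5 folds -> positives per fold in {18, 19}
        labels = pd.Series(
            [1] * 90 + [0] * 156, index=[f"P{i}" for i in range(246)]
        )
        plan = stratified_patient_folds(labels, k=5, seed=3)
        for fold in range(5):
            pos = sum(
                labels[p] for p, f in plan.assignment.items() if f == fold
            )
            assert pos in (18, 19)

    def test_multislide_patient_stays_in_one_fold(self):
        labels = pd.Series([1] * 5 + [0] * 5, index=[f"P{i}" for i in range(10)])
        plan = stratified_patient_folds(labels, k=5, seed=0)
        slides = [f"P{i}" for i in range(10) for _ in range(6)]
        folds = plan.fold_of(slides)
        for pid in labels.index:
            got = {f for s, f in zip(slides, folds) if s == pid}
            assert len(got) == 1

    def test_too_few_positives_errors(self):
        labels = pd.Series([1] * 3 + [0] * 20, index=[f"P{i}" for i in range(23)])
        with pytest.raises(FoldError):
            stratified_patient_folds(labels, k=5, seed=0)


class TestTrainHead:
    def test_default_config_matches_published_settings(self):
        cfg = HeadConfig()
        assert cfg.C == 7.0
        assert cfg.max_iterations == 10_000
        assert cfg.class_weighting == "balanced"

    def test_separable_data_training_auc_one(self, rng):
        X = np.r_[rng.normal(-3, 0.1, (20, 2)), rng.normal(3, 0.1, (20, 2))]
        y = np.repeat([0, 1], 20)
        clf = train_head(X, y)
        assert auc(y, clf.predict_proba(X)[:, 1]) == 1.0

    def test_balanced_weighting_shifts_intercept_towards_minority(self, rng):
        """On 90/10 data the balanced fit moves the intercept by roughly the
        log prior odds relative to the unweighted fit."""
        X = np.r_[rng.normal(-1, 1, (900, 1)), rng.normal(1, 1, (100, 1))]
        y = np.r_[np.zeros(900), np.ones(100)]
        bal = train_head(X, y, HeadConfig(class_weighting="balanced"))
        unw = train_head(X, y, HeadConfig(class_weighting="none"))
        shift = bal.intercept_[0] - unw.intercept_[0]
        assert shift > 0  # towards the minority positive class
        assert shift == pytest.approx(np.log(900 / 100), rel=0.35)

    def test_degenerate_labels_error(self, rng):
        with pytest.raises(FoldError):
            train_head(rng.normal(0, 1, (10, 2)), np.ones(10))


class TestCrossValidate:
    def _setup(self, rng, n_pat=30, informative=True):
        half = n_pat // 2
        labels = pd.Series(
            rng.permutation(np.r_[np.ones(half), np.zeros(n_pat - half)]).astype(int),
            index=[f"P{i}" for i in range(n_pat)],
        )
        X, y, pids = [], [], []
        for pid, lab in labels.items():
            for _ in range(2):  # two slides per patient
                centre = (2 * lab - 1) if informative else 0.0
                X.append(rng.normal(centre, 1.0, 4))
                y.append(lab)
                pids.append(pid)
        return labels, np.array(X), np.array(y), np.array(pids)

    def test_informative_embeddings_high_metrics(self, rng):
        labels, X, y, pids = self._setup(rng)
        X[:, 0] = (2 * y - 1) * 5  # make it separable
        plan = stratified_patient_folds(labels, k=5, seed=0)
        report, oof, models = cross_validate_head(X, y, pids, plan)
        assert report.auc == 1.0
        assert report.patient_auc == 1.0
        assert len(models) == 5
        assert not np.isnan(oof).any()

    def test_label_independent_embeddings_null_auc(self):
        rng = np.random.default_rng(0)
        aucs = []
        for rep in range(5):
            labels, X, y, pids = self._setup(
                np.random.default_rng(rep), n_pat=40, informative=False
            )
            plan = stratified_patient_folds(labels, k=5, seed=rep)
            report, oof, _ = cross_validate_head(X, y, pids, plan)
            aucs.append(auc(y, oof))
        assert 0.4 < np.mean(aucs) < 0.6

    def test_patient_never_in_train_and_test(self, rng):
        labels, X, y, pids = self._setup(rng)
        plan = stratified_patient_folds(labels, k=5, seed=1)
        folds = plan.fold_of(pids)
        for fold in range(5):
            assert not set(pids[folds == fold]) & set(pids[folds != fold])


class TestEnsembleInference:
    def test_identical_models_equal_single_model(self, rng):
        X = np.r_[rng.normal(-1, 1, (20, 3)), rng.normal(1, 1, (20, 3))]
        y = np.repeat([0, 1], 20)
        m = train_head(X, y)
        ens = ensemble_inference([m] * 5, X)
        assert np.allclose(ens, m.predict_proba(X)[:, 1])

    def test_probability_averaging_arithmetic(self):
        class Fixed:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([1 - np.full(len(X), self.p),
                                        np.full(len(X), self.p)])

        models = [Fixed(p) for p in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert ensemble_inference(models, np.zeros((3, 2)))[0] == pytest.approx(0.6)

    def test_dimension_mismatch_errors(self, rng):
        X = np.r_[rng.normal(-1, 1, (10, 3)), rng.normal(1, 1, (10, 3))]
        y = np.repeat([0, 1], 10)
        m = train_head(X, y)
        with pytest.raises(ValueError):
            ensemble_inference([m], rng.normal(0, 1, (5, 7)))

    def test_ensemble_auc_not_below_worst_fold_model(self):
        """Fold-averaged probabilities score at least as well as the worst
        individual fold model on held-out data (checked over seeds)."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = np.r_[rng.normal(-0.8, 1, (60, 4)), rng.normal(0.8, 1, (60, 4))]
            y = np.repeat([0, 1], 60)
            Xe = np.r_[rng.normal(-0.8, 1, (40, 4)), rng.normal(0.8, 1, (40, 4))]
            ye = np.repeat([0, 1], 40)
            models = []
            for f in range(5):
                sel = np.arange(len(y)) % 5 != f
                models.append(train_head(X[sel], y[sel]))
            ens_auc = auc(ye, ensemble_inference(models, Xe))
            worst = min(auc(ye, m.predict_proba(Xe)[:, 1]) for m in models)
            wins += ens_auc >= worst - 1e-9
        assert wins >= 9
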