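import numpy as np
import pytest

from modfuse import (
    CLASS_LEVELS,
    ModalityConfig,
    SyntheticSpec,
    TaskSpec,
    apply_feature_weighting,
    build_config_matrix,
    compute_metrics,
    generate_multimodal,
    predict_multiclass,
    run_cv,
    train_svm,
)
from modfuse.datasets import MODALITY_ORDER
from modfuse.evaluation import _FoldPipeline, make_folds
from oracles import svm_primal_objective, svm_qp_oracle


class TestFeatureWeighting:
    def test_elementwise_product(self):
        out = apply_feature_weighting(np.array([[1.0, 2.0, 3.0]]), np.array([0.0, 0.5, 2.0]))
        np.testing.assert_allclose(out, [[0.0, 1.0, 6.0]])

    def test_identity_weights(self, rng):
        X = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(apply_feature_weighting(X, np.ones(4)), X)

    def test_zero_weight_columns_equivalent_to_dropping(self, rng):
        X = rng.normal(size=(20, 6))
        y = np.sign(X[:, 0] + 0.1 * rng.normal(size=20)).astype(int)
        w = np.array([1.0, 0.8, 0.0, 0.0, 1.2, 0.0])
        kept = w > 0
        svc_all = train_svm(apply_feature_weighting(X, w), y, C=1.0)
        svc_drop = train_svm(apply_feature_weighting(X[:, kept], w[kept]), y, C=1.0)
        Xt = rng.normal(size=(5, 6))
        np.testing.assert_allclose(
            svc_all.decision_function(apply_feature_weighting(Xt, w)),
            svc_drop.decision_function(apply_feature_weighting(Xt[:, kept], w[kept])),
            atol=1e-8,
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_feature_weighting(np.ones((2, 3)), np.ones(4))


class TestTrainSVM:
    def test_separable_two_point_problem(self):
        X = np.array([[-1.0, -1.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        svc = train_svm(X, y, C=1e6)
        assert svc.predict(X).tolist() == [-1, 1]
        # decision boundary passes through the origin by symmetry
        assert svc.decision_function([[0.0, 0.0]])[0] == pytest.approx(0.0, abs=1e-9)

    def test_label_flip_negates_decision_values(self, rng):
        X = rng.normal(size=(16, 3))
        y = np.sign(X[:, 0] + 0.2 * rng.normal(size=16)).astype(int)
        a = train_svm(X, y, C=1.0).decision_function(X)
        b = train_svm(X, -y, C=1.0).decision_function(X)
        np.testing.assert_allclose(a, -b, atol=1e-4)

    def test_objective_matches_qp_oracle(self):
        X = np.array(
            [[0.2, 1.1], [1.0, 0.4], [1.5, -0.8], [-0.4, -1.2], [-1.2, 0.3], [-1.8, -0.6]]
        )
        y = np.array([1, 1, 1, -1, -1, -1])
        C = 1.0
        svc = train_svm(X, y, C=C)
        w = svc.coef_.ravel()
        obj = svm_primal_objective(w, float(svc.intercept_[0]), X, y, C)
        assert obj == pytest.approx(svm_qp_oracle(X, y, C), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.ones((4, 2)), np.ones(4), C=1.0)


class TestPredictMulticlass:
    class _Fixed:
        def __init__(self, v):
            self.v = np.asarray(v, float)

        def decision_function(self, X):
            return np.repeat(self.v, len(X))

    def test_argmax_selection(self):
        models = {"HC": self._Fixed([0.2]), "MCI": self._Fixed([-0.1]), "AD": self._Fixed([0.5])}
        assert predict_multiclass(models, np.zeros((1, 2)))[0] == CLASS_LEVELS.index("AD")

    def test_tie_broken_by_class_order(self):
        models = {"HC": self._Fixed([0.3]), "MCI": self._Fixed([0.3]), "AD": self._Fixed([0.1])}
        assert predict_multiclass(models, np.zeros((1, 2)))[0] == CLASS_LEVELS.index("HC")

    def test_agrees_with_bruteforce_argmax(self, rng):
        scores = rng.normal(size=(100, 3))

        class _Col:
            def __init__(self, c):
                self.c = c

            def decision_function(self, X):
                return scores[: len(X), self.c]

        models = {lvl: _Col(c) for c, lvl in enumerate(CLASS_LEVELS)}
        pred = predict_multiclass(models, np.zeros((100, 2)))
        np.testing.assert_array_equal(pred, np.argmax(scores, axis=1))

    def test_missing_scorer_rejected(self):
        with pytest.raises(ValueError):
            predict_multiclass({"HC": self._Fixed([0.0])}, np.zeros((1, 2)))


class TestMetrics:
    def test_hand_counts(self):
        y_true = np.array([1] * 5 + [0] * 5)
        y_pred = np.array([1, 1, 1, 0, 0, 0, 1, 0, 0, 0])
        acc, sens, spec = compute_metrics(y_true, y_pred, positive_class=1)
        assert (acc, sens, spec) == (70.0, 60.0, 80.0)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0])
        assert compute_metrics(y, y, positive_class=1) == (100.0, 100.0, 100.0)

    def test_random_confusion_matches_tally_oracle(self, rng):
        y_true = rng.integers(0, 2, size=50)
        y_pred = rng.integers(0, 2, size=50)
        acc, sens, spec = compute_metrics(y_true, y_pred, positive_class=1)
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        assert acc == pytest.approx(100 * (tp + tn) / 50)
        assert sens == pytest.approx(100 * tp / (tp + fn))
        assert spec == pytest.approx(100 * tn / (tn + fp))

    def test_undefined_rates_flagged_not_zero(self):
        with pytest.warns(UserWarning):
            _, sens, _ = compute_metrics(np.zeros(4), np.zeros(4), positive_class=1)
        assert np.isnan(sens)
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]))


class TestConfigMatrix:
    def test_default_dimension_contracts(self):
        ds = generate_multimodal(SyntheticSpec(n_per_class=(4, 4, 4)))
        X, names = build_config_matrix(ds, ModalityConfig("MRI+PET+CSF"))
        assert X.shape[1] == len(names) == 189  # 93 + 93 + 3
        X, names = build_config_matrix(ds, ModalityConfig("MRI+PET+CSF+SNP"))
        assert X.shape[1] == len(names) == 378
        X, names = build_config_matrix(ds, ModalityConfig("CSF"))
        assert X.shape[1] == 3 and all(n.startswith("CSF") for n in names)

    def test_canonical_order_enforced(self):
        with pytest.raises(ValueError):
            ModalityConfig("SNP+MRI")
        with pytest.raises(ValueError):
            ModalityConfig("MRI+EEG")

    def test_missing_modality_rejected(self, small_dataset):
        ds = small_dataset
        import copy

        ds2 = copy.copy(ds)
        ds2.blocks = {m: v for m, v in ds.blocks.items() if m != "PET"}
        with pytest.raises(ValueError):
            build_config_matrix(ds2, ModalityConfig("MRI+PET+CSF"))


class TestCrossValidation:
    def test_fold_partition_invariants(self, small_dataset):
        y = small_dataset.labels
        folds = make_folds(y, 5, seed=3)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(y.size))  # each subject exactly once
        global_frac = np.bincount(y) / y.size
        for _, te in folds:
            frac = np.bincount(y[te], minlength=3)
            expect = global_frac * te.size
            assert np.all(np.abs(frac - expect) <= 1.0 + 1e-9)

    def test_determinism_same_seed_identical_result(self, small_dataset):
        kw = dict(
            config=ModalityConfig("MRI+CSF"),
            task=TaskSpec("binary", "AD", "HC"),
            method="baseline",
            grid={"C": [0.1, 1.0]},
            seed=7,
            n_folds=5,
        )
        a = run_cv(small_dataset, **kw)
        b = run_cv(small_dataset, **kw)
        np.testing.assert_array_equal(a.fold_accuracy, b.fold_accuracy)
        assert a.chosen_params == b.chosen_params
        for wa, wb in zip(a.fold_weights, b.fold_weights):
            np.testing.assert_array_equal(wa, wb)

    def test_no_leakage_test_rows_never_touch_fitting(self, small_dataset):
        """Replacing the held-out rows with garbage changes nothing fitted."""
        import copy

        ds = small_dataset
        tr_idx = np.arange(0, 30)
        te_idx = np.arange(30, ds.n_subjects)
        pipe = _FoldPipeline(ds, ModalityConfig("MRI+SNP"), tr_idx, snp_top_k=10)
        ds2 = copy.copy(ds)
        ds2.blocks = {m: v.copy() for m, v in ds.blocks.items()}
        for m in ds2.blocks:
            ds2.blocks[m][te_idx] = 0.0 if m != "SNP" else 2.0
        pipe2 = _FoldPipeline(ds2, ModalityConfig("MRI+SNP"), tr_idx, snp_top_k=10)
        np.testing.assert_array_equal(pipe.snp_keep, pipe2.snp_keep)
        for m in pipe.normalizers:
            for a, b in zip(pipe.normalizers[m].stats, pipe2.normalizers[m].stats):
                np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(
            pipe.transform(ds, tr_idx), pipe2.transform(ds2, tr_idx)
        )

    def test_pure_noise_accuracy_within_binomial_null_band(self, noise_dataset):
        res = run_cv(
            noise_dataset,
            ModalityConfig("MRI"),
            TaskSpec("binary", "AD", "HC"),
            "baseline",
            grid={"C": [1.0]},
            seed=1,
            n_folds=5,
        )
        n = 30  # subjects in the contrast
        p = 0.5  # balanced classes: majority rate
        half_width = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(res.mean_accuracy / 100.0 - p) < half_width + 0.05

    def test_strong_signal_high_accuracy_all_methods(self):
        spec = SyntheticSpec(
            n_per_class=(15, 15, 15),
            modality_dims={"MRI": 12, "PET": 3, "CSF": 3, "SNP": 10},
            informative_counts={"MRI": 6, "PET": 0, "CSF": 0, "SNP": 0},
            effect_sizes={**{m: 0.0 for m in MODALITY_ORDER}, "MRI": 3.0},
            seed=21,
        )
        ds = generate_multimodal(spec)
        grids = {
            "baseline": {"C": [1.0]},
            "MKL": {"C": [1.0]},
            "HGM-FS": {"C": [1.0], "lam1": [1e-2], "lam2": [0.0], "lam3": [0.0]},
            "SMML": {"C": [1.0], "gam1": [1e-2], "gam2": [1e-2]},
        }
        for method, grid in grids.items():
            res = run_cv(
                ds, ModalityConfig("MRI"), TaskSpec("binary", "AD", "HC"),
                method, grid=grid, seed=2, n_folds=5,
            )
            assert res.mean_accuracy >= 95.0, method

    def test_mean_weights_have_full_config_dimension(self, small_dataset):
        res = run_cv(
            small_dataset,
            ModalityConfig("MRI+SNP"),
            TaskSpec("binary", "AD", "HC"),
            "HGM-FS",
            grid={"C": [1.0], "lam1": [1e-2], "lam2": [0.0], "lam3": [0.0]},
            seed=5,
            n_folds=5,
            snp_top_k=10,  # pre-screen active: weights still full-length
        )
        d_full = small_dataset.blocks["MRI"].shape[1] + small_dataset.blocks["SNP"].shape[1]
        assert res.mean_weights.shape == (d_full,)
        assert len(res.feature_names) == d_full

    def test_too_small_class_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            run_cv(
                small_dataset,
                ModalityConfig("CSF"),
                TaskSpec("binary", "AD", "HC"),
                "baseline",
                grid={"C": [1.0]},
                n_folds=20,
            )

    def test_nested_mode_runs_and_reports_per_fold_choices(self, small_dataset):
        res = run_cv(
            small_dataset,
            ModalityConfig("CSF"),
            TaskSpec("binary", "AD", "HC"),
            "baseline",
            grid={"C": [0.1, 10.0]},
            seed=3,
            n_folds=5,
            nested=True,
        )
        assert len(res.chosen_params["per_fold"]) == 5
        assert res.fold_accuracy.shape == (5,)
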