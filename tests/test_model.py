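"""Classifier contracts: shapes, folds, gradients, training, stacking."""

import numpy as np
import pandas as pd
import pytest

from sersdx import (CohortPlan, NoiseModel, binary_signatures,
                    simulate_cohort)
from sersdx.model import (CrossValResult, LeakageError, ModelConfig,
                          build_cnn, build_refiner_mlp, cross_validate,
                          make_folds, train_cnn, train_refiner)
from sersdx.nn import (Adam, Dense, Network, softmax,
                       softmax_cross_entropy)
from sersdx.preprocess import preprocess_pipeline

from conftest import SEED


class TestBuildCnn:
    def test_shape_report_full_grid(self):
        cfg = ModelConfig(n_classes=2)
        _, report = build_cnn(cfg, 1401)
        text = " ".join(report)
        assert "(1399, 64)" in text    # valid conv: 1401 - 3 + 1
        assert "(699, 64)" in text     # floor(1399 / 2)
        assert "(44736,)" in text      # 64 * 699

    def test_shape_report_minimal_input(self):
        cfg = ModelConfig(n_classes=2)
        _, report = build_cnn(cfg, 4)
        text = " ".join(report)
        assert "(2, 64)" in text
        assert "(1, 64)" in text
        assert "(64,)" in text

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_cnn(ModelConfig(n_classes=2), 3)

    def test_softmax_uniform_on_zero_logits(self):
        p = softmax(np.zeros((2, 11)))
        np.testing.assert_allclose(p, 1.0 / 11)

    def test_forward_probabilities_normalized(self):
        net, _ = build_cnn(ModelConfig(n_classes=3), 50,
                           np.random.default_rng(SEED))
        X = np.random.default_rng(1).random((7, 50)).astype(np.float32)
        p = net.predict_proba(X)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Central-difference check of the full conv/pool/dense stack."""
        rng = np.random.default_rng(SEED)
        cfg = ModelConfig(n_classes=3, conv_filters=4, fc_sizes=(5,),
                          dropout_rate=0.0)
        net, _ = build_cnn(cfg, 12, rng)
        for layer in net.layers:  # float64 for the check
            for i, p in enumerate(layer.params):
                layer.params[i] = p.astype(np.float64)
                layer.grads[i] = layer.grads[i].astype(np.float64)
            if hasattr(layer, "W"):
                layer.W = layer.params[0]
                layer.b = layer.params[1]
        X = rng.random((3, 12))
        y = np.array([0, 2, 1])

        logits = net.forward(X, train=True)
        _, d = softmax_cross_entropy(logits, y)
        net.backward(d)
        analytic = [g.copy() for g in net.grads]

        eps = 1e-6
        for pi, p in enumerate(net.params):
            flat = p.ravel()
            for j in (0, flat.size // 2, flat.size - 1):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = softmax_cross_entropy(net.forward(X, True), y)
                flat[j] = orig - eps
                lm, _ = softmax_cross_entropy(net.forward(X, True), y)
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert analytic[pi].ravel()[j] == pytest.approx(num,
                                                                abs=1e-5)

    def test_input_gradient_shape_and_locality(self):
        rng = np.random.default_rng(SEED)
        cfg = ModelConfig(n_classes=2, conv_filters=4, fc_sizes=(5,),
                          dropout_rate=0.0)
        net, _ = build_cnn(cfg, 30, rng)
        X = rng.random((5, 30)).astype(np.float32)
        g = net.input_gradient(X)
        assert g.shape == X.shape


@pytest.fixture(scope="module")
def cohort():
    plan = CohortPlan(binary_signatures(), samples_per_class=10,
                      spectra_per_sample=4, noise=NoiseModel.zero(),
                      seed=SEED)
    return simulate_cohort(plan)


class TestFolds:
    def test_stratified_two_samples_per_class_per_fold(self, cohort):
        folds = make_folds(cohort, k=5, seed=SEED)
        st = cohort.sample_table().set_index("sample_id")
        for f in range(5):
            members = folds[folds == f].index
            counts = st.loc[members, "class_label"].value_counts()
            assert (counts == 2).all()

    def test_spectra_never_straddle_folds(self, cohort):
        folds = make_folds(cohort, k=5, seed=SEED)
        per_spectrum = cohort.meta["sample_id"].map(folds)
        g = pd.DataFrame({"sample_id": cohort.meta["sample_id"],
                          "fold": per_spectrum}).groupby("sample_id")["fold"]
        assert (g.nunique() == 1).all()

    def test_deterministic_under_seed(self, cohort):
        a = make_folds(cohort, k=5, seed=SEED)
        b = make_folds(cohort, k=5, seed=SEED)
        pd.testing.assert_series_equal(a, b)

    def test_too_few_samples_per_class_rejected(self):
        plan = CohortPlan(binary_signatures(), samples_per_class=3,
                          spectra_per_sample=2, noise=NoiseModel.zero(),
                          seed=SEED)
        ds = simulate_cohort(plan)
        with pytest.raises(ValueError, match="fewer than"):
            make_folds(ds, k=5)


def _small_training_set(n_per_class=30, seed=SEED):
    """Linearly separable noiseless toy set on a short grid."""
    rng = np.random.default_rng(seed)
    X = np.zeros((2 * n_per_class, 40), dtype=np.float32)
    X[:n_per_class, 10] = 1.0
    X[n_per_class:, 30] = 1.0
    X += rng.random(X.shape).astype(np.float32) * 0.01
    y = np.repeat([0, 1], n_per_class)
    sample_ids = np.array([f"s{i % 10}_{y[i]}" for i in range(2 * n_per_class)])
    return X, y, sample_ids


class TestTrainCnn:
    def test_separable_set_reaches_perfect_accuracy(self):
        X, y, sids = _small_training_set()
        cfg = ModelConfig(n_classes=2, epochs=50, batch_size=16,
                          monitor_fraction=0.0, seed=SEED)
        net, hist = train_cnn(X, y, sids, cfg)
        assert hist["train_acc"].iloc[-1] == 1.0
        assert hist["train_loss"].iloc[-1] <= hist["train_loss"].iloc[0]

    def test_same_seed_identical_history(self):
        X, y, sids = _small_training_set()
        cfg = ModelConfig(n_classes=2, epochs=8, batch_size=16, seed=SEED)
        _, h1 = train_cnn(X, y, sids, cfg)
        _, h2 = train_cnn(X, y, sids, cfg)
        assert h1["train_loss"].tolist() == h2["train_loss"].tolist()

    def test_single_class_split_rejected(self):
        X, y, sids = _small_training_set()
        with pytest.raises(ValueError, match="single class"):
            train_cnn(X, np.zeros_like(y), sids,
                      ModelConfig(n_classes=2, seed=SEED))

    def test_scheduler_reduces_lr_on_plateau(self):
        net = Network([Dense(4, 2, np.random.default_rng(0))])
        opt = Adam(net.params, lr=1e-3)
        from sersdx.nn import ReduceLROnPlateau
        sched = ReduceLROnPlateau(opt, patience=5, factor=0.5)
        for _ in range(7):
            sched.step(1.0)  # stalled
        assert opt.lr == pytest.approx(5e-4)


class TestRefiner:
    def test_one_hot_inputs_refined_to_same_argmax(self):
        rng = np.random.default_rng(SEED)
        y = rng.integers(0, 3, 300)
        probs = np.eye(3, dtype=np.float32)[y]
        cfg = ModelConfig(n_classes=3, refiner_epochs=150, seed=SEED)
        net = train_refiner(probs, y, cfg)
        refined = net.predict_proba(probs)
        assert (refined.argmax(axis=1) == probs.argmax(axis=1)).all()
        np.testing.assert_allclose(refined.sum(axis=1), 1.0, atol=1e-6)

    def test_in_fold_leakage_rejected(self):
        probs = np.full((10, 2), 0.5, dtype=np.float32)
        y = np.zeros(10, dtype=int)
        y[5:] = 1
        folds = np.array([0, 1, 2, 3, 4] * 2)
        with pytest.raises(LeakageError):
            train_refiner(probs, y, ModelConfig(n_classes=2),
                          producer_folds=folds, heldout_fold=2)

    def test_refiner_output_normalized_on_random_inputs(self):
        rng = np.random.default_rng(SEED)
        net = build_refiner_mlp(ModelConfig(n_classes=4), rng)
        p = net.predict_proba(rng.random((20, 4)).astype(np.float32))
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


@pytest.fixture(scope="module")
def cv_result() -> CrossValResult:
    plan = CohortPlan(binary_signatures(), samples_per_class=10,
                      spectra_per_sample=6, seed=SEED)
    pp = preprocess_pipeline(simulate_cohort(plan))
    cfg = ModelConfig(n_classes=2, epochs=12, seed=SEED)
    return cross_validate(pp, cfg, k=5)


class TestCrossValidate:
    def test_every_spectrum_predicted_exactly_once(self, cv_result):
        pred = cv_result.predictions
        assert pred["spectrum_id"].is_unique
        assert len(pred) == 120
        for kind in ("cnn", "refined"):
            p = cv_result.prob_matrix(kind)
            assert (p >= 0).all()
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_fold_partition_is_grouped_and_complete(self, cv_result):
        pred = cv_result.predictions
        g = pred.groupby("sample_id")["fold"].nunique()
        assert (g == 1).all()
        assert sorted(pred["fold"].unique()) == [0, 1, 2, 3, 4]
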