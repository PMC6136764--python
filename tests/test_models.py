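"""CNN and SVM decoders: architecture, training recipe, persistence."""

import numpy as np
import pytest

from emgctl.models import (
    CnnClassifier,
    CnnSpec,
    SvmClassifier,
    TrainSpec,
    build_cnn,
    cross_validate,
    load_model,
)
from emgctl.motions import MotionClass
from emgctl.preprocess import LabeledWindowSet

FS = 1200.0


def toy_windows(rng, n_per_class=120, scales=(0.1, 1.0)):
    """Amplitude-separated two-class window sets (trivially separable)."""
    windows, labels = [], []
    for scale, cls in zip(scales, (MotionClass.FLEXION, MotionClass.EXTENSION)):
        windows.append(scale * rng.standard_normal((n_per_class, 8, 192)))
        labels += [cls] * n_per_class
    return np.concatenate(windows), labels


class TestArchitecture:
    def test_layer_count_is_22(self):
        assert CnnSpec().n_layers == 22

    def test_shape_halving_sequence(self):
        # 8x192 -> 4x96 -> 2x48 -> 1x24, then constant
        assert CnnSpec().shape_trace() == [(4, 96), (2, 48), (1, 24), (1, 24), (1, 24)]

    def test_forward_gives_nine_probabilities_summing_to_one(self, rng):
        net = build_cnn(seed=0)
        probs = net.predict_proba(rng.standard_normal((3, 1, 8, 192)))
        assert probs.shape == (3, 9)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)
        assert np.all(probs >= 0)

    def test_filter_counts(self):
        spec = CnnSpec()
        assert spec.conv_filters == (16, 32, 64, 64, 16)

    def test_odd_spatial_size_rejected(self):
        with pytest.raises(ValueError):
            CnnSpec(input_shape=(7, 192)).build(np.random.default_rng(0))

    def test_wrong_window_shape_rejected(self, rng):
        model = CnnClassifier()
        with pytest.raises(ValueError):
            model.fit(rng.standard_normal((10, 8, 100)), [MotionClass.FLEXION] * 10)


class TestCnnTraining:
    def test_separable_toy_validation_accuracy(self, rng):
        windows, labels = toy_windows(rng)
        model = CnnClassifier(tspec=TrainSpec(max_epochs=6, seed=0))
        model.fit(windows, labels)
        assert model.history[-1]["val_acc"] >= 0.95
        # SVM oracle agrees the same data are separable
        from emgctl.features import extract_many
        feats = extract_many(windows, FS)
        svm = SvmClassifier().fit(feats, labels)
        assert svm.accuracy(feats, labels) >= 0.95

    def test_training_set_accuracy_after_convergence(self, rng):
        windows, labels = toy_windows(rng, n_per_class=60)
        model = CnnClassifier(tspec=TrainSpec(max_epochs=6, seed=1)).fit(windows, labels)
        assert model.accuracy(windows, labels) >= 0.95

    def test_same_seed_reproduces_history(self, rng):
        windows, labels = toy_windows(rng, n_per_class=40)
        spec = TrainSpec(max_epochs=2, seed=7)
        h1 = CnnClassifier(tspec=spec).fit(windows, labels).history
        h2 = CnnClassifier(tspec=spec).fit(windows, labels).history
        assert h1 == h2

    def test_early_stopping_on_unlearnable_labels(self, rng):
        # random labels: validation loss cannot keep improving, so the
        # 5-check patience must halt training before the epoch cap
        windows = 0.1 * rng.standard_normal((200, 8, 192))
        labels = [MotionClass(v) for v in
                  rng.choice([MotionClass.FLEXION.value, MotionClass.EXTENSION.value], 200)]
        spec = TrainSpec(max_epochs=40, seed=0, patience=5)
        model = CnnClassifier(tspec=spec).fit(windows, labels)
        assert model.history[-1]["epoch"] < 39

    def test_single_class_rejected(self, rng):
        model = CnnClassifier()
        with pytest.raises(ValueError):
            model.fit(rng.standard_normal((10, 8, 192)), [MotionClass.FLEXION] * 10)


class TestSvm:
    def test_default_gamma_is_reciprocal_feature_count(self, rng):
        feats = rng.standard_normal((60, 40))
        labels = [MotionClass.FLEXION] * 30 + [MotionClass.EXTENSION] * 30
        model = SvmClassifier().fit(feats, labels)
        assert model.pipeline.named_steps["svc"].gamma == pytest.approx(1 / 40)
        assert model.pipeline.named_steps["svc"].C == 1.0

    def test_nan_features_rejected(self, rng):
        feats = rng.standard_normal((10, 40))
        feats[3, 5] = np.nan
        with pytest.raises(ValueError):
            SvmClassifier().fit(feats, [MotionClass.FLEXION] * 5 + [MotionClass.EXTENSION] * 5)

    def test_duplicated_training_points_leave_predictions_unchanged(self, rng):
        feats = rng.standard_normal((80, 40))
        labels = ([MotionClass.FLEXION] * 40) + ([MotionClass.EXTENSION] * 40)
        feats[:40] += 2.0
        probe = rng.standard_normal((30, 40))
        base = SvmClassifier().fit(feats, labels).predict(probe)
        doubled = SvmClassifier().fit(np.concatenate([feats, feats]),
                                      labels + labels).predict(probe)
        assert all(a == b for a, b in zip(base, doubled))

    def test_scaler_is_inside_the_model(self, rng):
        feats = rng.standard_normal((60, 40)) * 100 + 50  # far from z-scored
        labels = [MotionClass.FLEXION] * 30 + [MotionClass.EXTENSION] * 30
        model = SvmClassifier().fit(feats, labels)
        assert "scale" in model.pipeline.named_steps


class TestPersistence:
    def test_cnn_round_trip(self, rng, tmp_path):
        windows, labels = toy_windows(rng, n_per_class=40)
        model = CnnClassifier(tspec=TrainSpec(max_epochs=1, seed=0)).fit(windows, labels)
        probe = rng.standard_normal((12, 8, 192))
        model.save(tmp_path / "cnn")
        loaded = load_model(tmp_path / "cnn")
        np.testing.assert_allclose(loaded.predict_scores(probe),
                                   model.predict_scores(probe), rtol=1e-6)
        assert loaded.classes_ == model.classes_

    def test_svm_round_trip(self, rng, tmp_path):
        feats = rng.standard_normal((60, 40))
        labels = [MotionClass.FLEXION] * 30 + [MotionClass.EXTENSION] * 30
        model = SvmClassifier().fit(feats, labels)
        probe = rng.standard_normal((20, 40))
        model.save(tmp_path / "svm")
        loaded = load_model(tmp_path / "svm")
        np.testing.assert_allclose(loaded.predict_scores(probe),
                                   model.predict_scores(probe))


class TestCrossValidate:
    def _tiny_set(self, rng):
        windows, labels = toy_windows(rng, n_per_class=60)
        return LabeledWindowSet(windows=windows, labels=labels, fs=FS)

    def test_four_folds_reported_with_mean_and_sem(self, rng):
        res = cross_validate(self._tiny_set(rng), method="svm", k_folds=4, seed=0)
        assert len(res.fold_accuracies) == 4
        assert res.mean == pytest.approx(np.mean(res.fold_accuracies))
        assert res.sem >= 0

    def test_fold_assignment_seeded(self, rng):
        data = self._tiny_set(rng)
        a = cross_validate(data, method="svm", k_folds=4, seed=3)
        b = cross_validate(data, method="svm", k_folds=4, seed=3)
        assert a.fold_accuracies == b.fold_accuracies

    def test_perfectly_separable_data_scores_100(self, rng):
        res = cross_validate(self._tiny_set(rng), method="svm", k_folds=4, seed=0)
        assert res.mean == pytest.approx(1.0)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate(self._tiny_set(rng), method="forest")
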