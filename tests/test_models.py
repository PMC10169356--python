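"""CNN construction, the differentiable-prediction contract, and the training protocol."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from simplexgrad.models import (
    ModelSpec,
    SequenceCNN,
    TrainConfig,
    build_model,
    load_model,
    save_model,
    train,
    train_ensemble,
)
from simplexgrad.nn.layers import Conv1D, Dense, ExpActivation, ReLU


class TestBuildModel:
    def test_deep_stack_layout(self):
        model = build_model(ModelSpec(architecture="deep", first_layer_activation="relu"))
        summary = model.summary()
        conv_shapes = [s for name, s, _ in summary if name == "Conv1D"]
        assert conv_shapes == [(200, 24), (200, 32), (50, 48), (12, 64)]
        dense_shapes = [s for name, s, _ in summary if name == "Dense"]
        assert dense_shapes == [(96,), (1,)]

    def test_shallow_stack_layout(self):
        model = build_model(ModelSpec(architecture="shallow"))
        summary = model.summary()
        assert [s for n, s, _ in summary if n == "Conv1D"] == [(200, 24), (4, 48)]
        assert [s for n, s, _ in summary if n == "MaxPool1D"] == [(4, 24), (2, 48)]

    def test_batchnorm_precedes_every_hidden_activation(self):
        model = build_model(ModelSpec(architecture="deep"))
        names = [type(l).__name__ for l in model.network_.layers]
        for i, name in enumerate(names):
            if name in ("ReLU", "ExpActivation"):
                assert names[i - 1] == "BatchNorm"
        assert names[-1] == "Dense"  # sigmoid applied at the loss/predict stage

    def test_exponential_only_on_first_layer(self):
        model = build_model(ModelSpec(architecture="shallow", first_layer_activation="exponential"))
        acts = [l for l in model.network_.layers if isinstance(l, (ReLU, ExpActivation))]
        assert isinstance(acts[0], ExpActivation)
        assert all(isinstance(a, ReLU) for a in acts[1:])

    def test_same_seed_identical_weights(self):
        a = build_model(ModelSpec(), seed=7)
        b = build_model(ModelSpec(), seed=7)
        for (ka, wa), (kb, wb) in zip(a.network_.parameters(), b.network_.parameters()):
            assert ka == kb
            np.testing.assert_array_equal(wa, wb)

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(architecture="resnet")
        with pytest.raises(ValueError):
            ModelSpec(first_layer_activation="gelu")

    def test_init_gain_scales_weights(self):
        small = build_model(ModelSpec(init_gain=0.5), seed=0)
        big = build_model(ModelSpec(init_gain=2.0), seed=0)
        w_s = small.network_.layers[0].params["W"]
        w_b = big.network_.layers[0].params["W"]
        np.testing.assert_allclose(w_b, 4.0 * w_s, rtol=1e-6)


class TestPredictorContract:
    @pytest.mark.parametrize("arch", ["shallow", "deep"])
    @pytest.mark.parametrize("act", ["relu", "exponential"])
    def test_gradient_matches_finite_differences(self, arch, act, rng):
        """Directional derivative vs central differences at relaxed inputs (float64)."""
        model = build_model(
            ModelSpec(architecture=arch, first_layer_activation=act), seed=3, dtype="float64"
        )
        x = rng.random((200, 4))
        g = model.input_gradient(x)
        v = rng.normal(size=(200, 4))
        v /= np.linalg.norm(v)
        h = 1e-3
        fd = (model.decision_function(x + h * v) - model.decision_function(x - h * v)) / (2 * h)
        assert abs(fd - float((g * v).sum())) <= 1e-3 * max(1.0, abs(fd))

    def test_prob_gradient_is_sigmoid_scaled_logit_gradient(self, rng):
        model = build_model(ModelSpec(architecture="shallow"), seed=1, dtype="float64")
        x = rng.random((200, 4))
        gz = model.input_gradient(x, output="logit")
        gp = model.input_gradient(x, output="prob")
        p = model.predict_score(x)
        np.testing.assert_allclose(gp, p * (1 - p) * gz, rtol=1e-9)

    def test_predictions_in_unit_interval(self, rng):
        model = build_model(ModelSpec(architecture="deep"), seed=2)
        X = (rng.random((7, 200, 4)) < 0.25).astype(np.float32)
        p = model.predict_proba(X)
        assert p.shape == (7, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-6)
        assert np.all((p > 0) & (p < 1))

    def test_shape_validation(self):
        model = build_model(ModelSpec(), seed=0)
        with pytest.raises(ValueError):
            model.decision_function(np.zeros((10, 100, 4)))


class TestTraining:
    def test_learns_above_chance_and_history_schema(self, easy_dataset):
        model = train(
            build_model(ModelSpec(architecture="shallow", input_length=100), seed=0),
            easy_dataset,
            TrainConfig(epochs=30, lr_patience=10, early_stopping=0, seed=0),
        )
        X, y, _ = easy_dataset.arrays("test")
        auc = roc_auc_score(y, model.predict_proba(X)[:, 1])
        assert auc > 0.65
        h = model.history_
        assert len(h["loss"]) == len(h["val_auc"]) == len(h["lr"]) == 30
        assert model.best_val_auc_ == max(h["val_auc"])

    def test_permuted_labels_give_chance_auc(self, tiny_dataset, rng):
        X, y, _ = tiny_dataset.arrays("train")
        Xv, yv, _ = tiny_dataset.arrays("valid")
        y_perm = rng.permutation(y)
        model = SequenceCNN(architecture="shallow", epochs=8, random_state=0).fit(
            X, y_perm, X_val=Xv, y_val=yv
        )
        Xt, yt, _ = tiny_dataset.arrays("test")
        auc = roc_auc_score(yt, model.predict_proba(Xt)[:, 1])
        assert abs(auc - 0.5) < 0.12

    def test_lr_trace_non_increasing_steps_by_decay(self, tiny_dataset):
        model = train(
            build_model(ModelSpec(architecture="shallow"), seed=1),
            tiny_dataset,
            TrainConfig(epochs=12, lr_patience=1, early_stopping=0, seed=1),
        )
        lrs = model.history_["lr"]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        distinct = sorted(set(lrs), reverse=True)
        for a, b in zip(distinct, distinct[1:]):
            assert b == pytest.approx(a * 0.2, rel=1e-9)

    def test_restores_best_validation_weights(self, tiny_dataset):
        model = train(
            build_model(ModelSpec(architecture="shallow"), seed=2),
            tiny_dataset,
            TrainConfig(epochs=10, early_stopping=0, seed=2),
        )
        Xv, yv, _ = tiny_dataset.arrays("valid")
        auc_now = roc_auc_score(yv, model.predict_proba(Xv)[:, 1])
        assert auc_now == pytest.approx(model.best_val_auc_, abs=1e-9)

    def test_checkpoint_roundtrip(self, tiny_dataset, tmp_path):
        model = train(
            build_model(ModelSpec(architecture="shallow"), seed=3),
            tiny_dataset,
            TrainConfig(epochs=2, seed=3),
        )
        X, _, _ = tiny_dataset.arrays("test")
        save_model(model, tmp_path / "ckpt.npz")
        back = load_model(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(
            back.decision_function(X[:8]), model.decision_function(X[:8]), rtol=1e-6
        )

    def test_divergence_detection(self, tiny_dataset):
        X, y, _ = tiny_dataset.arrays("valid")
        model = SequenceCNN(architecture="shallow", epochs=2, learning_rate=1e6, random_state=0)
        with pytest.raises(RuntimeError, match="diverged"):
            model.fit(X, y)


class TestEnsemble:
    def test_counts_and_distinct_members(self, tiny_dataset):
        models = train_ensemble(
            ModelSpec(architecture="shallow"),
            tiny_dataset,
            TrainConfig(epochs=1, seed=0),
            filter_counts=[12, 16],
            per_count=2,
        )
        assert len(models) == 4
        keys = {(m.first_layer_filters, m.random_state) for m in models}
        assert len(keys) == 4

    def test_full_scale_enumeration(self):
        counts = [12, 14, 16, 18, 20, 22, 24, 26, 28, 30]
        assert len(counts) * 5 == 50  # the full proxy-ensemble configuration

    def test_per_count_validation(self, tiny_dataset):
        with pytest.raises(ValueError):
            train_ensemble(ModelSpec(), tiny_dataset, TrainConfig(), per_count=0)

    def test_correction_moves_maps_toward_ensemble_proxy(self, easy_dataset):
        """Ensemble difference reduction is positive on average for a real mini-ensemble.

        Individual models' off-simplex gradient components are idiosyncratic,
        so they largely cancel in the ensemble mean; removing them from an
        individual map shrinks its distance to the proxy.
        """
        from simplexgrad.correction import correct_attribution
        from simplexgrad.evaluation import ensemble_difference_reduction

        models = train_ensemble(
            ModelSpec(architecture="shallow", input_length=100),
            easy_dataset,
            TrainConfig(epochs=2, seed=5),
            filter_counts=[12, 24],
            per_count=2,
        )
        X, _, _ = easy_dataset.arrays("test")
        maps = np.stack([m.input_gradient(X[:20]) for m in models])
        ens_mean = maps.mean(axis=0)
        reductions = []
        for k in range(len(models)):
            red = ensemble_difference_reduction(
                maps[k], correct_attribution(maps[k]), ens_mean
            )
            reductions.append(np.nanmean(red))
        assert np.mean(reductions) > 0
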