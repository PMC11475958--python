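import numpy as np
import pytest

from nirmoist import (
    CNNRegressor,
    PredictionSet,
    ResNet1DRegressor,
    XGBConfig,
    make_prediction_set,
    train_xgb,
)
from nirmoist import _nn
from nirmoist.metrics import r_squared


class TestXGB:
    def test_fits_step_function_exactly(self):
        x = np.linspace(0, 1, 200)[:, None]
        y = np.where(x.ravel() < 0.5, 1.0, 3.0)
        model = train_xgb(x, y, XGBConfig(n_estimators=200, max_depth=3, learning_rate=0.3))
        rmse = np.sqrt(np.mean((model.predict(x) - y) ** 2))
        assert rmse < 1e-3

    def test_zero_learning_rate_predicts_constant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (50, 3))
        y = rng.normal(0, 1, 50)
        model = train_xgb(x, y, XGBConfig(n_estimators=1, learning_rate=0.0))
        pred = model.predict(x)
        assert np.allclose(pred, pred[0])

    def test_seeded_determinism(self, small_xy):
        x, y = small_xy
        a = train_xgb(x, y, XGBConfig(n_estimators=50)).predict(x)
        b = train_xgb(x, y, XGBConfig(n_estimators=50)).predict(x)
        np.testing.assert_array_equal(a, b)

    def test_invalid_training_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_xgb(np.empty((0, 3)), np.empty(0))
        with pytest.raises(ValueError, match="finite"):
            train_xgb(np.array([[np.nan, 1.0]]), np.array([1.0]))


class TestNetworkContracts:
    def test_untrained_cnn_predicts_training_mean(self, small_xy):
        # the output head is zero-initialised, so with zero epochs every
        # prediction is the (de-standardised) zero = training mean
        x, y = small_xy
        model = CNNRegressor(epochs=0, random_state=0).fit(x, y)
        np.testing.assert_allclose(model.predict(x), y.mean(), atol=1e-6)

    def test_constant_target_converges_immediately(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (40, 32))
        y = np.full(40, 7.5)
        model = CNNRegressor(epochs=5, random_state=0).fit(x, y)
        rmse = np.sqrt(np.mean((model.predict(x) - y) ** 2))
        assert rmse < 1e-2

    def test_channel_count_mismatch_names_both_counts(self, small_xy):
        x, y = small_xy
        model = CNNRegressor(epochs=0, random_state=0).fit(x, y)
        with pytest.raises(ValueError, match=f"{x.shape[1]}.*got 60"):
            model.predict(np.zeros((2, 60)))

    def test_input_too_short_for_pooling_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            CNNRegressor(epochs=1).fit(np.zeros((10, 3)), np.zeros(10))

    def test_seeded_determinism(self, small_xy):
        x, y = small_xy
        a = CNNRegressor(epochs=3, random_state=5).fit(x, y).predict(x)
        b = CNNRegressor(epochs=3, random_state=5).fit(x, y).predict(x)
        np.testing.assert_allclose(a, b, atol=1e-4)


class TestResidualBlocks:
    def test_zero_convolutions_give_identity_mapping(self):
        rng = np.random.default_rng(2)
        block = _nn.ResidualBlock(8, 8, rng=rng)
        for layer in block.body.layers:
            if isinstance(layer, _nn.Conv1d):
                layer.w.value[...] = 0.0
                layer.b.value[...] = 0.0
        x = np.abs(rng.normal(0, 1, (3, 16, 8))).astype(np.float32)
        out = block.forward(x, train=False)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_equal_width_shortcut_has_no_parameters(self):
        block = _nn.ResidualBlock(16, 16)
        assert block.shortcut is None
        projected = _nn.ResidualBlock(16, 32, stride=2)
        assert projected.shortcut is not None

    def test_resnet_has_sixteen_convolutions_in_blocks(self, small_xy):
        x, y = small_xy
        model = ResNet1DRegressor(epochs=0, random_state=0).fit(x, y)
        n_body_convs = 0
        for layer in model.net_.layers:
            if isinstance(layer, _nn.ResidualBlock):
                n_body_convs += sum(
                    isinstance(sub, _nn.Conv1d) for sub in layer.body.layers
                )
        assert n_body_convs == 16


class TestPredictionSets:
    def test_perfectly_fit_tree_reproduces_training_targets(self):
        x = np.arange(20.0)[:, None]
        y = np.where(x.ravel() < 10, 0.0, 1.0)
        model = train_xgb(x, y, XGBConfig(n_estimators=50, max_depth=2,
                                          learning_rate=1.0, reg_lambda=0.0))
        ps = make_prediction_set(model, x, y, "train", "xgb", "full")
        np.testing.assert_allclose(ps.y_actual, ps.y_pred, atol=1e-6)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="entries"):
            PredictionSet(y_actual=np.zeros(3), y_pred=np.zeros(4))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PredictionSet(y_actual=np.array([1.0, np.inf]), y_pred=np.zeros(2))


class TestNetworkAccuracy:
    """Scaled-down end-to-end accuracy on synthetic spectra."""

    def test_cnn_on_selected_wavelengths(self, small_xy):
        x, y = small_xy
        # emulate a selected-wavelength subset around the informative bands
        cols = np.arange(60, 100)
        tr, te = np.arange(90), np.arange(90, 120)
        model = CNNRegressor(epochs=100, random_state=0).fit(x[tr][:, cols], y[tr])
        ps = make_prediction_set(model, x[te][:, cols], y[te])
        assert r_squared(ps) > 0.8

    def test_resnet_on_full_wavelengths(self, small_xy):
        x, y = small_xy
        tr, te = np.arange(90), np.arange(90, 120)
        model = ResNet1DRegressor(epochs=150, random_state=0).fit(x[tr], y[tr])
        ps = make_prediction_set(model, x[te], y[te])
        assert r_squared(ps) > 0.75
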