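"""The three regressor families: gradient boosting, 1-D CNN, 1-D ResNet-18.

All three are exposed as scikit-learn regressors that accept a spectra
matrix ``(n_samples, n_channels)`` and a moisture vector.  The networks
standardise inputs per channel and the response internally, train on mean
squared error with Adam for a fixed number of epochs (the epoch count is
the stopping criterion; no early stopping), and are fully deterministic
for a fixed ``random_state``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBRegressor

from . import _nn

__all__ = [
    "XGBConfig",
    "make_xgb_regressor",
    "train_xgb",
    "CNNRegressor",
    "ResNet1DRegressor",
    "PredictionSet",
    "make_prediction_set",
]


@dataclass(frozen=True)
class XGBConfig:
    """Gradient-boosting hyperparameters.

    ``reg_lambda`` is the L2 leaf-weight penalty and ``gamma`` the per-leaf
    complexity penalty of the regularised objective; both are passed through
    to the boosting implementation.
    """

    n_estimators: int = 400
    max_depth: int = 6
    learning_rate: float = 0.05
    reg_lambda: float = 1.0
    gamma: float = 0.0
    objective: str = "reg:squarederror"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.reg_lambda < 0 or self.gamma < 0:
            raise ValueError("penalties must be >= 0")


def make_xgb_regressor(config: XGBConfig | None = None) -> XGBRegressor:
    config = config or XGBConfig()
    return XGBRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        reg_lambda=config.reg_lambda,
        gamma=config.gamma,
        objective=config.objective,
        random_state=config.seed,
        n_jobs=1,
        tree_method="exact",
    )


def train_xgb(x_train: np.ndarray, y_train: np.ndarray, config: XGBConfig | None = None) -> XGBRegressor:
    """Fit the boosted-tree moisture model; deterministic (single thread)."""
    x_train = np.atleast_2d(np.asarray(x_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    if x_train.shape[0] != y_train.size:
        raise ValueError("x_train rows and y_train length differ")
    if not np.all(np.isfinite(x_train)) or not np.all(np.isfinite(y_train)):
        raise ValueError("non-finite values in training data")
    model = make_xgb_regressor(config)
    model.fit(x_train, y_train)
    return model


class _NetworkRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing for the numpy network regressors."""

    def _build(self, n_channels: int, rng: np.random.Generator) -> _nn.Module:
        raise NotImplementedError

    def _validate_length(self, n_channels: int) -> None:
        raise NotImplementedError

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=1, dtype="numeric")
        y = np.asarray(y, dtype=float).ravel()
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0 (0 trains nothing, initialise only)")
        self._validate_length(X.shape[1])

        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_sd_ = np.where(sd > 0, sd, 1.0)
        self.y_mean_ = float(y.mean())
        y_sd = float(y.std())
        self.y_sd_ = y_sd if y_sd > 0 else 1.0

        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build(X.shape[1], rng)
        xz = ((X - self.x_mean_) / self.x_sd_)[:, :, None]  # (B, L, 1)
        yz = (y - self.y_mean_) / self.y_sd_
        self.loss_history_ = _nn.fit_mse(
            self.net_, xz, yz, epochs=self.epochs,
            batch_size=min(self.batch_size, X.shape[0]), lr=self.learning_rate, rng=rng,
        )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"channel-count mismatch: model was trained on "
                f"{self.n_features_in_} channels but got {X.shape[1]}"
            )
        xz = ((X - self.x_mean_) / self.x_sd_)[:, :, None]
        out = self.net_.forward(xz.astype(_nn.DTYPE), train=False).ravel()
        return out.astype(float) * self.y_sd_ + self.y_mean_


class CNNRegressor(_NetworkRegressorBase):
    """1-D convolutional network for spectral regression.

    Architecture: conv(64) -> maxpool -> conv(128) -> maxpool -> conv(256)
    -> flatten -> dense -> dense(1), with ReLU activations.  The stem
    convolution uses a 7-tap kernel, later convolutions 3 taps.  The output
    head is zero-initialised so an untrained model predicts the training
    mean.

    Parameters
    ----------
    epochs : int
        Exact number of training epochs (the stopping criterion).
    learning_rate : float
        Adam step size; default 0.001.
    """

    def __init__(self, conv_channels=(64, 128, 256), kernel_size: int = 3,
                 stem_kernel_size: int = 7, dense_units: int = 64,
                 learning_rate: float = 0.001, epochs: int = 800,
                 batch_size: int = 32, random_state: int = 0):
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.stem_kernel_size = stem_kernel_size
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate_length(self, n_channels: int) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("conv_channels must list exactly three widths")
        # two 2x poolings must leave at least one position
        if n_channels // 4 < 1 or n_channels < self.stem_kernel_size:
            raise ValueError(
                f"input length {n_channels} too short for two pooling "
                f"halvings and a {self.stem_kernel_size}-tap stem"
            )

    def _build(self, n_channels: int, rng: np.random.Generator) -> _nn.Module:
        c1, c2, c3 = self.conv_channels
        flat = (n_channels // 2 // 2) * c3
        return _nn.Sequential(
            _nn.Conv1d(1, c1, self.stem_kernel_size, rng=rng),
            _nn.ReLU(),
            _nn.MaxPool1d(2),
            _nn.Conv1d(c1, c2, self.kernel_size, rng=rng),
            _nn.ReLU(),
            _nn.MaxPool1d(2),
            _nn.Conv1d(c2, c3, self.kernel_size, rng=rng),
            _nn.ReLU(),
            _nn.Flatten(),
            _nn.Dense(flat, self.dense_units, rng=rng),
            _nn.ReLU(),
            _nn.Dense(self.dense_units, 1, rng=rng, zero_init=True),
        )


class ResNet1DRegressor(_NetworkRegressorBase):
    """1-D ResNet-18-style network for spectral regression.

    Stem: 7-tap stride-2 convolution + batch norm + ReLU + 3-tap stride-2
    max pool.  Body: four stages of two basic residual blocks each (two
    3-tap convolutions per block, 16 in total), widths 64/128/256/512,
    identity shortcuts within a stage and strided projection shortcuts at
    stage entries.  Head: global average pool + zero-initialised linear
    output.
    """

    stage_widths = (64, 128, 256, 512)

    def __init__(self, learning_rate: float = 0.0001, epochs: int = 1200,
                 batch_size: int = 32, random_state: int = 0):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate_length(self, n_channels: int) -> None:
        # stem conv (stride 2) + pool (stride 2) + three strided stages
        length = n_channels
        for _ in range(5):
            length = (length + 1) // 2
        if length < 1:
            raise ValueError(f"input length {n_channels} too short for the residual stack")

    def _build(self, n_channels: int, rng: np.random.Generator) -> _nn.Module:
        layers: list[_nn.Module] = [
            _nn.Conv1d(1, 64, 7, stride=2, rng=rng),
            _nn.BatchNorm1d(64),
            _nn.ReLU(),
            _nn.MaxPool1d(3, stride=2, pad=1),
        ]
        in_ch = 64
        for stage, width in enumerate(self.stage_widths):
            stride = 1 if stage == 0 else 2
            layers.append(_nn.ResidualBlock(in_ch, width, stride=stride, rng=rng))
            layers.append(_nn.ResidualBlock(width, width, rng=rng))
            in_ch = width
        layers += [
            _nn.GlobalAvgPool(),
            _nn.Dense(in_ch, 1, rng=rng, zero_init=True),
        ]
        return _nn.Sequential(*layers)


@dataclass
class PredictionSet:
    """Aligned actual/predicted moisture for one model on one sample set."""

    y_actual: np.ndarray
    y_pred: np.ndarray
    set_label: str = "test"
    model_label: str = ""
    wavelength_set_label: str = "full"

    def __post_init__(self) -> None:
        self.y_actual = np.asarray(self.y_actual, dtype=float).ravel()
        self.y_pred = np.asarray(self.y_pred, dtype=float).ravel()
        if self.y_actual.size != self.y_pred.size:
            raise ValueError(
                f"y_actual has {self.y_actual.size} entries but y_pred has "
                f"{self.y_pred.size}"
            )
        if not (np.all(np.isfinite(self.y_actual)) and np.all(np.isfinite(self.y_pred))):
            raise ValueError("non-finite values in prediction set")

    @property
    def n(self) -> int:
        return self.y_actual.size


def make_prediction_set(model, x, y, set_label="test", model_label="",
                        wavelength_set_label="full") -> PredictionSet:
    """Predict with a fitted model and bundle aligned actual/predicted values."""
    return PredictionSet(
        y_actual=y,
        y_pred=model.predict(np.atleast_2d(np.asarray(x, dtype=float))),
        set_label=set_label,
        model_label=model_label,
        wavelength_set_label=wavelength_set_label,
    )
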