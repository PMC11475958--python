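"""Gaussian-process prediction intervals for moisture predictions.

A one-dimensional GP regression is fitted from a model's point predictions
(inputs) to the corresponding measured moisture values (targets), using a
Matern 5/2 kernel plus Gaussian white noise:

    y = f(x) + eps,   f ~ GP(0, k_Matern52),   eps ~ N(0, sigma_n^2)

Hyperparameters (signal variance, length scale, noise variance) are set by
marginal-likelihood maximisation.  The predictive distribution at a new
point has mean mu* and variance sigma*^2 = k** - k*ᵀ (K + sigma_n^2 I)^-1 k*
+ sigma_n^2; the noise term is included so the 95 % band is a prediction
interval for observations, not a confidence interval for the latent mean.
Bounds are mu* +/- 1.96 sigma*.

To avoid information leakage, the calibration is fitted on TRAINING-set
(prediction, actual) pairs and then applied to test-set predictions; fitting
on pooled train+test pairs is available via ``include_test_in_fit`` for
protocol comparisons only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.utils.validation import check_is_fitted

__all__ = ["PredictionInterval", "IntervalCalibrator", "fit_gpr", "predict_interval"]

_NOISE_FLOOR = 1e-8


@dataclass
class PredictionInterval:
    """Per-sample posterior mean/SD and symmetric interval bounds."""

    mu: np.ndarray
    sigma: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    confidence: float = 0.95

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if not (self.mu.size == self.sigma.size == self.lower.size == self.upper.size):
            raise ValueError("interval vectors must have equal length")
        if np.any(self.lower > self.mu) or np.any(self.mu > self.upper):
            raise ValueError("interval bounds must bracket the posterior mean")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def _z_value(confidence: float) -> float:
    # the conventional two-decimal multiplier at 95 %, exact quantile otherwise
    if confidence == 0.95:
        return 1.96
    return float(stats.norm.ppf(0.5 + confidence / 2.0))


class IntervalCalibrator(BaseEstimator):
    """GP calibration from point predictions to measured values.

    Parameters
    ----------
    confidence : float
        Two-sided interval coverage level; 0.95 uses the 1.96 multiplier.
    n_restarts : int
        Extra random restarts of the marginal-likelihood optimiser.
    normalize_y : bool
        Centre/scale targets inside the GP (recommended); fitted noise and
        signal SDs are always reported in original target units.

    Fitted attributes
    -----------------
    gpr_ : the underlying Gaussian-process regressor
    noise_sd_, signal_sd_, length_scale_ : kernel hyperparameters in
        original target units
    """

    def __init__(self, confidence: float = 0.95, n_restarts: int = 2,
                 normalize_y: bool = True, random_state: int = 0):
        self.confidence = confidence
        self.n_restarts = n_restarts
        self.normalize_y = normalize_y
        self.random_state = random_state

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape[0] != y.size:
            raise ValueError("x and y lengths differ")
        if x.shape[0] < 3:
            raise ValueError("need at least 3 calibration pairs")

        degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
        if degenerate:
            warnings.warn(
                "degenerate calibration inputs (no spread); fitting with a "
                "fixed kernel and noise floor", stacklevel=2,
            )
        kernel = (
            ConstantKernel(1.0, (1e-4, 1e4))
            * Matern(length_scale=1.0, length_scale_bounds=(1e-3, 1e4), nu=2.5)
            + WhiteKernel(noise_level=1e-2, noise_level_bounds=(_NOISE_FLOOR, 1e2))
        )
        self.gpr_ = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-10,
            normalize_y=self.normalize_y,
            optimizer=None if degenerate else "fmin_l_bfgs_b",
            n_restarts_optimizer=self.n_restarts,
            random_state=self.random_state,
        )
        self.gpr_.fit(x, y)

        k = self.gpr_.kernel_
        y_scale = float(np.std(y)) if (self.normalize_y and np.ptp(y) > 0) else 1.0
        self.length_scale_ = float(k.k1.k2.length_scale)
        self.signal_sd_ = float(np.sqrt(k.k1.k1.constant_value)) * y_scale
        self.noise_sd_ = float(np.sqrt(k.k2.noise_level)) * y_scale
        return self

    def predict_interval(self, x) -> PredictionInterval:
        """Posterior mean, predictive SD and symmetric bounds per input."""
        check_is_fitted(self)
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        mu, sigma = self.gpr_.predict(x, return_std=True)
        z = _z_value(self.confidence)
        half = z * sigma
        return PredictionInterval(
            mu=mu, sigma=sigma, lower=mu - half, upper=mu + half,
            confidence=self.confidence,
        )


def fit_gpr(calib_inputs, calib_targets, confidence: float = 0.95,
            n_restarts: int = 2, random_state: int = 0) -> IntervalCalibrator:
    """Fit the interval calibration; thin wrapper over IntervalCalibrator."""
    return IntervalCalibrator(
        confidence=confidence, n_restarts=n_restarts, random_state=random_state,
    ).fit(calib_inputs, calib_targets)


def predict_interval(calib: IntervalCalibrator, inputs) -> PredictionInterval:
    return calib.predict_interval(inputs)
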