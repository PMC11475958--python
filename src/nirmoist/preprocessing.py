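"""Savitzky-Golay smoothing combined with the first derivative.

Smoothing and differentiation are performed in a single least-squares
convolution pass; the first derivative removes additive baseline offsets and
attenuates multiplicative scatter, the polynomial smoothing suppresses
channel noise.  Output is in absorbance per nm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .simulate import SpectraSet

__all__ = ["SGParams", "SavitzkyGolayDerivative", "sg_first_derivative"]

#: relative tolerance for the uniform-grid check
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter settings.

    window_length must be odd and larger than polyorder; delta_nm is the
    (uniform) channel spacing in nm so the derivative comes out per nm.
    """

    window_length: int = 11
    polyorder: int = 2
    deriv_order: int = 1
    delta_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length <= self.polyorder:
            raise ValueError(
                f"window_length ({self.window_length}) must be odd and > "
                f"polyorder ({self.polyorder})"
            )
        if self.polyorder < 1:
            raise ValueError("polyorder must be >= 1")
        if self.deriv_order != 1:
            raise ValueError("only the first derivative is supported")
        if self.delta_nm <= 0:
            raise ValueError("delta_nm must be > 0")


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """First-derivative Savitzky-Golay transformer over spectral channels.

    Parameters
    ----------
    window_length : int
        Odd filter window in channels.
    polyorder : int
        Degree of the local fitting polynomial (>= 1, < window_length).
    delta : float
        Channel spacing in nm; derivatives are returned per nm.

    Edges are handled by re-fitting the boundary polynomial (``mode="interp"``)
    so the output shape equals the input shape.
    """

    def __init__(self, window_length: int = 11, polyorder: int = 2, delta: float = 1.0):
        self.window_length = window_length
        self.polyorder = polyorder
        self.delta = delta

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_features=2)
        SGParams(self.window_length, self.polyorder, 1, self.delta)  # validate
        if self.window_length > X.shape[1]:
            raise ValueError(
                f"window_length ({self.window_length}) exceeds the channel "
                f"count ({X.shape[1]})"
            )
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return savgol_filter(
            X, self.window_length, self.polyorder, deriv=1,
            delta=self.delta, axis=-1, mode="interp",
        )


def sg_first_derivative(spectra: SpectraSet, params: SGParams | None = None) -> SpectraSet:
    """Apply S-G smoothing + first derivative to a SpectraSet.

    The wavelength grid must be uniform (relative tolerance 1e-6); the
    channel spacing of the grid overrides ``params.delta_nm``.  The moisture
    vector passes through unchanged.
    """
    params = params or SGParams()
    steps = np.diff(spectra.wavelengths)
    delta = float(steps.mean())
    if np.any(np.abs(steps - delta) > _GRID_RTOL * abs(delta)):
        raise ValueError("non-uniform wavelength grid is not supported by the S-G derivative")
    params = replace(params, delta_nm=delta)

    est = SavitzkyGolayDerivative(params.window_length, params.polyorder, delta=params.delta_nm)
    deriv = est.fit_transform(spectra.absorbance)
    return SpectraSet(wavelengths=spectra.wavelengths, absorbance=deriv, moisture=spectra.moisture)
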