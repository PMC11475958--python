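"""Point and interval evaluation metrics for moisture calibration models.

Point metrics: coefficient of determination R², root mean square error of
prediction (RMSEP, with an n-1 denominator), and the ratio of performance
to deviation (RPD) in two conventions — ``1/sqrt(1 - R²)`` and
``SD(actual)/RMSEP``.  Interval metrics: prediction interval coverage
probability (PICP, strict bounds), prediction interval normalized average
width (PINAW, normalised by the observed response range), and the coverage
width criterion CWC = PICP / PINAW.  Percent changes between model runs are
computed under explicit conventions because comparative statements in the
field mix "relative to the old value" and "relative to the new value"
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regressors import PredictionSet
from .uncertainty import PredictionInterval

__all__ = [
    "PointMetrics",
    "IntervalMetrics",
    "r_squared",
    "rmsep",
    "rpd_from_r2",
    "rpd_sd_ratio",
    "picp",
    "pinaw",
    "cwc",
    "relative_change",
    "point_metrics",
    "interval_metrics",
]


@dataclass(frozen=True)
class PointMetrics:
    r2: float
    rmsep: float
    rpd_eq: float        # 1 / sqrt(1 - R²)
    rpd_sd_ratio: float  # SD(actual) / RMSEP
    n: int


@dataclass(frozen=True)
class IntervalMetrics:
    picp: float
    pinaw: float
    cwc: float
    n: int
    response_range: float


def _vectors(p: PredictionSet) -> tuple[np.ndarray, np.ndarray]:
    return p.y_actual, p.y_pred


def r_squared(p: PredictionSet) -> float:
    """Coefficient of determination, denominator centred on mean(actual)."""
    y, yhat = _vectors(p)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance actual values; R² undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmsep(p: PredictionSet) -> float:
    """Root mean square error of prediction with an n-1 denominator."""
    y, yhat = _vectors(p)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / (y.size - 1)))


def rpd_from_r2(r2: float) -> float:
    """RPD from R² as 1/sqrt(1 - R²); infinite at R² = 1."""
    if r2 > 1:
        raise ValueError("R² cannot exceed 1")
    if r2 == 1:
        return float("inf")
    return float(1.0 / np.sqrt(1.0 - r2))


def rpd_sd_ratio(p: PredictionSet) -> float:
    """RPD in the SD(actual)/RMSEP convention."""
    y, _ = _vectors(p)
    e = rmsep(p)
    sd = float(np.std(y, ddof=1))
    return float("inf") if e == 0 else sd / e


def picp(y_actual: np.ndarray, interval: PredictionInterval) -> float:
    """Fraction of observations strictly inside their prediction interval.

    Bounds are exclusive: a value exactly on a bound counts as uncovered.
    """
    y = np.asarray(y_actual, dtype=float).ravel()
    if y.size != interval.mu.size:
        raise ValueError(
            f"y has {y.size} entries but the interval covers {interval.mu.size}"
        )
    return float(np.mean((interval.lower < y) & (y < interval.upper)))


def pinaw(y_actual: np.ndarray, interval: PredictionInterval) -> float:
    """Mean interval width normalised by the observed response range."""
    y = np.asarray(y_actual, dtype=float).ravel()
    if y.size != interval.mu.size:
        raise ValueError("length mismatch between y and interval")
    r = float(np.ptp(y))
    if r == 0:
        raise ValueError("zero response range; PINAW undefined")
    return float(np.mean(np.abs(interval.upper - interval.lower)) / r)


def cwc(picp_value: float, pinaw_value: float) -> float:
    """Coverage width criterion: PICP / PINAW (higher is better)."""
    if pinaw_value < 0:
        raise ValueError("PINAW must be >= 0")
    if pinaw_value == 0:
        return float("inf")
    return picp_value / pinaw_value


_CONVENTIONS = ("increase_vs_old", "decrease_vs_old", "reduction_vs_new")


def relative_change(old: float, new: float, convention: str) -> float:
    """Percent change between two metric values under a named convention.

    increase_vs_old: 100 (new - old) / old
    decrease_vs_old: 100 (old - new) / old
    reduction_vs_new: 100 (old - new) / new
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {_CONVENTIONS}")
    denom = old if convention.endswith("_old") else new
    if denom == 0:
        raise ValueError("zero denominator in percent change")
    num = (new - old) if convention == "increase_vs_old" else (old - new)
    return 100.0 * num / denom


def point_metrics(p: PredictionSet) -> PointMetrics:
    r2 = r_squared(p)
    return PointMetrics(
        r2=r2,
        rmsep=rmsep(p),
        rpd_eq=rpd_from_r2(min(r2, 1.0)),
        rpd_sd_ratio=rpd_sd_ratio(p),
        n=p.n,
    )


def interval_metrics(y_actual: np.ndarray, interval: PredictionInterval) -> IntervalMetrics:
    y = np.asarray(y_actual, dtype=float).ravel()
    p = picp(y, interval)
    w = pinaw(y, interval)
    return IntervalMetrics(picp=p, pinaw=w, cwc=cwc(p, w), n=y.size,
                           response_range=float(np.ptp(y)))
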