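"""Deterministic SPXY / Kennard-Stone train-test partitioning.

Both algorithms grow the training set by max-min selection: start from the
two most distant samples, then repeatedly add the candidate whose minimum
distance to the already-selected set is largest.  Kennard-Stone uses the
Euclidean spectral distance only; SPXY adds the response distance, each
normalised by its maximum:

    d(i, j) = dx(i, j) / max dx + |y_i - y_j| / max dy

so a training set is representative in both spectral and chemical space.
Ties are broken toward the lowest index, making the split fully
deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SplitResult", "spxy_split", "ks_split", "split_diagnostics"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test index sets with provenance."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    method: str
    n_train: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_indices", np.asarray(self.train_indices, dtype=int))
        object.__setattr__(self, "test_indices", np.asarray(self.test_indices, dtype=int))
        train, test = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")
        if len(self.train_indices) != self.n_train:
            raise ValueError("train size does not match n_train")

    @property
    def n_samples(self) -> int:
        return len(self.train_indices) + len(self.test_indices)

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "n_train": int(self.n_train),
            "train_indices": self.train_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            train_indices=np.array(payload["train_indices"]),
            test_indices=np.array(payload["test_indices"]),
            method=payload["method"],
            n_train=payload["n_train"],
        )


def _normalized(d: np.ndarray, label: str) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        warnings.warn(
            f"maximum {label} distance is 0; that term is dropped from the "
            "joint distance", stacklevel=3,
        )
        return np.zeros_like(d)
    return d / dmax

def _maxmin_select(d: np.ndarray, n_train: int) -> np.ndarray:
    """Max-min training selection on a full distance matrix.

    Ties resolve to the lowest index (np.argmax convention on both the
    seeding pair and each growth step).
    """
    n = d.shape[0]
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}], got {n_train}")
    # seed: lexicographically first pair attaining the maximum distance
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    if i == j:  # all-identical degenerate case
        selected = [0, 1]
    mask = np.zeros(n, dtype=bool)
    mask[selected] = True
    # min distance from every sample to the selected set
    min_d = d[:, selected].min(axis=1)
    while mask.sum() < n_train:
        min_d_masked = np.where(mask, -np.inf, min_d)
        nxt = int(np.argmax(min_d_masked))
        mask[nxt] = True
        min_d = np.minimum(min_d, d[:, nxt])
    return np.flatnonzero(mask)


def _finish(x: np.ndarray, d: np.ndarray, n_train: int, method: str) -> SplitResult:
    train = _maxmin_select(d, n_train)
    test = np.setdiff1d(np.arange(x.shape[0]), train)
    return SplitResult(train_indices=train, test_indices=test, method=method, n_train=n_train)


def spxy_split(x: np.ndarray, y: np.ndarray, n_train: int) -> SplitResult:
    """SPXY partition on the joint normalised spectral + response distance."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError(f"x has {x.shape[0]} rows but y has {y.size} entries")
    dx = cdist(x, x)
    dy = np.abs(y[:, None] - y[None, :])
    d = _normalized(dx, "spectral") + _normalized(dy, "response")
    return _finish(x, d, n_train, "spxy")


def ks_split(x: np.ndarray, n_train: int) -> SplitResult:
    """Kennard-Stone partition on the Euclidean spectral distance."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = _normalized(cdist(x, x), "spectral")
    return _finish(x, d, n_train, "ks")


def split_diagnostics(y: np.ndarray, split: SplitResult) -> dict:
    """Report whether the test-set response range lies inside the train range.

    Max-min selection usually places the response extremes in the training
    set, but does not guarantee it, so this is reported rather than enforced.
    """
    y = np.asarray(y, dtype=float)
    y_train, y_test = y[split.train_indices], y[split.test_indices]
    out = {
        "train_y_min": float(y_train.min()),
        "train_y_max": float(y_train.max()),
        "test_y_min": float(y_test.min()) if y_test.size else None,
        "test_y_max": float(y_test.max()) if y_test.size else None,
    }
    out["test_range_within_train"] = (
        y_test.size == 0
        or (out["test_y_min"] >= out["train_y_min"] and out["test_y_max"] <= out["train_y_max"])
    )
    return out
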