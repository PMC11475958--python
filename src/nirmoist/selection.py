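"""Genetic-algorithm wavelength selection with a PLS cross-validation fitness.

Chromosomes are binary channel masks.  Each mask is scored by the negative
mean squared error of a k-fold cross-validated PLS regression restricted to
the masked channels; the GA maximises this fitness with tournament
selection, uniform crossover, per-bit mutation and elitism.  The all-ones
chromosome is injected into the initial population so the selected subset
can never score worse than the full spectrum on the training CV criterion.

For interpretation, PLS regression coefficients on standardised predictors
quantify each selected channel's contribution to the moisture prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "GAConfig",
    "SelectionResult",
    "pls_fitness",
    "ga_select",
    "wavelength_importance",
    "GAPLSSelector",
]

INFEASIBLE = -np.inf


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    n_generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism_count: int = 2
    min_selected: int = 5
    pls_components: int = 8
    cv_folds: int = 5
    tournament_size: int = 3
    init_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.min_selected < 1:
            raise ValueError("min_selected must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.pls_components < 1:
            raise ValueError("pls_components must be >= 1")


@dataclass
class SelectionResult:
    selected_channels: np.ndarray
    selected_wavelengths_nm: np.ndarray | None
    best_fitness_per_generation: np.ndarray
    importance: np.ndarray
    best_fitness: float

    def to_json(self, path) -> None:
        import json

        payload = {
            "selected_channels": self.selected_channels.tolist(),
            "selected_wavelengths_nm": (
                None if self.selected_wavelengths_nm is None
                else self.selected_wavelengths_nm.tolist()
            ),
            "best_fitness_per_generation": self.best_fitness_per_generation.tolist(),
            "importance": self.importance.tolist(),
            "best_fitness": self.best_fitness,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _cv_folds(n: int, config: GAConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    return list(kf.split(np.empty((n, 1))))


def pls_fitness(
    mask: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Negative CV mean squared error of PLS restricted to masked channels.

    Returns ``-inf`` for infeasible masks (fewer active channels than
    ``min_selected``) instead of raising, so the GA can score any chromosome.
    """
    mask = np.asarray(mask, dtype=bool)
    n_sel = int(mask.sum())
    if n_sel < config.min_selected:
        return INFEASIBLE
    x_sel = np.asarray(x, dtype=float)[:, mask]
    y = np.asarray(y, dtype=float).ravel()
    folds = folds if folds is not None else _cv_folds(len(y), config)
    sq_errors = np.empty(len(y))
    for train_idx, test_idx in folds:
        n_comp = min(config.pls_components, n_sel, len(train_idx) - 1)
        pls = PLSRegression(n_components=n_comp, scale=False)
        pls.fit(x_sel[train_idx], y[train_idx])
        pred = pls.predict(x_sel[test_idx]).ravel()
        sq_errors[test_idx] = (pred - y[test_idx]) ** 2
    return float(-np.mean(sq_errors))


def wavelength_importance(x_selected: np.ndarray, y: np.ndarray, pls_components: int) -> np.ndarray:
    """PLS regression coefficients on standardised predictors.

    Standardisation makes coefficient magnitudes comparable across channels
    with different variances.  Zero-variance channels get coefficient 0; a
    constant response yields the all-zero vector.  The component count is
    reduced automatically (with a warning) when it exceeds what the data
    support.
    """
    x_selected = np.atleast_2d(np.asarray(x_selected, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x_selected.shape[1] == 0:
        raise ValueError("no channels selected")
    if np.ptp(y) == 0:
        return np.zeros(x_selected.shape[1])
    sd = x_selected.std(axis=0)
    keep = sd > 0
    z = np.zeros_like(x_selected)
    z[:, keep] = (x_selected[:, keep] - x_selected[:, keep].mean(axis=0)) / sd[keep]
    max_comp = min(int(keep.sum()), x_selected.shape[0] - 1)
    n_comp = min(pls_components, max_comp)
    if n_comp < pls_components:
        warnings.warn(
            f"pls_components reduced from {pls_components} to {n_comp} "
            "(limited by data rank)", stacklevel=2,
        )
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(z[:, keep], y)
    coef = np.zeros(x_selected.shape[1])
    coef[keep] = pls.coef_.ravel()
    return coef


def _repair(mask: np.ndarray, min_selected: int, rng: np.random.Generator) -> np.ndarray:
    """Activate random bits until the mask is feasible."""
    deficit = min_selected - int(mask.sum())
    if deficit > 0:
        off = np.flatnonzero(~mask)
        mask = mask.copy()
        mask[rng.choice(off, size=deficit, replace=False)] = True
    return mask


def ga_select(
    x: np.ndarray,
    y: np.ndarray,
    config: GAConfig | None = None,
    wavelengths: np.ndarray | None = None,
) -> SelectionResult:
    """Run the seeded GA and return the best channel subset ever seen."""
    config = config or GAConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n_samples, n_channels = x.shape
    if n_samples != y.size:
        raise ValueError("x rows and y length differ")
    rng = np.random.default_rng(config.seed)
    folds = _cv_folds(n_samples, config)

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = pls_fitness(mask, x, y, config, folds)
        return cache[key]

    # initial population: random masks at the target density + the full mask
    pop = rng.random((config.population_size, n_channels)) < config.init_density
    pop[-1, :] = True
    pop = np.array([_repair(m, config.min_selected, rng) for m in pop])

    best_mask: np.ndarray | None = None
    best_fit = INFEASIBLE
    history = np.empty(config.n_generations)

    for gen in range(config.n_generations):
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        history[gen] = fits[gen_best]

        if gen == config.n_generations - 1:
            break

        order = np.argsort(-fits, kind="stable")
        elite = pop[order[: config.elitism_count]].copy()

        children = []
        while len(children) < config.population_size - config.elitism_count:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, config.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            p1, p2 = parents
            if rng.random() < config.crossover_rate:
                swap = rng.random(n_channels) < 0.5
                c1 = np.where(swap, p2, p1)
                c2 = np.where(swap, p1, p2)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                flip = rng.random(n_channels) < config.mutation_rate
                child = np.logical_xor(child, flip)
                children.append(_repair(child, config.min_selected, rng))
        pop = np.vstack([elite, np.array(children[: config.population_size - config.elitism_count])])

    assert best_mask is not None
    selected = np.flatnonzero(best_mask)
    importance = wavelength_importance(x[:, selected], y, config.pls_components)
    return SelectionResult(
        selected_channels=selected,
        selected_wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[selected],
        best_fitness_per_generation=history,
        importance=importance,
        best_fitness=best_fit,
    )


class GAPLSSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector backed by :func:`ga_select`.

    Fitted attributes
    -----------------
    support_ : boolean mask of selected channels
    result_ : full :class:`SelectionResult` (fitness history, importance)
    """

    def __init__(
        self,
        population_size: int = 100,
        n_generations: int = 50,
        crossover_rate: float = 0.8,
        mutation_rate: float = 0.02,
        elitism_count: int = 2,
        min_selected: int = 5,
        pls_components: int = 8,
        cv_folds: int = 5,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.n_generations = n_generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism_count = elitism_count
        self.min_selected = min_selected
        self.pls_components = pls_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            n_generations=self.n_generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            elitism_count=self.elitism_count,
            min_selected=self.min_selected,
            pls_components=self.pls_components,
            cv_folds=self.cv_folds,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=2)
        self.result_ = ga_select(X, y, self._config())
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.result_.selected_channels] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
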