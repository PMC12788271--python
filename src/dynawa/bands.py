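"""Genetic-algorithm spectral band selection.

A chromosome is a binary mask over wavelength columns; fitness scores a mask
by how well the selected columns explain the target.  Available evaluators:

``lasso`` / ``ridge`` / ``linreg``
    cross-validated R^2 of the named (penalised) linear fit on the selected
    columns;
``corr``
    mean absolute Pearson correlation of selected columns with the target
    (zero-variance columns count as 0);
``mic``
    mean maximal-information-coefficient estimate per selected column, using
    an equipartition grid search bounded by ``n ** 0.6`` cells.

The GA uses roulette-wheel selection, single-point crossover, per-bit flip
mutation and elitism (the best individual always survives, so the best
fitness is non-decreasing across generations).  Reference configuration:
population 135, mutation rate 0.03, crossover rate 0.8, 100 generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import KFold, cross_val_score

from .synthetic import SpectraSet

__all__ = ["GABandConfig", "BandMask", "fitness_score", "ga_select_bands", "mic_estimate"]

FITNESS_NAMES = ("lasso", "ridge", "linreg", "mic", "corr")


@dataclass(frozen=True)
class GABandConfig:
    population_size: int = 135
    chromosome_length: int | None = None  # None -> bound to the wavelength grid
    mutation_rate: float = 0.03
    crossover_rate: float = 0.8
    generations: int = 100
    fitness_name: str = "corr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name, rate in (("mutation_rate", self.mutation_rate),
                           ("crossover_rate", self.crossover_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fitness_name not in FITNESS_NAMES:
            raise ValueError(
                f"unknown fitness '{self.fitness_name}'; choose from {FITNESS_NAMES}"
            )


@dataclass
class BandMask:
    """Binary wavelength-selection mask with its fitness score."""

    mask: np.ndarray
    fitness: float = np.nan

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 1:
            raise ValueError("a band mask must select at least one band")

    def selected_wavelengths(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.asarray(wavelengths)[self.mask]


def mic_estimate(x: np.ndarray, y: np.ndarray, exponent: float = 0.6) -> float:
    """Grid-based approximation of the maximal information coefficient.

    Searches equipartition (quantile) grids of shape (nx, ny) with
    nx * ny <= n ** exponent and returns the maximum of normalised mutual
    information MI / log(min(nx, ny)).  This is the equicharacteristic-grid
    approximation; the exact MIC additionally optimises partition boundaries.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    budget = max(4.0, n ** exponent)
    best = 0.0
    for nx in range(2, int(budget // 2) + 1):
        max_ny = int(budget // nx)
        for ny in range(2, max_ny + 1):
            xb = _quantile_bins(x, nx)
            yb = _quantile_bins(y, ny)
            mi = mutual_info_score(xb, yb)
            norm = np.log(min(len(np.unique(xb)), len(np.unique(yb))))
            if norm > 0:
                best = max(best, mi / norm)
    return float(min(best, 1.0))


def _quantile_bins(v: np.ndarray, k: int) -> np.ndarray:
    edges = np.quantile(v, np.linspace(0, 1, k + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


def fitness_score(
    spectra_set: SpectraSet, mask: BandMask, fitness_name: str, cv: int = 3,
) -> float:
    """Score a band mask; higher is better."""
    if fitness_name not in FITNESS_NAMES:
        raise ValueError(f"unknown fitness '{fitness_name}'")
    X = spectra_set.reflectance[:, mask.mask]
    y = spectra_set.target
    if X.shape[1] < 1:
        raise ValueError("empty band mask")
    if fitness_name == "corr":
        return _mean_abs_corr(X, y)
    if fitness_name == "mic":
        return float(np.mean([mic_estimate(X[:, j], y) for j in range(X.shape[1])]))
    model = {
        "lasso": Lasso(alpha=0.01, max_iter=5000),
        "ridge": Ridge(alpha=1.0),
        "linreg": LinearRegression(),
    }[fitness_name]
    folds = KFold(n_splits=min(cv, len(y)), shuffle=True, random_state=0)
    return float(np.mean(cross_val_score(model, X, y, cv=folds, scoring="r2")))


def _mean_abs_corr(X: np.ndarray, y: np.ndarray) -> float:
    ys = y - y.mean()
    y_norm = np.linalg.norm(ys)
    Xc = X - X.mean(axis=0)
    col_norm = np.linalg.norm(Xc, axis=0)
    r = np.zeros(X.shape[1])
    ok = (col_norm > 0) & (y_norm > 0)  # zero-variance columns score 0
    if ok.any():
        r[ok] = np.abs(Xc[:, ok].T @ ys) / (col_norm[ok] * y_norm)
    return float(r.mean())


def ga_select_bands(
    spectra_set: SpectraSet,
    config: GABandConfig,
    initial_population: np.ndarray | None = None,
) -> BandMask:
    """Evolve band masks and return the best mask ever seen.

    Deterministic for a fixed seed.  Offspring that would select no band are
    repaired by activating one uniformly random bit.  The returned mask's
    diagnostics include the per-generation best-fitness curve via
    ``ga_select_bands.last_fitness_curve`` on the mask (stored as attribute
    ``fitness_curve``).
    """
    if spectra_set.n_samples < 2:
        raise ValueError("need at least 2 samples for band selection")
    length = config.chromosome_length or spectra_set.n_wavelengths
    if length != spectra_set.n_wavelengths:
        raise ValueError(
            f"chromosome_length {length} must match the wavelength grid "
            f"({spectra_set.n_wavelengths})"
        )
    rng = np.random.default_rng(config.seed)
    if initial_population is None:
        pop = rng.random((config.population_size, length)) < 0.5
        for row in pop:
            if not row.any():
                row[rng.integers(length)] = True
    else:
        pop = np.asarray(initial_population, dtype=bool).copy()

    def score(row: np.ndarray) -> float:
        return fitness_score(spectra_set, BandMask(mask=row), config.fitness_name)

    fit = np.array([score(row) for row in pop])
    best_idx = int(np.argmax(fit))
    best_mask, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    curve = [best_fit]

    for _ in range(config.generations):
        shifted = fit - fit.min() + 1e-12
        probs = shifted / shifted.sum()
        parents_idx = rng.choice(len(pop), size=len(pop), p=probs)
        parents = pop[parents_idx]
        children = parents.copy()
        for i in range(0, len(children) - 1, 2):
            if rng.random() < config.crossover_rate and length > 1:
                point = int(rng.integers(1, length))
                children[i, point:], children[i + 1, point:] = (
                    children[i + 1, point:].copy(), children[i, point:].copy(),
                )
        flip = rng.random(children.shape) < config.mutation_rate
        children ^= flip
        for row in children:
            if not row.any():
                row[rng.integers(length)] = True
        children[0] = best_mask  # elitism
        pop = children
        fit = np.array([score(row) for row in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_mask = pop[gen_best].copy()
        curve.append(best_fit)

    result = BandMask(mask=best_mask, fitness=best_fit)
    result.fitness_curve = np.array(curve)  # type: ignore[attr-defined]
    return result
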