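import numpy as np
import pytest

from dynawa.learners import PredictionMatrix, TrainingTrace
from dynawa.synthetic import SimConfig, SpectraSet, simulate


@pytest.fixture(scope="session")
def small_set() -> SpectraSet:
    """60 synthetic samples on a coarse grid — cheap pipeline currency."""
    return simulate(SimConfig(n_samples=60, wavelength_start_nm=400,
                              wavelength_end_nm=2400, step_nm=50, seed=3))


def make_spectra(X: np.ndarray, y: np.ndarray) -> SpectraSet:
    """Wrap an arbitrary feature matrix as a SpectraSet (unit wavelengths)."""
    X = np.atleast_2d(np.asarray(X, float))
    return SpectraSet(wavelengths=np.arange(1.0, X.shape[1] + 1),
                      reflectance=X, target=np.asarray(y, float))


def oracle_matrix(K: int = 5, n: int = 200, seed: int = 0,
                  uninformative: str = "constant"):
    """Learner 1 = y + 1% noise; learners 2..K uninformative.

    ``uninformative`` is either 'constant' (mean predictor) or 'shuffled'
    (a permuted copy of y, accurate marginally but uncorrelated with y).
    """
    rng = np.random.default_rng(seed)
    y = rng.normal(14.85, 6.6, n)
    cols = [y + rng.normal(0, 0.01 * y.std(), n)]
    for _ in range(K - 1):
        if uninformative == "constant":
            cols.append(np.full(n, y.mean()))
        else:
            cols.append(rng.permutation(y))
    P = PredictionMatrix(np.column_stack(cols), [f"L{i}" for i in range(K)],
                         np.arange(n))
    return P, y


def trace_from_matrix(P: PredictionMatrix, y: np.ndarray) -> TrainingTrace:
    """A single-fold trace whose per-learner MAE matches the columns vs y."""
    records = {
        name: {
            "fold_mae": [float(np.mean(np.abs(P.values[:, j] - y)))],
            "fold_mse": [float(np.mean((P.values[:, j] - y) ** 2))],
            "failed": False,
        }
        for j, name in enumerate(P.learner_names)
    }
    return TrainingTrace(records=records, fold_of=np.zeros(len(y), dtype=int))
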