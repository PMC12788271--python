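"""Kennard-Stone calibration/validation partitioning.

The Kennard-Stone algorithm deterministically picks a space-filling
calibration subset: starting from a seed sample it repeatedly adds the
candidate whose minimum Euclidean distance to the already-selected set is
largest (max-min).  The remaining samples form the validation set.  The
default split ratio is 2:1 (validation = floor(n/3)), which partitions 704
samples into 470 calibration and 234 validation samples.

Seed-point convention: the sample whose spectrum is closest to the mean
spectrum.  ``classic_init=True`` instead starts from the two mutually most
distant samples (the textbook initialisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .synthetic import SpectraSet

__all__ = ["SplitResult", "kennard_stone", "split_two_to_one"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation index sets covering all samples."""

    calibration_idx: np.ndarray
    validation_idx: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        cal = set(self.calibration_idx.tolist())
        val = set(self.validation_idx.tolist())
        if cal & val:
            raise ValueError("calibration and validation indices overlap")


def kennard_stone(
    spectra_set: SpectraSet, n_cal: int, classic_init: bool = False
) -> SplitResult:
    """Greedy max-min selection of ``n_cal`` calibration samples.

    Deterministic: distances are Euclidean on the reflectance matrix and
    ties are broken by the lowest sample index.
    """
    n = spectra_set.n_samples
    if not 1 <= n_cal <= n:
        raise ValueError(f"n_cal must be in [1, {n}], got {n_cal}")
    X = spectra_set.reflectance
    dist = cdist(X, X)

    selected: list[int] = []
    if classic_init:
        # textbook start: the two mutually farthest samples
        i, j = np.unravel_index(np.argmax(dist), dist.shape)
        selected = [int(min(i, j))] + ([int(max(i, j))] if n_cal > 1 else [])
    else:
        to_mean = np.linalg.norm(X - X.mean(axis=0), axis=1)
        selected = [int(np.argmin(to_mean))]  # argmin takes the lowest index on ties

    min_dist = dist[:, selected].min(axis=1)
    min_dist[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[:, nxt])
        min_dist[nxt] = -np.inf

    cal = np.array(selected, dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[cal] = False
    val = np.flatnonzero(mask)
    return SplitResult(calibration_idx=cal, validation_idx=val, ratio=n_cal / n)


def split_two_to_one(spectra_set: SpectraSet, classic_init: bool = False) -> SplitResult:
    """Kennard-Stone split at 2:1 — validation = floor(n/3), calibration the rest."""
    n = spectra_set.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for a 2:1 split")
    n_cal = n - n // 3
    return kennard_stone(spectra_set, n_cal, classic_init=classic_init)
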