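"""Spectral preprocessing: band trimming and Savitzky-Golay smoothing.

The working window is the 400-2400 nm core interval (instrument ends and the
water-vapour region beyond 2400 nm are noisy), and smoothing uses an 11-point
window, order-2 Savitzky-Golay filter — a moving local least-squares
polynomial fit that attenuates random noise while preserving the width and
shape of absorption features.  Edges are handled by mirror reflection so the
output length equals the input length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import SpectraSet

__all__ = ["SGConfig", "trim_bands", "sg_smooth"]


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay smoothing parameters (defaults: 11-point window, order 2)."""

    window_points: int = 11
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points % 2 != 1:
            raise ValueError("window_points must be odd")
        if self.poly_order >= self.window_points:
            raise ValueError("window_points must exceed poly_order")


def trim_bands(spectra_set: SpectraSet, low_nm: float, high_nm: float) -> SpectraSet:
    """Keep only wavelengths in the closed interval [low_nm, high_nm].

    Column order is preserved and the target is untouched.  Raises
    ``ValueError`` if the interval misses the grid entirely.
    """
    if not low_nm < high_nm:
        raise ValueError("low_nm must be < high_nm")
    keep = (spectra_set.wavelengths >= low_nm) & (spectra_set.wavelengths <= high_nm)
    if not keep.any():
        raise ValueError(
            f"trim window [{low_nm}, {high_nm}] nm does not intersect the "
            f"grid [{spectra_set.wavelengths[0]}, {spectra_set.wavelengths[-1]}] nm"
        )
    return SpectraSet(
        wavelengths=spectra_set.wavelengths[keep],
        reflectance=spectra_set.reflectance[:, keep],
        target=spectra_set.target.copy(),
        sample_ids=list(spectra_set.sample_ids),
    )


def sg_smooth(spectra_set: SpectraSet, config: SGConfig | None = None) -> SpectraSet:
    """Savitzky-Golay smooth every spectrum row; shape is unchanged.

    Mirror-reflect padding at both ends avoids edge shrinkage.  A filter of
    order p reproduces any degree-<=p polynomial exactly at interior points.
    """
    config = config or SGConfig()
    if spectra_set.n_wavelengths < config.window_points:
        raise ValueError(
            f"window of {config.window_points} points exceeds spectrum length "
            f"{spectra_set.n_wavelengths}"
        )
    smoothed = savgol_filter(
        spectra_set.reflectance,
        window_length=config.window_points,
        polyorder=config.poly_order,
        axis=1,
        mode="mirror",
    )
    return SpectraSet(
        wavelengths=spectra_set.wavelengths.copy(),
        reflectance=smoothed,
        target=spectra_set.target.copy(),
        sample_ids=list(spectra_set.sample_ids),
    )
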