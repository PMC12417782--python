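"""Spectral harmonisation: grid interpolation + standard normal variate.

Spectra from different spectrometers live on different wavenumber grids and
intensity scales.  Harmonisation is two steps only — piecewise-linear
interpolation onto a common grid, then per-spectrum SNV — deliberately
avoiding classic preprocessing such as baseline correction or smoothing,
which the convolutional model is expected to learn itself.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .spectra import Spectrum, make_axis, default_profile

__all__ = ["PreprocConfig", "interpolate_to_grid", "snv", "harmonize"]


class PreprocConfig(BaseModel):
    """Target grid and SNV guard; the default grid is the primary instrument's."""

    target_grid: tuple[float, ...] = ()
    snv_epsilon: float = Field(1e-8, gt=0)
    out_of_range: Literal["clip-to-edge", "zero-fill"] = "clip-to-edge"

    @model_validator(mode="after")
    def _check(self) -> "PreprocConfig":
        if not self.target_grid:
            object.__setattr__(self, "target_grid", tuple(make_axis(default_profile())))
        grid = np.asarray(self.target_grid)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("target grid must be strictly increasing with >= 2 points")
        return self

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.target_grid, dtype=float)


def interpolate_to_grid(
    spectrum: Spectrum | tuple[np.ndarray, np.ndarray],
    target_grid: np.ndarray,
    policy: str = "clip-to-edge",
) -> np.ndarray:
    """Piecewise-linear resampling of one spectrum onto ``target_grid``."""
    if isinstance(spectrum, Spectrum):
        wn, y = spectrum.wavenumbers, spectrum.intensities
    else:
        wn, y = (np.asarray(a, dtype=float) for a in spectrum)
    if wn.size < 2:
        raise ValueError("need at least 2 source points to interpolate")
    if np.any(np.diff(wn) <= 0):
        raise ValueError("source axis must be strictly increasing")
    target_grid = np.asarray(target_grid, dtype=float)
    if policy == "clip-to-edge":
        return np.interp(target_grid, wn, y)
    if policy == "zero-fill":
        return np.interp(target_grid, wn, y, left=0.0, right=0.0)
    raise ValueError(f"unknown out-of-range policy: {policy!r}")


def snv(intensities: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Standard normal variate: (x - mean) / max(population std, epsilon).

    Works on a single spectrum (1-D) or row-wise on a matrix (2-D).
    """
    x = np.asarray(intensities, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 points")
    mean = x.mean(axis=-1, keepdims=True)
    std = np.maximum(x.std(axis=-1, keepdims=True), epsilon)
    return (x - mean) / std


def harmonize(
    spectra: Sequence[Spectrum],
    config: PreprocConfig | None = None,
    apply_snv: bool = True,
) -> np.ndarray:
    """Interpolate all spectra to the config grid; optionally SNV row-wise."""
    config = config or PreprocConfig()
    grid = config.grid
    x = np.stack([interpolate_to_grid(s, grid, config.out_of_range) for s in spectra])
    return snv(x, config.snv_epsilon) if apply_snv else x
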