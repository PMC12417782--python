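"""Training-time spectral augmentation: MixUp plus baseline/slope jitter.

MixUp forms convex combinations of spectrum pairs and their labels with
lambda ~ Beta(alpha, alpha); the shape augmentation adds a random constant
offset and a random linear tilt around the grid midpoint, emulating
fluorescence-baseline and instrument-slope variation without touching the
labels.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

__all__ = ["AugmentConfig", "mixup", "mixup_batch", "augment_shape"]


class AugmentConfig(BaseModel):
    mixup_alpha: float = Field(0.2, gt=0)
    baseline_range: tuple[float, float] = (-0.3, 0.3)  # SNV units
    slope_range: tuple[float, float] = (-2e-4, 2e-4)  # SNV units per cm^-1
    probability: float = Field(0.5, ge=0, le=1)


def mixup(spectrum_a, labels_a, spectrum_b, labels_b, lam: float):
    """lam * a + (1 - lam) * b applied to intensities and labels alike."""
    xa, xb = np.asarray(spectrum_a, dtype=float), np.asarray(spectrum_b, dtype=float)
    ya, yb = np.asarray(labels_a, dtype=float), np.asarray(labels_b, dtype=float)
    if xa.shape != xb.shape or ya.shape != yb.shape:
        raise ValueError("mixup inputs must have matching shapes")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    return lam * xa + (1.0 - lam) * xb, lam * ya + (1.0 - lam) * yb


def mixup_batch(x: np.ndarray, y: np.ndarray, alpha: float, rng: np.random.Generator):
    """Within-batch MixUp: pair rows by a random permutation, one lambda per row."""
    perm = rng.permutation(x.shape[0])
    lam = rng.beta(alpha, alpha, size=(x.shape[0], 1))
    return lam * x + (1 - lam) * x[perm], lam * y + (1 - lam) * y[perm]


def augment_shape(
    intensities: np.ndarray,
    wavenumbers: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Add c + m * (wn - wn_mid) with c, m drawn from the configured ranges.

    Accepts a single spectrum or a batch (rows); labels are untouched by
    construction.  Reproducible for a fixed seed.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(intensities, dtype=float)
    wn = np.asarray(wavenumbers, dtype=float)
    wn_mid = 0.5 * (wn[0] + wn[-1])
    batch = x.ndim == 2
    n = x.shape[0] if batch else 1
    c = gen.uniform(*config.baseline_range, size=(n, 1))
    m = gen.uniform(*config.slope_range, size=(n, 1))
    tilt = c + m * (wn - wn_mid)[None, :]
    return x + tilt if batch else x + tilt[0]
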