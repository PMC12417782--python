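"""Concentration trajectories of E. coli batch / glucose-limited fed-batch runs.

Monod growth on glucose with acetate overflow during the batch phase, a low
residual glucose set-point during feeding, slow acetate re-consumption, an
exponentially decaying ethanol background (needle-disinfectant carry-over)
and a slowly declining MgSO4 cofactor level.  The dynamics are deliberately
simple: their role is to span realistic concentration ranges and temporal
correlation for the chemometrics benchmark, not to be a process model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

__all__ = ["FermentationParams", "FermentationProfile", "simulate_fermentation"]


class FermentationParams(BaseModel):
    """Growth and feed settings; defaults give ~4 h batch + ~4 h fed-batch."""

    glucose_0: float = Field(5.0, ge=0)  # g/L
    biomass_0: float = Field(0.15, gt=0)  # g/L
    acetate_0: float = Field(0.0, ge=0)
    ethanol_0: float = Field(2.0, ge=0)
    mgso4_0: float = Field(2.0, ge=0)
    mu_max: float = Field(0.7, gt=0)  # 1/h
    k_s: float = Field(0.05, gt=0)  # g/L, Monod half-saturation
    yield_xs: float = Field(0.45, gt=0)  # gX/gS
    acetate_yield: float = Field(0.25, ge=0)  # g acetate per g glucose (batch overflow)
    acetate_uptake: float = Field(0.15, ge=0)  # 1/h per g/L biomass, fed-batch
    ethanol_decay: float = Field(0.35, ge=0)  # 1/h
    mgso4_decay: float = Field(0.025, ge=0)  # 1/h
    glucose_residual: float = Field(0.1, ge=0)  # g/L set-point during feeding
    t_batch: float = Field(4.0, gt=0)  # h
    t_feed: float = Field(4.0, ge=0)  # h
    dt: float = Field(0.01, gt=0)  # h, Euler step
    jitter: float = Field(0.1, ge=0)  # relative lognormal spread across runs


@dataclass
class FermentationProfile:
    times: np.ndarray  # hours
    concentrations: dict[str, np.ndarray]  # per-analyte g/L
    phases: np.ndarray  # "batch" | "fed-batch" per time point

    def at(self, t: float) -> dict[str, float]:
        """Linear interpolation of every analyte at time ``t`` (hours)."""
        return {
            name: float(np.interp(t, self.times, traj))
            for name, traj in self.concentrations.items()
        }


def simulate_fermentation(
    params: FermentationParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> FermentationProfile:
    """Integrate one run; a seeded rng jitters initial values between runs."""
    p = params or FermentationParams()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def jit(x: float) -> float:
        if p.jitter == 0 or x == 0:
            return x
        return float(x * gen.lognormal(0.0, p.jitter))

    glc, bio = jit(p.glucose_0), jit(p.biomass_0)
    ace, eth, mgs = jit(p.acetate_0), jit(p.ethanol_0), jit(p.mgso4_0)

    n = int(round((p.t_batch + p.t_feed) / p.dt)) + 1
    times = np.arange(n) * p.dt
    out = {k: np.empty(n) for k in ("glucose", "acetate", "ethanol", "mgso4", "biomass")}
    phases = np.where(times < p.t_batch, "batch", "fed-batch")

    for i, t in enumerate(times):
        for key, val in (("glucose", glc), ("acetate", ace), ("ethanol", eth),
                         ("mgso4", mgs), ("biomass", bio)):
            out[key][i] = val
        in_batch = t < p.t_batch
        if in_batch:
            mu = p.mu_max * glc / (p.k_s + glc)
            uptake = mu * bio / p.yield_xs
            glc = max(glc - uptake * p.dt, 0.0)
            ace += p.acetate_yield * uptake * p.dt
            bio += mu * bio * p.dt
        else:
            # Feeding holds glucose near the residual set-point; growth is
            # substrate-limited and acetate is slowly re-consumed.
            glc = glc + (p.glucose_residual - glc) * min(1.0, 2.0 * p.dt)
            mu = p.mu_max * glc / (p.k_s + glc)
            bio += mu * bio * p.dt
            ace = max(ace - p.acetate_uptake * bio * ace / (0.5 + ace) * p.dt, 0.0)
        eth = max(eth - p.ethanol_decay * eth * p.dt, 0.0)
        mgs = max(mgs - p.mgso4_decay * mgs * p.dt, 0.0)

    return FermentationProfile(times, out, phases)
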