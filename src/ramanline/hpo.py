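"""Hyperparameter search: Hyperband-style successive halving.

Configurations are sampled from a search space, evaluated at the smallest
budget, and the best 1/eta survive to the next budget rung.  Proposals are
model-based once enough trials have completed — a random-forest surrogate
ranks random candidates by predicted validation loss — and fall back to
plain random sampling while the history is short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from pydantic import BaseModel, Field, model_validator
from sklearn.ensemble import RandomForestRegressor

__all__ = ["HPOConfig", "Trial", "survivor_counts", "hyperband_search"]

#: search-space entry: ("uniform", lo, hi) | ("log_uniform", lo, hi) | ("choice", [..])
SearchSpace = Mapping[str, tuple]


class HPOConfig(BaseModel):
    eta: float = Field(3.0, gt=1)
    budgets: tuple[float, ...] = (1.0, 3.0, 9.0)
    n_configs: int = Field(9, ge=1)
    proposal: str = "model-based"  # or "random"
    min_history_for_model: int = Field(10, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "HPOConfig":
        if any(b2 <= b1 for b1, b2 in zip(self.budgets, self.budgets[1:])):
            raise ValueError("budgets must be strictly increasing")
        return self


@dataclass
class Trial:
    config: dict
    budget: float
    loss: float


@dataclass
class SearchResult:
    best_config: dict
    best_loss: float
    trials: list[Trial] = field(default_factory=list)

    def survivors_per_rung(self) -> list[int]:
        rungs = sorted({t.budget for t in self.trials})
        return [sum(1 for t in self.trials if t.budget == b) for b in rungs]


def survivor_counts(n_configs: int, eta: float, n_rungs: int) -> list[int]:
    """Successive-halving ladder sizes, e.g. 9 -> 3 -> 1 at eta = 3."""
    counts = [n_configs]
    for _ in range(n_rungs - 1):
        counts.append(max(1, math.ceil(counts[-1] / eta)))
    return counts


def _sample_config(space: SearchSpace, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "log_uniform":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "choice":
            out[name] = spec[1][int(rng.integers(len(spec[1])))]
        else:
            raise ValueError(f"unknown search-space entry kind: {kind!r}")
    return out


def _encode(config: dict, space: SearchSpace) -> list[float]:
    row = []
    for name, spec in space.items():
        v = config[name]
        if spec[0] == "choice":
            row.append(float(spec[1].index(v)))
        else:
            row.append(float(v))
    return row


def _propose(
    space: SearchSpace,
    history: list[Trial],
    cfg: HPOConfig,
    rng: np.random.Generator,
) -> dict:
    if cfg.proposal != "model-based" or len(history) < cfg.min_history_for_model:
        return _sample_config(space, rng)
    x = np.asarray([_encode(t.config, space) for t in history])
    y = np.asarray([t.loss for t in history])
    surrogate = RandomForestRegressor(n_estimators=30, random_state=int(rng.integers(2**31)))
    surrogate.fit(x, y)
    candidates = [_sample_config(space, rng) for _ in range(64)]
    scores = surrogate.predict(np.asarray([_encode(c, space) for c in candidates]))
    return candidates[int(np.argmin(scores))]


def hyperband_search(
    space: SearchSpace,
    hpo_cfg: HPOConfig,
    train_fn: Callable[[dict, float], float],
    rng: np.random.Generator | int | None = 0,
) -> SearchResult:
    """Run one successive-halving bracket; return the max-budget winner.

    ``train_fn(config, budget) -> validation loss``; lower is better.
    Deterministic given a seed and a deterministic ``train_fn``.
    """
    if not space:
        raise ValueError("empty search space")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    trials: list[Trial] = []
    configs = []
    for _ in range(hpo_cfg.n_configs):
        configs.append(_propose(space, trials, hpo_cfg, gen))
    active = configs
    last_scores: list[tuple[float, dict]] = []
    for rung, budget in enumerate(hpo_cfg.budgets):
        scored = []
        for config in active:
            loss = float(train_fn(config, budget))
            trials.append(Trial(config, budget, loss))
            scored.append((loss, config))
        scored.sort(key=lambda t: t[0])
        last_scores = scored
        if rung + 1 < len(hpo_cfg.budgets):
            keep = max(1, math.ceil(len(scored) / hpo_cfg.eta))
            active = [c for _, c in scored[:keep]]
    best_loss, best_config = last_scores[0]
    return SearchResult(best_config, best_loss, trials)
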