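"""Experiment-wise splitting, MAE evaluation and the end-to-end benchmark.

Spectra from one fermentation experiment are strongly correlated, so the
train/validation/test partition is drawn at the experiment level (default
8/8/8 of 24 experiments) and split hygiene — no experiment id in two
partitions — is asserted on every build.  Test MAE is reported per analyte
in g/L on the original scale, with one prediction per sample (the mean over
its replicate spectra).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .augment import AugmentConfig
from .datasets import SpectraDataset, TARGET_ANALYTES, make_dataset
from .hpo import HPOConfig, hyperband_search
from .model import RamanCNNRegressor
from .nn import CNNConfig, TrainConfig
from .preprocess import PreprocConfig

__all__ = [
    "SplitSpec",
    "split_experiments",
    "evaluate_mae",
    "BenchmarkSettings",
    "run_benchmark",
]


class SplitSpec(BaseModel):
    n_train: int = Field(8, ge=1)
    n_val: int = Field(8, ge=0)
    n_test: int = Field(8, ge=1)
    use_auxiliary: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SplitSpec":
        return self


def split_experiments(
    experiment_ids: list[str],
    spec: SplitSpec | None = None,
    rng: np.random.Generator | int | None = 0,
) -> dict[str, list[str]]:
    """Random disjoint experiment-level partition; raises if ids run short."""
    spec = spec or SplitSpec()
    need = spec.n_train + spec.n_val + spec.n_test
    ids = sorted(set(experiment_ids))
    if len(ids) < need:
        raise ValueError(f"need {need} experiments, have {len(ids)}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    order = list(gen.permutation(ids))
    parts = {
        "train": sorted(order[: spec.n_train]),
        "val": sorted(order[spec.n_train : spec.n_train + spec.n_val]),
        "test": sorted(order[spec.n_train + spec.n_val : need]),
    }
    assert not (set(parts["train"]) & set(parts["val"]) | set(parts["train"]) & set(parts["test"])
                | set(parts["val"]) & set(parts["test"])), "split hygiene violated"
    return parts


def evaluate_mae(
    estimator,
    test_set: SpectraDataset,
    analytes=TARGET_ANALYTES,
) -> dict[str, float]:
    """Per-analyte mean absolute error (g/L), one prediction per sample."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    pred = estimator.predict_dataset(test_set)
    frame = test_set.labels.copy()
    for j, a in enumerate(analytes):
        frame[f"pred_{a}"] = pred[:, j]
    per_sample = frame.groupby("sample_id", sort=False).mean(numeric_only=True)
    return {
        a: float(np.mean(np.abs(per_sample[f"pred_{a}"] - per_sample[a])))
        for a in analytes
    }


class BenchmarkSettings(BaseModel):
    """Default synthetic benchmark: 24 fermentations split 8/8/8 plus an
    auxiliary multi-instrument mixture corpus folded into training.

    The reduced problem sizes (auxiliary spectra count, epoch budgets) keep
    the full tune + train + evaluate loop tractable on a single CPU while
    preserving the structure: multi-instrument harmonisation, experiment-wise
    splitting, Hyperband tuning, held-out MAE.
    """

    n_experiments: int = 24
    samples_per_experiment: int = 9
    spectra_per_sample: int = 2
    aux_instruments: int = 8
    aux_experiments: int = 40
    aux_samples_per_experiment: int = 15
    aux_spectra_per_sample: int = 1
    grid_points: int = 1024
    final_epochs: int = 100
    hpo_epochs: tuple[float, ...] = (3.0, 6.0, 12.0)
    hpo_configs: int = 9
    run_hpo: bool = True


def _analyte_ranges(dataset: SpectraDataset, analytes=TARGET_ANALYTES) -> dict[str, float]:
    return {
        a: float(dataset.labels[a].max() - dataset.labels[a].min())
        for a in analytes
    }


def run_benchmark(
    seed: int = 0,
    settings: BenchmarkSettings | None = None,
) -> dict:
    """Generate data, tune, train and evaluate; returns a metrics report.

    Deterministic given ``seed``: dataset generation, the split, Hyperband
    and training all derive their randomness from it.
    """
    s = settings or BenchmarkSettings()
    master = np.random.default_rng(seed)
    data_seed, split_seed, hpo_seed, train_seed = (int(master.integers(2**31)) for _ in range(4))

    ferm = make_dataset(
        n_experiments=s.n_experiments,
        samples_per_experiment=s.samples_per_experiment,
        n_instruments=1,
        rng_seed=data_seed,
        spectra_per_sample=s.spectra_per_sample,
        mode="fermentation",
    )
    aux = make_dataset(
        n_experiments=s.aux_experiments,
        samples_per_experiment=s.aux_samples_per_experiment,
        n_instruments=s.aux_instruments,
        rng_seed=data_seed + 1,
        spectra_per_sample=s.aux_spectra_per_sample,
        mode="mixture",
    )
    parts = split_experiments(ferm.experiment_ids, SplitSpec(), split_seed)
    train_set = ferm.subset(parts["train"]).concat(aux)
    val_set = ferm.subset(parts["val"])
    test_set = ferm.subset(parts["test"])

    grid = np.linspace(65.0, 3350.0, s.grid_points)
    preproc = PreprocConfig(target_grid=tuple(grid))

    def make_estimator(config: dict, epochs: int) -> RamanCNNRegressor:
        return RamanCNNRegressor(
            cnn_config=CNNConfig(
                base_channels=int(config.get("base_channels", 16)),
                kernel_size=int(config.get("kernel_size", 7)),
            ),
            train_config=TrainConfig(
                peak_lr=float(config.get("peak_lr", 1e-2)),
                weight_decay=float(config.get("weight_decay", 1e-4)),
                warmup_epochs=min(20, max(1, epochs // 5)),
                gamma=0.98,
                epochs=epochs,
                batch_size=int(config.get("batch_size", 32)),
                seed=train_seed,
            ),
            augment_config=AugmentConfig(mixup_alpha=float(config.get("mixup_alpha", 0.2))),
            preproc_config=preproc,
        )

    best_config: dict = {}
    hpo_result = None
    if s.run_hpo:
        space = {
            "peak_lr": ("log_uniform", 2e-3, 2e-2),
            "weight_decay": ("log_uniform", 1e-6, 1e-3),
            "base_channels": ("choice", [8, 16]),
            "kernel_size": ("choice", [5, 7, 9]),
            "mixup_alpha": ("log_uniform", 0.1, 0.4),
            "batch_size": ("choice", [32, 64]),
        }

        def train_fn(config: dict, budget: float) -> float:
            est = make_estimator(config, int(round(budget)))
            est.fit(train_set, val_set)
            return est.validation_loss

        hpo_result = hyperband_search(
            space,
            HPOConfig(budgets=s.hpo_epochs, n_configs=s.hpo_configs),
            train_fn,
            rng=hpo_seed,
        )
        best_config = hpo_result.best_config

    estimator = make_estimator(best_config, s.final_epochs)
    estimator.fit(train_set, val_set)
    mae = evaluate_mae(estimator, test_set)
    ranges = _analyte_ranges(ferm)
    report = {
        "mae_g_per_l": mae,
        "range_g_per_l": ranges,
        "mae_pct_of_range": {a: 100.0 * mae[a] / ranges[a] for a in mae},
        "n_train_spectra": len(train_set),
        "n_val_spectra": len(val_set),
        "n_test_spectra": len(test_set),
        "n_experiments": s.n_experiments,
        "split": parts,
        "best_config": best_config,
        "final_val_loss": estimator.validation_loss,
    }
    report["_estimator"] = estimator
    return report
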