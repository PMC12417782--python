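"""High-level concentration regressor: harmonisation + CNN + target scaling.

`RamanCNNRegressor` is the user-facing estimator: it harmonises raw spectra
(interpolation to the primary grid + SNV), z-scores the targets on the
training set, trains the NumPy CNN, and de-standardises predictions back to
g/L.  It satisfies the orchestrator's estimator contract (``predict`` on a
sample's spectra returns per-analyte g/L, averaging over the sample's
replicate spectra).
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from .augment import AugmentConfig
from .datasets import SpectraDataset, TARGET_ANALYTES
from .nn import (
    CNNConfig,
    RamanCNN,
    TrainConfig,
    TrainingHistory,
    predict_in_batches,
    train,
)
from .preprocess import PreprocConfig, harmonize
from .spectra import Spectrum

__all__ = ["RamanCNNRegressor"]


class RamanCNNRegressor:
    def __init__(
        self,
        cnn_config: CNNConfig | None = None,
        train_config: TrainConfig | None = None,
        augment_config: AugmentConfig | None = None,
        preproc_config: PreprocConfig | None = None,
        analytes: Sequence[str] = TARGET_ANALYTES,
    ) -> None:
        self.cnn_config = cnn_config or CNNConfig(n_targets=len(analytes))
        self.train_config = train_config or TrainConfig()
        self.augment_config = augment_config or AugmentConfig()
        self.preproc_config = preproc_config or PreprocConfig()
        self.analytes = tuple(analytes)
        self.model: RamanCNN | None = None
        self.history: TrainingHistory | None = None
        self.y_mean: np.ndarray | None = None
        self.y_std: np.ndarray | None = None

    # -- data plumbing -------------------------------------------------
    def _design(self, dataset: SpectraDataset) -> tuple[np.ndarray, np.ndarray]:
        x = harmonize(dataset.spectra, self.preproc_config)
        y = dataset.targets(self.analytes)
        return x, y

    def _scale(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_std

    def _unscale(self, z: np.ndarray) -> np.ndarray:
        return z * self.y_std + self.y_mean

    # -- fitting -------------------------------------------------------
    def fit(self, train_set: SpectraDataset, val_set: SpectraDataset | None = None) -> "RamanCNNRegressor":
        if len(train_set) == 0:
            raise ValueError("empty training set")
        if val_set is not None:
            overlap = set(train_set.experiment_ids) & set(val_set.experiment_ids)
            if overlap:
                raise ValueError(f"experiments span train and validation: {sorted(overlap)}")
        x_tr, y_tr = self._design(train_set)
        self.y_mean = y_tr.mean(axis=0)
        self.y_std = np.maximum(y_tr.std(axis=0), 1e-9)
        x_val = y_val = None
        if val_set is not None and len(val_set):
            x_val, y_val = self._design(val_set)
            y_val = self._scale(y_val)
        self.model = RamanCNN(self.cnn_config, rng=self.train_config.seed)
        self.history = train(
            self.model, x_tr, self._scale(y_tr), x_val, y_val,
            self.train_config, self.augment_config,
            wavenumbers=self.preproc_config.grid,
        )
        return self

    # -- prediction ----------------------------------------------------
    def predict_matrix(self, x: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit the model first")
        return self._unscale(predict_in_batches(self.model, x))

    def predict_dataset(self, dataset: SpectraDataset) -> np.ndarray:
        x = harmonize(dataset.spectra, self.preproc_config)
        return self.predict_matrix(x)

    def predict(self, spectra: Sequence[Spectrum]) -> dict[str, float]:
        """Per-analyte g/L for one sample: mean over its replicate spectra."""
        x = harmonize(list(spectra), self.preproc_config)
        pred = self.predict_matrix(x).mean(axis=0)
        return dict(zip(self.analytes, map(float, pred)))

    @property
    def validation_loss(self) -> float:
        """Validation MSE of the model as fitted (best epoch when restored)."""
        if not self.history or not self.history.val_loss:
            raise RuntimeError("no validation history")
        if self.history.best_epoch is not None:
            return self.history.val_loss[self.history.best_epoch]
        return self.history.val_loss[-1]

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        if self.model is None:
            raise RuntimeError("nothing to save: fit the model first")
        meta = {
            "cnn_config": self.cnn_config.model_dump(),
            "train_config": self.train_config.model_dump(),
            "augment_config": self.augment_config.model_dump(),
            "preproc_config": self.preproc_config.model_dump(),
            "analytes": list(self.analytes),
            "history": {
                "train_loss": self.history.train_loss if self.history else [],
                "val_loss": self.history.val_loss if self.history else [],
            },
        }
        np.savez(
            path,
            __meta__=json.dumps(meta),
            __y_mean__=self.y_mean,
            __y_std__=self.y_std,
            **self.model.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "RamanCNNRegressor":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        est = cls(
            CNNConfig(**meta["cnn_config"]),
            TrainConfig(**meta["train_config"]),
            AugmentConfig(**meta["augment_config"]),
            PreprocConfig(**meta["preproc_config"]),
            meta["analytes"],
        )
        est.model = RamanCNN(est.cnn_config, rng=0)
        reserved = {"__meta__", "__y_mean__", "__y_std__"}
        est.model.load_state_dict({k: data[k] for k in data.files if k not in reserved})
        est.y_mean = data["__y_mean__"]
        est.y_std = data["__y_std__"]
        est.history = TrainingHistory(
            train_loss=list(meta["history"]["train_loss"]),
            val_loss=list(meta["history"]["val_loss"]),
        )
        return est
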