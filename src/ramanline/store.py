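"""File-backed experiment store standing in for the database service.

A directory of plain-text tables: JSONL records for experiments, samples,
spectra metadata, predictions and models, with spectrum arrays in per-
experiment wide CSV files.  Records are validated before writing, ids are
stamped on acceptance, and nothing is ever mutated in place (append-only);
the API surface — experiment management, spectra storage and export, sample
annotation, prediction persistence, model persistence — is kept as an
interface a relational backend could implement instead.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = ["ExperimentStore", "ValidationError", "IntegrityError"]


class ValidationError(ValueError):
    pass


class IntegrityError(RuntimeError):
    pass


REQUIRED_META = ("experiment_id", "sample_id", "channel", "timestamp")


class ExperimentStore:
    def __init__(self, root) -> None:
        self.root = Path(root)
        (self.root / "spectra").mkdir(parents=True, exist_ok=True)
        (self.root / "models").mkdir(exist_ok=True)
        for table in ("experiments", "samples", "spectra_index", "predictions", "models_index", "events"):
            path = self._table(table)
            if not path.exists():
                path.touch()

    def _table(self, name: str) -> Path:
        return self.root / f"{name}.jsonl"

    def _read(self, name: str) -> list[dict]:
        with open(self._table(name)) as fh:
            return [json.loads(line) for line in fh if line.strip()]

    def _append(self, name: str, record: dict) -> None:
        with open(self._table(name), "a") as fh:
            fh.write(json.dumps(record, default=str) + "\n")

    def _log(self, event: str, **info) -> None:
        self._append("events", {"event": event, "at": time.time(), **info})

    # -- spectra -------------------------------------------------------
    def _validate_spectrum(self, s: Spectrum) -> list[str]:
        problems = []
        if np.any(np.diff(s.wavenumbers) <= 0):
            problems.append("wavenumbers")
        for key in REQUIRED_META:
            if key not in s.meta:
                problems.append(f"meta.{key}")
        return problems

    def put_spectra(self, records: list[Spectrum]) -> list[str]:
        """Validate-then-write; duplicates (sample, channel, timestamp) conflict."""
        if not records:
            return []
        index = self._read("spectra_index")
        seen = {(r["sample_id"], r["channel"], r["timestamp"]) for r in index}
        for s in records:
            problems = self._validate_spectrum(s)
            if problems:
                raise ValidationError(f"invalid spectrum record; offending fields: {problems}")
            key = (s.meta["sample_id"], s.meta["channel"], s.meta["timestamp"])
            if key in seen:
                raise ValidationError(f"duplicate spectrum for {key}")
            seen.add(key)
        known_samples = {r["sample_id"] for r in self._read("samples")}
        known_experiments = {r["experiment_id"] for r in self._read("experiments")}
        ids = []
        next_id = len(index)
        for s in records:
            exp, sample = s.meta["experiment_id"], s.meta["sample_id"]
            if exp not in known_experiments:
                self._append("experiments", {"experiment_id": exp})
                known_experiments.add(exp)
            if sample not in known_samples:
                self._append("samples", {"sample_id": sample, "experiment_id": exp,
                                         **{k: v for k, v in s.meta.items()
                                            if k not in ("experiment_id", "sample_id")}})
                known_samples.add(sample)
            sid = f"sp-{next_id:06d}"
            next_id += 1
            csv_path = self.root / "spectra" / f"{sid}.csv"
            pd.DataFrame({"wavenumber": s.wavenumbers, "intensity": s.intensities}).to_csv(
                csv_path, index=False)
            self._append("spectra_index", {
                "spectrum_id": sid,
                "experiment_id": exp,
                "sample_id": sample,
                "channel": s.meta["channel"],
                "timestamp": s.meta["timestamp"],
                "meta": {k: v for k, v in s.meta.items()},
                "path": str(csv_path.relative_to(self.root)),
            })
            ids.append(sid)
        self._log("put_spectra", n=len(ids))
        return ids

    def get_spectra(self, experiment_id: str | None = None, sample_id: str | None = None) -> list[Spectrum]:
        out = []
        for rec in self._read("spectra_index"):
            if experiment_id is not None and rec["experiment_id"] != experiment_id:
                continue
            if sample_id is not None and rec["sample_id"] != sample_id:
                continue
            frame = pd.read_csv(self.root / rec["path"])
            out.append(Spectrum(frame["wavenumber"].to_numpy(),
                                frame["intensity"].to_numpy(), dict(rec["meta"])))
        return out

    # -- predictions ---------------------------------------------------
    def put_model(self, model_id: str, description: str = "", path: str | None = None) -> str:
        self._append("models_index", {"model_id": model_id, "description": description,
                                      "path": path, "at": time.time()})
        self._log("put_model", model_id=model_id)
        return model_id

    def put_predictions(self, sample_id: str, model_id: str, values: dict,
                        spectrum_ids: list[str] | None = None) -> str:
        samples = {r["sample_id"] for r in self._read("samples")}
        if sample_id not in samples:
            raise IntegrityError(f"unknown sample: {sample_id}")
        models = {r["model_id"] for r in self._read("models_index")}
        if model_id not in models:
            raise IntegrityError(f"unknown model: {model_id}")
        if spectrum_ids:
            known = {r["spectrum_id"] for r in self._read("spectra_index")}
            missing = set(spectrum_ids) - known
            if missing:
                raise IntegrityError(f"unknown spectra: {sorted(missing)}")
        pid = f"pred-{len(self._read('predictions')):06d}"
        self._append("predictions", {
            "prediction_id": pid, "sample_id": sample_id, "model_id": model_id,
            "values": {k: float(v) for k, v in values.items()},
            "spectrum_ids": spectrum_ids or [], "at": time.time(),
        })
        self._log("put_predictions", prediction_id=pid)
        return pid

    def get_predictions(self, sample_id: str | None = None, experiment_id: str | None = None) -> list[dict]:
        sample_to_exp = {r["sample_id"]: r["experiment_id"] for r in self._read("samples")}
        out = []
        for rec in self._read("predictions"):
            if sample_id is not None and rec["sample_id"] != sample_id:
                continue
            if experiment_id is not None and sample_to_exp.get(rec["sample_id"]) != experiment_id:
                continue
            out.append(rec)
        return out

    # -- export --------------------------------------------------------
    def export_experiment(self, experiment_id: str, out_dir, format: str = "csv") -> dict[str, Path]:
        experiments = {r["experiment_id"] for r in self._read("experiments")}
        if experiment_id not in experiments:
            raise KeyError(f"unknown experiment: {experiment_id}")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        spectra = self.get_spectra(experiment_id=experiment_id)
        files: dict[str, Path] = {}
        meta_path = out_dir / f"{experiment_id}_meta.jsonl"
        with open(meta_path, "w") as fh:
            for s in spectra:
                fh.write(json.dumps(s.meta, default=str) + "\n")
        files["metadata"] = meta_path
        if format == "csv":
            data_path = out_dir / f"{experiment_id}_spectra.csv"
            if spectra:
                frame = pd.DataFrame({"wavenumber": spectra[0].wavenumbers})
                for i, s in enumerate(spectra):
                    frame[f"spectrum_{i}"] = s.intensities
            else:
                frame = pd.DataFrame({"wavenumber": []})
            frame.to_csv(data_path, index=False)
        elif format == "hdf":
            import h5py

            data_path = out_dir / f"{experiment_id}_spectra.h5"
            with h5py.File(data_path, "w") as h5:
                for i, s in enumerate(spectra):
                    grp = h5.create_group(f"spectrum_{i}")
                    grp.create_dataset("wavenumber", data=s.wavenumbers)
                    grp.create_dataset("intensity", data=s.intensities)
        else:
            raise ValueError(f"unknown export format: {format!r}")
        files["spectra"] = data_path
        pred_path = out_dir / f"{experiment_id}_predictions.csv"
        preds = self.get_predictions(experiment_id=experiment_id)
        rows = [{"sample_id": p["sample_id"], "model_id": p["model_id"], **p["values"]}
                for p in preds]
        pd.DataFrame(rows).to_csv(pred_path, index=False)
        files["predictions"] = pred_path
        self._log("export_experiment", experiment_id=experiment_id, format=format)
        return files

    def import_experiment(self, spectra_csv, meta_jsonl) -> list[str]:
        frame = pd.read_csv(spectra_csv)
        metas = []
        with open(meta_jsonl) as fh:
            metas = [json.loads(line) for line in fh if line.strip()]
        wn = frame["wavenumber"].to_numpy()
        cols = [c for c in frame.columns if c != "wavenumber"]
        spectra = [Spectrum(wn, frame[c].to_numpy(), metas[i]) for i, c in enumerate(cols)]
        return self.put_spectra(spectra)
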