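"""Annotated synthetic spectrum collections.

Two dataset flavours feed the chemometrics pipeline:

* ``mode="fermentation"`` — experiments follow simulated batch/fed-batch
  trajectories sampled roughly hourly, every sample recorded as a small
  number of replicate spectra (two by default, matching the measurement
  procedure's spectra-per-sample setting).
* ``mode="mixture"`` — random analyte mixtures spread over the calibration
  ranges, recorded on a fleet of distinct spectrometers.  This emulates the
  auxiliary multi-instrument training corpus (default: 8 instruments).

Labels are returned as a tidy :class:`pandas.DataFrame`; spectra keep their
native per-instrument wavenumber grids so that harmonisation is exercised
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fermentation import FermentationParams, simulate_fermentation
from .spectra import (
    AnalytePeakLibrary,
    SpectrometerProfile,
    Spectrum,
    default_library,
    instrument_profiles,
    synth_spectrum,
)

__all__ = ["SpectraDataset", "make_dataset"]

TARGET_ANALYTES = ("glucose", "acetate")

#: Concentration ranges (g/L) for random mixture samples.
MIXTURE_RANGES = {
    "glucose": (0.0, 10.0),
    "acetate": (0.0, 2.0),
    "ethanol": (0.0, 3.0),
    "mgso4": (0.0, 3.0),
}
WATER_G_PER_L = 980.0


@dataclass
class SpectraDataset:
    """Spectra plus a label table aligned by row order."""

    spectra: list[Spectrum]
    labels: pd.DataFrame
    profiles: list[SpectrometerProfile] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def experiment_ids(self) -> list[str]:
        return sorted(self.labels["experiment_id"].unique())

    def subset(self, experiment_ids) -> "SpectraDataset":
        wanted = set(experiment_ids)
        mask = self.labels["experiment_id"].isin(wanted).to_numpy()
        idx = np.flatnonzero(mask)
        return SpectraDataset(
            [self.spectra[i] for i in idx],
            self.labels.iloc[idx].reset_index(drop=True),
            self.profiles,
        )

    def concat(self, other: "SpectraDataset") -> "SpectraDataset":
        labels = pd.concat([self.labels, other.labels], ignore_index=True)
        return SpectraDataset(self.spectra + other.spectra, labels,
                              self.profiles + other.profiles)

    def targets(self, analytes=TARGET_ANALYTES) -> np.ndarray:
        return self.labels[list(analytes)].to_numpy(dtype=float)

    def manifest(self) -> dict:
        return {
            "n_spectra": len(self),
            "n_experiments": len(self.experiment_ids),
            "n_instruments": int(self.labels["instrument_id"].nunique()),
            "analytes": list(TARGET_ANALYTES),
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.manifest(), fh)


def make_dataset(
    n_experiments: int = 24,
    samples_per_experiment: int = 9,
    n_instruments: int = 1,
    rng_seed: int | np.random.Generator | None = 0,
    spectra_per_sample: int = 2,
    mode: str = "fermentation",
    profiles: list[SpectrometerProfile] | None = None,
    library: AnalytePeakLibrary | None = None,
    fermentation_params: FermentationParams | None = None,
) -> SpectraDataset:
    """Generate an annotated spectrum collection.

    Every spectrum carries its concentration labels and instrument id;
    instruments differ in grid, gain and baseline.  Deterministic for a
    fixed seed.
    """
    if min(n_experiments, samples_per_experiment, n_instruments, spectra_per_sample) < 1:
        raise ValueError("all dataset counts must be >= 1")
    gen = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    library = library if library is not None else default_library()
    if profiles is None:
        profiles = instrument_profiles(n_instruments, gen)
    elif len(profiles) < n_instruments:
        raise ValueError("fewer profiles than requested instruments")

    spectra: list[Spectrum] = []
    rows: list[dict] = []
    for e in range(n_experiments):
        exp_id = f"{mode[:4]}-{e:03d}"
        instrument = e % n_instruments
        profile = profiles[instrument]
        if mode == "fermentation":
            fp = simulate_fermentation(fermentation_params, gen)
            t_max = float(fp.times[-1])
            sample_times = np.linspace(0.0, t_max, samples_per_experiment)
            sample_times = sample_times + gen.uniform(-0.05, 0.05, samples_per_experiment) * (
                t_max / max(samples_per_experiment - 1, 1)
            )
            sample_times = np.clip(sample_times, 0.0, t_max)
            concs = [fp.at(t) for t in sample_times]
        elif mode == "mixture":
            sample_times = np.arange(samples_per_experiment, dtype=float)
            concs = [
                {a: float(gen.uniform(lo, hi)) for a, (lo, hi) in MIXTURE_RANGES.items()}
                for _ in range(samples_per_experiment)
            ]
        else:
            raise ValueError(f"unknown dataset mode: {mode!r}")

        for s, (t, conc) in enumerate(zip(sample_times, concs)):
            conc = dict(conc)
            conc.pop("biomass", None)  # supernatant: cells removed before measurement
            conc["water"] = WATER_G_PER_L
            sample_id = f"{exp_id}-s{s:02d}"
            for r in range(spectra_per_sample):
                meta = {
                    "experiment_id": exp_id,
                    "sample_id": sample_id,
                    "instrument_id": instrument,
                    "replicate": r,
                    "time_h": float(t),
                    "channel": 1 + (s % 8),
                    "n_spectra": spectra_per_sample,
                    "exposure_s": 10.0,
                    "timestamp": float(t) * 3600.0 + r * 10.0,
                }
                spectra.append(synth_spectrum(conc, profile, library, gen, meta))
                rows.append(
                    {
                        "experiment_id": exp_id,
                        "sample_id": sample_id,
                        "instrument_id": instrument,
                        "replicate": r,
                        "time_h": float(t),
                        **{a: conc.get(a, 0.0) for a in ("glucose", "acetate", "ethanol", "mgso4")},
                    }
                )
    return SpectraDataset(spectra, pd.DataFrame(rows), list(profiles[:n_instruments]))
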