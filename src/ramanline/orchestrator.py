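"""The per-sample measure/store/predict/clean cycle and its timing budget.

One cycle per channel k:

1. switch the multiplexer to k,
2. pump the sample-to-cuvette volume V_sc forward,
3. record N spectra of exposure tau while circulating the move volume V_m
   at flow rate V_m / (N * tau), so the plug is still advancing when the
   last spectrum ends,
4. predict concentrations and persist spectra + predictions,
5. clean: pump the cleaning volume V_clean in reverse (wash pushed through
   the cuvette toward the well overflow), then pump the pull-back volume
   V_pb forward to empty the well for the next sample.

The four mechanical steps carry fixed measured durations from
:class:`~ramanline.rig.TimingConfig`; only spectrum acquisition is timed by
volume/rate.  With the default durations the per-sample overhead is 20.2 s,
giving 40.2 s per sample at two 10 s spectra — inside the 45 s envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .rig import Rig, TimingConfig
from .spectra import Spectrum

__all__ = [
    "MeasurementParams",
    "MeasurementRecord",
    "Estimator",
    "move_rate",
    "overhead_time",
    "cycle_time",
    "compare_scheduling",
    "measure_samples",
    "verify_cleaning",
]


class MeasurementParams(BaseModel):
    """The adjustable procedure parameters.

    V_sc and V_pb are the two jointly calibrated volumes; the defaults are
    the simulated geometry's own calibrated optimum.  The sample volume must
    cover the cuvette plus the circulated move volume (the fill rule
    V_sample >= cuvette + V_m is checked against the 18 uL default cuvette).
    """

    v_sc: float = Field(115.0, gt=0)  # sample-to-cuvette volume, uL
    v_pb: float = Field(400.0, gt=0)  # pull-back volume, uL
    v_m: float = Field(20.0, gt=0)  # move-sample volume, uL
    v_clean: float = Field(1250.0, ge=0)  # cleaning volume, uL
    v_sample: float = Field(50.0, gt=0)  # pipetted sample volume, uL
    q_s: float = Field(32.0, gt=0)  # sample-to-cuvette flow rate, uL/s
    q_c: float = Field(125.0, gt=0)  # cleaning flow rate, uL/s
    q_pb: float = Field(84.0, gt=0)  # pull-back flow rate, uL/s
    n_spectra: int = Field(2, ge=1)
    exposure_s: float = Field(10.0, gt=0)
    cuvette_volume: float = Field(18.0, gt=0)

    @model_validator(mode="after")
    def _fill_rule(self) -> "MeasurementParams":
        if self.v_sample < self.cuvette_volume + self.v_m:
            raise ValueError("sample volume must cover cuvette volume plus move volume")
        return self

    @classmethod
    def from_yaml(cls, path) -> "MeasurementParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class MeasurementRecord:
    sample_id: str
    channel: int
    spectra: list[Spectrum]
    predictions: dict[str, float]
    timing: dict[str, float]
    started_s: float
    finished_s: float

    @property
    def duration_s(self) -> float:
        return self.finished_s - self.started_s


class Estimator(Protocol):
    """Anything that maps a sample's spectra to per-analyte g/L."""

    def predict(self, spectra: Sequence[Spectrum]) -> dict[str, float]: ...


def move_rate(v_m: float, n_spectra: int, exposure_s: float) -> float:
    """Flow rate V_m / (N * tau) used while recording the N spectra."""
    if n_spectra < 1:
        raise ValueError("need at least one spectrum")
    if exposure_s <= 0:
        raise ValueError("exposure must be positive")
    if v_m < 0:
        raise ValueError("move volume must be non-negative")
    return v_m / (n_spectra * exposure_s)


def overhead_time(timing: TimingConfig) -> float:
    """Fixed per-sample overhead: every step except spectrum acquisition."""
    return (timing.t_valve + timing.t_pump_to_cuvette + timing.t_clean
            + timing.t_pullback + timing.t_software)


def cycle_time(timing: TimingConfig, n_spectra: int, exposure_s: float) -> float:
    """Total time per sample: overhead plus N * tau of acquisition."""
    if n_spectra < 1:
        raise ValueError("need at least one spectrum")
    if exposure_s <= 0:
        raise ValueError("exposure must be positive")
    return overhead_time(timing) + n_spectra * exposure_s


def compare_scheduling(timing: TimingConfig, k: int = 8) -> float:
    """Per-channel time saved by cleaning immediately after each measurement.

    Deferring all cleaning to the end of the round needs 2K valve switches
    per cycle instead of K, so the immediate strategy saves one valve switch
    per channel: (2K - K) * t_valve / K = t_valve.
    """
    if k < 1:
        raise ValueError("need at least one channel")
    switches_immediate = k
    switches_deferred = 2 * k
    return (switches_deferred - switches_immediate) * timing.t_valve / k


def _run_cycle(
    rig: Rig,
    params: MeasurementParams,
    k: int,
    estimator: Estimator | None,
    sample_id: str,
) -> MeasurementRecord:
    timing = rig.timing
    started = rig.clock
    rig.select_channel(k)
    ch = rig.channels[k]
    if ch.well_volume <= rig.geometry.well_dead_volume + 1e-9:
        warnings.warn(f"channel {k}: well not pipetted; recording air-dominated spectra",
                      stacklevel=2)
    rig.pump("forward", params.v_sc, duration=timing.t_pump_to_cuvette)
    rate = move_rate(params.v_m, params.n_spectra, params.exposure_s)
    spectra: list[Spectrum] = []
    for i in range(params.n_spectra):
        # the plug advances V_m in total across the N exposures
        rig.pump("forward", params.v_m / params.n_spectra, rate=rate)
        spectra.append(
            rig.read_intensity(meta={
                "sample_id": sample_id,
                "n_spectra": params.n_spectra,
                "exposure_s": params.exposure_s,
                "timestamp": rig.clock,
            })
        )
    predictions = estimator.predict(spectra) if estimator is not None else {}
    rig.clock += timing.t_software  # prediction + persistence are software time
    rig.pump("reverse", params.v_clean, duration=timing.t_clean)
    rig.pump("forward", params.v_pb, duration=timing.t_pullback,
             well_draw_fraction=rig.geometry.pullback_draw_fraction)
    breakdown = {
        "valve": timing.t_valve,
        "to_cuvette": timing.t_pump_to_cuvette,
        "acquisition": params.n_spectra * params.exposure_s,
        "software": timing.t_software,
        "clean": timing.t_clean,
        "pullback": timing.t_pullback,
    }
    return MeasurementRecord(sample_id, k, spectra, predictions, breakdown, started, rig.clock)


def measure_samples(
    rig: Rig,
    params: MeasurementParams,
    k_samples: int,
    estimator: Estimator | None = None,
    store=None,
    experiment_id: str = "run",
) -> list[MeasurementRecord]:
    """Measure wells 1..K in channel-ascending order; one clean per channel."""
    if not 1 <= k_samples <= Rig.N_CHANNELS:
        raise ValueError(f"K must be in 1..{Rig.N_CHANNELS}")
    records = []
    for k in range(1, k_samples + 1):
        sample_id = f"{experiment_id}-k{k}"
        rec = _run_cycle(rig, params, k, estimator, sample_id)
        if store is not None:
            for s in rec.spectra:
                s.meta.setdefault("experiment_id", experiment_id)
                s.meta.setdefault("channel", k)
            ids = store.put_spectra(rec.spectra)
            if rec.predictions:
                store.put_predictions(sample_id, "estimator", rec.predictions,
                                      spectrum_ids=ids)
        records.append(rec)
    return records


def verify_cleaning(
    rig: Rig,
    params: MeasurementParams,
    probe_concentrations: Mapping[str, float],
    channel: int = 1,
) -> float:
    """Residual analyte fraction left in the optical window after one clean.

    Measures a probe sample (e.g. 50 g/L MgSO4), runs the clean + pull-back
    of the normal cycle, then reports max over analytes of (window mean
    concentration) / (probe concentration).  Pure plug flow (kappa = 0)
    gives exactly 0; the software analogue of seeing no sulfate band after
    cleaning.
    """
    probe = {a: c for a, c in probe_concentrations.items() if c > 0}
    if not probe:
        raise ValueError("probe must contain at least one analyte")
    timing = rig.timing
    rig.pipette_sample(channel, params.v_sample, probe)
    rig.select_channel(channel)
    rig.pump("forward", params.v_sc, duration=timing.t_pump_to_cuvette)
    rig.pump("forward", params.v_m, rate=move_rate(params.v_m, 1, params.exposure_s))
    if params.v_clean > 0:
        rig.pump("reverse", params.v_clean, duration=timing.t_clean)
    conc, _air = rig.window_contents(channel)
    return max(conc.get(a, 0.0) / c for a, c in probe.items())
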