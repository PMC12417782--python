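"""Volumetric plug-flow simulation of the sampling path.

Each of the eight channels is modelled on a 1-D volume coordinate (uL) with
origin at the well outlet and increasing toward the peristaltic pump:

    well -> tube -> multiplexer -> tube -> connector -> cuvette -> downstream -> pump

The liquid column is an ordered list of labelled segments (sample with
per-analyte g/L, wash, air).  Pumping shifts the column: forward draws from
the well (air once it empties) and expels the pump end to waste; reverse
draws wash from the reservoir and expels the well end into the well, whose
overflow drains to waste.  The optical window of the flow cuvette is an
interval on the same axis; spectra are synthesised from its volume-averaged
contents.

Carry-over between sample and wash is modelled by an optional dispersion
step: after pumping a volume V, every liquid/liquid boundary is replaced by
a linearly graded mixing zone of width kappa * sqrt(V) (symmetric, so every
analyte's mass is conserved exactly).  kappa = 0 is pure plug flow.

The pull-back step that empties a well uses a partial-draw rule: only a
fraction of the pumped volume is drawn from the well, the remainder entering
through the overflow tee, and the well cannot be pumped below its dead
volume.  Residual wash after pull-back therefore decreases smoothly with the
pull-back volume — the mechanism behind the pull-back axis of the
calibration surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .spectra import AnalytePeakLibrary, SpectrometerProfile, Spectrum, default_library, default_profile, synth_spectrum

__all__ = [
    "ChannelGeometry",
    "TimingConfig",
    "Rig",
    "RigError",
    "tube_volume",
    "select_channel",
    "pipette_sample",
    "pump",
    "apply_dispersion",
    "window_contents",
    "read_intensity",
]

WASH: dict[str, float] = {}
_EPS = 1e-12


class RigError(RuntimeError):
    pass


def tube_volume(length_mm: float, inner_diameter_mm: float) -> float:
    """Internal volume of a cylindrical tube in uL (1 mm^3 == 1 uL)."""
    if length_mm < 0:
        raise ValueError("tube length must be non-negative")
    if inner_diameter_mm <= 0:
        raise ValueError("inner diameter must be positive")
    return math.pi * (inner_diameter_mm / 2.0) ** 2 * length_mm


class ChannelGeometry(BaseModel):
    """Volumes (uL) along one channel; defaults follow the physical rig.

    The two tube volumes derive from 125 mm and 65 mm of 0.508 mm ID tubing;
    the multiplexer and connector dead volumes are not published for the
    hardware and are configuration with stated defaults.
    """

    well_capacity: float = Field(125.0, gt=0)
    well_dead_volume: float = Field(5.0, gt=0)
    tube_well_to_valve: float = Field(default_factory=lambda: tube_volume(125.0, 0.508), gt=0)
    valve_dead_volume: float = Field(40.0, ge=0)
    tube_valve_to_cuvette: float = Field(default_factory=lambda: tube_volume(65.0, 0.508), gt=0)
    connector_dead_volume: float = Field(12.5, ge=0)
    cuvette_volume: float = Field(18.0, gt=0)
    window_interval: tuple[float, float] = (4.0, 14.0)
    downstream_volume: float = Field(150.0, gt=0)
    pullback_draw_fraction: float = Field(0.3, gt=0, le=1.0)
    dispersion_kappa: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ChannelGeometry":
        lo, hi = self.window_interval
        if not (0 <= lo < hi <= self.cuvette_volume):
            raise ValueError("window_interval must lie inside the cuvette")
        if self.well_dead_volume >= self.well_capacity:
            raise ValueError("well dead volume must be below capacity")
        return self

    @property
    def cuvette_start(self) -> float:
        return (self.tube_well_to_valve + self.valve_dead_volume
                + self.tube_valve_to_cuvette + self.connector_dead_volume)

    @property
    def window_bounds(self) -> tuple[float, float]:
        lo, hi = self.window_interval
        return self.cuvette_start + lo, self.cuvette_start + hi

    @property
    def path_volume(self) -> float:
        return self.cuvette_start + self.cuvette_volume + self.downstream_volume

    @classmethod
    def from_yaml(cls, path) -> "ChannelGeometry":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class TimingConfig(BaseModel):
    """Measured step durations (s) of the mechanical cycle."""

    t_valve: float = Field(1.3, ge=0)
    t_pump_to_cuvette: float = Field(3.6, ge=0)
    t_clean: float = Field(10.0, ge=0)
    t_pullback: float = Field(4.74, ge=0)
    t_software: float = Field(0.56, ge=0)

    @classmethod
    def from_yaml(cls, path) -> "TimingConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class Segment:
    label: str  # "sample" | "wash" | "air"
    conc: dict[str, float] | None  # None for air, {} for wash
    volume: float

    def copy(self) -> "Segment":
        return Segment(self.label, None if self.conc is None else dict(self.conc), self.volume)


def _mix(parts: list[tuple[dict[str, float], float]]) -> dict[str, float]:
    total = sum(v for _, v in parts)
    if total <= 0:
        return {}
    out: dict[str, float] = {}
    for conc, vol in parts:
        for a, c in conc.items():
            out[a] = out.get(a, 0.0) + c * vol / total
    return {a: c for a, c in out.items() if c > _EPS}


def _same_conc(a: dict[str, float], b: dict[str, float]) -> bool:
    keys = set(a) | set(b)
    return all(abs(a.get(k, 0.0) - b.get(k, 0.0)) <= 1e-9 * max(1.0, abs(a.get(k, 0.0))) for k in keys)


def _liquid_label(conc: dict[str, float]) -> str:
    return "sample" if any(c > _EPS for a, c in conc.items()) else "wash"


@dataclass
class Channel:
    geometry: ChannelGeometry
    well_volume: float = 0.0
    well_conc: dict[str, float] = field(default_factory=dict)
    segments: list[Segment] = field(default_factory=list)

    @classmethod
    def pristine(cls, geometry: ChannelGeometry) -> "Channel":
        ch = cls(geometry, well_volume=geometry.well_dead_volume, well_conc={})
        ch.segments = [Segment("wash", {}, geometry.path_volume)]
        return ch

    # -- bookkeeping ---------------------------------------------------
    def coalesce(self) -> None:
        merged: list[Segment] = []
        for seg in self.segments:
            if seg.volume <= _EPS:
                continue
            if merged and merged[-1].label == seg.label and (
                seg.conc is None or _same_conc(merged[-1].conc or {}, seg.conc or {})
            ):
                merged[-1].volume += seg.volume
            else:
                merged.append(seg)
        self.segments = merged

    def liquid_volume(self) -> float:
        return sum(s.volume for s in self.segments if s.label != "air")

    def analyte_mass(self, analyte: str) -> float:
        mass = sum(s.volume * s.conc.get(analyte, 0.0) for s in self.segments if s.conc)
        mass += self.well_volume * self.well_conc.get(analyte, 0.0)
        return mass


class Rig:
    """Mutable rig state: eight channels, a selected channel and a clock."""

    N_CHANNELS = 8

    def __init__(
        self,
        geometry: ChannelGeometry | None = None,
        timing: TimingConfig | None = None,
        profile: SpectrometerProfile | None = None,
        library: AnalytePeakLibrary | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        self.geometry = geometry or ChannelGeometry()
        self.timing = timing or TimingConfig()
        self.profile = profile or default_profile()
        self.library = library if library is not None else default_library()
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.channels = {k: Channel.pristine(self.geometry) for k in range(1, self.N_CHANNELS + 1)}
        self.selected: int | None = None
        self.clock = 0.0
        self.waste_volume = 0.0
        self.reservoir_draw = 0.0
        self.bypass_draw = 0.0
        self.pipetted_volume = 0.0

    # -- conservation ledger -------------------------------------------
    def liquid_inventory(self) -> float:
        """Liquid currently inside the system plus cumulative waste."""
        inside = sum(ch.liquid_volume() + ch.well_volume for ch in self.channels.values())
        return inside + self.waste_volume

    def liquid_input(self) -> float:
        """Liquid ever introduced (initial fill + pipetted + reservoir/tee draws)."""
        initial = self.N_CHANNELS * (self.geometry.path_volume + self.geometry.well_dead_volume)
        return initial + self.pipetted_volume + self.reservoir_draw + self.bypass_draw

    # -- operations ----------------------------------------------------
    def select_channel(self, k: int) -> "Rig":
        if not 1 <= k <= self.N_CHANNELS:
            raise RigError(f"channel {k} out of range 1..{self.N_CHANNELS}")
        self.selected = k
        self.clock += self.timing.t_valve  # charged even when re-selecting
        return self

    def pipette_sample(self, k: int, volume: float, concentrations: Mapping[str, float]) -> "Rig":
        if not 1 <= k <= self.N_CHANNELS:
            raise RigError(f"channel {k} out of range 1..{self.N_CHANNELS}")
        if volume <= 0:
            raise ValueError("pipetted volume must be positive")
        if any(c < 0 for c in concentrations.values()):
            raise ValueError("concentrations must be non-negative")
        ch = self.channels[k]
        conc = {a: float(c) for a, c in concentrations.items() if c > _EPS}
        mixed = _mix([(ch.well_conc, ch.well_volume), (conc, volume)])
        total = ch.well_volume + volume
        self.pipetted_volume += volume
        if total > self.geometry.well_capacity:
            excess = total - self.geometry.well_capacity
            self.waste_volume += excess
            total = self.geometry.well_capacity
        ch.well_volume, ch.well_conc = total, mixed
        return self

    def pump(
        self,
        direction: str,
        volume: float,
        rate: float | None = None,
        duration: float | None = None,
        well_draw_fraction: float = 1.0,
    ) -> "Rig":
        """Shift the selected channel's column by ``volume`` uL.

        The clock advances by ``duration`` when given (fixed mechanical step
        durations), else by volume/rate.  ``well_draw_fraction`` < 1 routes
        the remainder of a forward draw through the overflow tee as wash
        (the pull-back step).
        """
        if self.selected is None:
            raise RigError("no channel selected")
        if volume < 0:
            raise ValueError("pumped volume must be non-negative")
        if duration is None:
            if rate is None or rate <= 0:
                raise ValueError("need a positive rate or an explicit duration")
            duration = volume / rate
        self.clock += duration
        if volume == 0:
            return self
        ch = self.channels[self.selected]
        if direction == "forward":
            self._pump_forward(ch, volume, well_draw_fraction)
        elif direction == "reverse":
            self._pump_reverse(ch, volume)
        else:
            raise ValueError("direction must be 'forward' or 'reverse'")
        if self.geometry.dispersion_kappa > 0:
            self.apply_dispersion(volume)
        ch.coalesce()
        return self

    def _pump_forward(self, ch: Channel, volume: float, f: float) -> None:
        # expel at the pump end
        remaining = volume
        while remaining > _EPS and ch.segments:
            tail = ch.segments[-1]
            take = min(tail.volume, remaining)
            tail.volume -= take
            remaining -= take
            if tail.label != "air":
                self.waste_volume += take
            if tail.volume <= _EPS:
                ch.segments.pop()
        # draw at the well end
        drainable = max(0.0, ch.well_volume - self.geometry.well_dead_volume)
        from_well = min(f * volume, drainable)
        bypass = (1.0 - f) * volume
        air = volume - from_well - bypass
        ch.well_volume -= from_well
        if ch.well_volume <= self.geometry.well_dead_volume + _EPS and not ch.well_conc:
            ch.well_conc = {}
        self.bypass_draw += bypass
        head: list[Segment] = []
        if air > _EPS:
            head.append(Segment("air", None, air))
        liquid = from_well + bypass
        if liquid > _EPS:
            conc = _mix([(ch.well_conc, from_well), (WASH, bypass)])
            head.append(Segment(_liquid_label(conc), conc, liquid))
        ch.segments = head + ch.segments

    def _pump_reverse(self, ch: Channel, volume: float) -> None:
        # draw wash from the reservoir at the pump end
        ch.segments.append(Segment("wash", {}, volume))
        self.reservoir_draw += volume
        # expel at the well end into the well; overflow drains to waste
        remaining = volume
        into_well: list[tuple[dict[str, float], float]] = []
        while remaining > _EPS and ch.segments:
            headseg = ch.segments[0]
            take = min(headseg.volume, remaining)
            headseg.volume -= take
            remaining -= take
            if headseg.label != "air":
                into_well.append((headseg.conc or {}, take))
            if headseg.volume <= _EPS:
                ch.segments.pop(0)
        # The well is bottom-fed and overflows at the top: incoming liquid
        # displaces the oldest content, so the well retains only the newest
        # capacity-worth of liquid (a long wash flush leaves it clean).
        pieces = [(ch.well_conc, ch.well_volume)] + into_well
        capacity = self.geometry.well_capacity
        total = sum(v for _, v in pieces)
        overflow = max(0.0, total - capacity)
        self.waste_volume += overflow
        retained: list[tuple[dict[str, float], float]] = []
        skip = overflow  # oldest liquid leaves first
        for conc, vol in pieces:
            if skip >= vol - _EPS:
                skip -= vol
                continue
            retained.append((conc, vol - skip))
            skip = 0.0
        ch.well_volume = sum(v for _, v in retained)
        ch.well_conc = _mix(retained)

    def apply_dispersion(self, pumped_volume: float, kappa: float | None = None) -> "Rig":
        """Replace liquid/liquid boundaries with linearly graded mixing zones.

        Zone width is kappa * sqrt(pumped_volume), clipped symmetrically so
        that each side contributes equally (mass conservation is exact).
        """
        if self.selected is None:
            raise RigError("no channel selected")
        kappa = self.geometry.dispersion_kappa if kappa is None else kappa
        if kappa <= 0 or pumped_volume <= 0:
            return self
        ch = self.channels[self.selected]
        w_half = 0.5 * kappa * math.sqrt(pumped_volume)
        n_sub = 6
        out: list[Segment] = []
        for seg in ch.segments:
            seg = seg.copy()
            if (
                out
                and out[-1].label != "air"
                and seg.label != "air"
                and not _same_conc(out[-1].conc or {}, seg.conc or {})
            ):
                left = out[-1]
                h = min(w_half, left.volume, seg.volume)
                if h > _EPS:
                    a, b = left.conc or {}, seg.conc or {}
                    left.volume -= h
                    seg.volume -= h
                    if left.volume <= _EPS:
                        out.pop()
                    width = 2.0 * h
                    for i in range(n_sub):
                        t = (i + 0.5) / n_sub
                        conc = _mix([(a, 1.0 - t), (b, t)])
                        out.append(Segment(_liquid_label(conc), conc, width / n_sub))
            out.append(seg)
        ch.segments = [s for s in out if s.volume > _EPS]
        return self

    def window_contents(self, k: int | None = None) -> tuple[dict[str, float], float]:
        """Volume-weighted analyte means over the optical window + air fraction.

        Concentrations are averaged over the liquid part of the window only;
        the air fraction reports how much of the window holds air.
        """
        k = self.selected if k is None else k
        if k is None:
            raise RigError("no channel selected")
        ch = self.channels[k]
        lo, hi = self.geometry.window_bounds
        pos = 0.0
        liquid_parts: list[tuple[dict[str, float], float]] = []
        air_vol = 0.0
        for seg in ch.segments:
            start, end = pos, pos + seg.volume
            pos = end
            overlap = min(end, hi) - max(start, lo)
            if overlap <= _EPS:
                continue
            if seg.label == "air":
                air_vol += overlap
            else:
                liquid_parts.append((seg.conc or {}, overlap))
        window = hi - lo
        return _mix(liquid_parts), min(1.0, air_vol / window)

    def read_intensity(self, rng: np.random.Generator | int | None = None, meta: dict | None = None) -> Spectrum:
        conc, air = self.window_contents()
        base_meta = {"channel": self.selected, "clock_s": self.clock}
        base_meta.update(meta or {})
        gen = rng if rng is not None else self.rng
        return synth_spectrum(conc, self.profile, self.library, gen, base_meta, signal_scale=1.0 - air)

    # -- diagnostics ---------------------------------------------------
    def snapshot(self) -> dict:
        return {
            "selected": self.selected,
            "clock_s": self.clock,
            "waste_uL": self.waste_volume,
            "reservoir_uL": self.reservoir_draw,
            "channels": {
                k: {
                    "well_volume": ch.well_volume,
                    "well_conc": ch.well_conc,
                    "segments": [[s.label, s.conc, s.volume] for s in ch.segments],
                }
                for k, ch in self.channels.items()
            },
        }

    def dump_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.snapshot(), fh, indent=2)


# ---------------------------------------------------------------------------
# Functional facade matching the operation-per-state style.

def select_channel(rig: Rig, k: int) -> Rig:
    return rig.select_channel(k)


def pipette_sample(rig: Rig, k: int, volume: float, concentrations: Mapping[str, float]) -> Rig:
    return rig.pipette_sample(k, volume, concentrations)


def pump(rig: Rig, direction: str, volume: float, rate: float | None = None, **kw) -> Rig:
    return rig.pump(direction, volume, rate, **kw)


def apply_dispersion(rig: Rig, pumped_volume: float, kappa: float | None = None) -> Rig:
    return rig.apply_dispersion(pumped_volume, kappa)


def window_contents(rig: Rig) -> tuple[dict[str, float], float]:
    return rig.window_contents()


def read_intensity(rig: Rig, rng=None, meta: dict | None = None) -> Spectrum:
    return rig.read_intensity(rng, meta)
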