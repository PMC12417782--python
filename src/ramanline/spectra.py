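"""Synthetic Raman spectra of fermentation supernatant.

The measurement system records Raman spectra of cell-free supernatant in a
flow-through cuvette.  This module provides the spectral forward model used
throughout the package: an instrument profile (wavenumber grid, gain,
fluorescence baseline, detector noise, cuvette-holder mirror), a library of
analyte peaks (glucose, acetate, MgSO4, ethanol, water), and a generator that
composes them into a spectrum

    I(wn) = mirror * gain * sum_analyte c_a * sum_peaks A * shape(wn) + baseline(wn) + noise

so that the baseline-subtracted signal is exactly linear in concentration.
Peak positions other than the 980 cm^-1 sulfate band are editable
configuration; they are placed at literature-typical positions (the glucose
cluster sits inside the 1000-1500 cm^-1 calibration band).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SpectrometerProfile",
    "Peak",
    "AnalytePeakLibrary",
    "Spectrum",
    "make_axis",
    "synth_spectrum",
    "default_library",
    "default_profile",
    "instrument_profiles",
    "write_spectra_csv",
    "read_spectra_csv",
]

#: Default wavenumber grid of the spectrometer: 2048 points, 65-3350 cm^-1.
DEFAULT_WN_MIN = 65.0
DEFAULT_WN_MAX = 3350.0
DEFAULT_N_POINTS = 2048


class SpectrometerProfile(BaseModel):
    """One spectrometer's acquisition characteristics.

    ``baseline_coeffs`` are polynomial coefficients (constant first) in the
    normalised coordinate u = (wn - wn_min)/(wn_max - wn_min); together with
    an exponentially decaying fluorescence term they form the background.
    ``mirror_factor`` models the retro-reflecting mirror in the cuvette
    holder that sends the laser through the sample a second time.
    """

    wn_min: float = DEFAULT_WN_MIN
    wn_max: float = DEFAULT_WN_MAX
    n_points: int = Field(DEFAULT_N_POINTS, ge=2)
    gain: float = Field(1.0, gt=0)
    baseline_coeffs: tuple[float, ...] = (60.0, -20.0, 12.0, -4.0)
    fluor_amplitude: float = 300.0
    fluor_decay: float = 3.0
    noise_sd: float = Field(0.5, ge=0)
    noise_proportional: float = Field(0.0, ge=0)
    mirror_factor: float = Field(2.0, ge=1)

    @model_validator(mode="after")
    def _check_range(self) -> "SpectrometerProfile":
        if not self.wn_min < self.wn_max:
            raise ValueError("wn_min must be < wn_max")
        return self


@dataclass(frozen=True)
class Peak:
    """A single Raman band: position, width and height per g/L of analyte."""

    center: float  # cm^-1
    fwhm: float  # cm^-1
    amplitude: float  # intensity units per g/L at the peak maximum
    shape: Literal["gaussian", "lorentzian", "pseudo_voigt"] = "pseudo_voigt"
    eta: float = 0.5  # Lorentzian fraction for pseudo-Voigt

    def profile(self, wn: np.ndarray) -> np.ndarray:
        return self.amplitude * line_shape(wn, self.center, self.fwhm, self.shape, self.eta)


#: Analyte name -> list of peaks.
AnalytePeakLibrary = Mapping[str, Sequence[Peak]]


def line_shape(
    wn: np.ndarray, center: float, fwhm: float, shape: str = "pseudo_voigt", eta: float = 0.5
) -> np.ndarray:
    """Unit-height line profile on the grid ``wn``.

    Gaussian: exp(-4 ln2 (x-c)^2 / w^2); Lorentzian: 1/(1 + 4((x-c)/w)^2);
    pseudo-Voigt: eta * L + (1 - eta) * G, all sharing the same FWHM ``w``.
    """
    x = (np.asarray(wn, dtype=float) - center) / fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * x**2)
    if shape == "gaussian":
        return gauss
    lorentz = 1.0 / (1.0 + 4.0 * x**2)
    if shape == "lorentzian":
        return lorentz
    if shape == "pseudo_voigt":
        return eta * lorentz + (1.0 - eta) * gauss
    raise ValueError(f"unknown line shape: {shape!r}")


def default_library() -> dict[str, list[Peak]]:
    """Shipped peak library.

    MgSO4 must carry the 980 cm^-1 sulfate symmetric-stretch band (it is the
    cleaning-verification marker); the glucose cluster lies inside the
    1000-1500 cm^-1 calibration band.  Other positions follow common
    literature assignments for aqueous solutions and are configuration, not
    ground truth.
    """
    return {
        "glucose": [
            Peak(520.0, 35.0, 0.25),
            Peak(1065.0, 40.0, 0.55),
            Peak(1125.0, 38.0, 1.00),
            Peak(1365.0, 45.0, 0.45),
            Peak(1460.0, 40.0, 0.35),
            Peak(2900.0, 70.0, 0.40),
        ],
        "acetate": [
            Peak(928.0, 25.0, 1.20),
            Peak(1413.0, 30.0, 0.80),
            Peak(2935.0, 60.0, 0.50),
        ],
        "mgso4": [
            Peak(980.0, 18.0, 3.00),
            Peak(1110.0, 30.0, 0.20),
        ],
        "ethanol": [
            Peak(880.0, 25.0, 1.50),
            Peak(1050.0, 30.0, 0.60),
            Peak(1095.0, 30.0, 0.45),
            Peak(2930.0, 65.0, 0.90),
        ],
        "water": [
            Peak(1640.0, 90.0, 0.02, "gaussian"),
            Peak(3250.0, 220.0, 0.12, "gaussian"),
        ],
    }


def default_profile() -> SpectrometerProfile:
    return SpectrometerProfile()


@dataclass
class Spectrum:
    """A single Raman spectrum plus acquisition metadata.

    ``meta`` carries at least experiment_id, sample_id, channel, n_spectra,
    exposure_s and timestamp when the spectrum comes from a measurement run.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if self.wavenumbers.ndim != 1:
            raise ValueError("spectrum arrays must be 1-D")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        exposure = self.meta.get("exposure_s")
        if exposure is not None and exposure <= 0:
            raise ValueError("exposure_s must be positive")

    def __len__(self) -> int:
        return self.wavenumbers.size


def make_axis(profile: SpectrometerProfile) -> np.ndarray:
    """Evenly spaced, strictly increasing wavenumber grid of the profile."""
    if profile.n_points < 2:
        raise ValueError("profile must have at least 2 points")
    return np.linspace(profile.wn_min, profile.wn_max, profile.n_points)


def baseline(profile: SpectrometerProfile, wn: np.ndarray) -> np.ndarray:
    """Background: instrument polynomial + sample fluorescence.

    The exponentially decaying fluorescence originates in the sample, so it
    lives on the absolute wavenumber scale and is collected through the same
    optics as the Raman signal (gain and mirror apply); the polynomial is
    instrument-specific detector/optics structure on the local axis.
    """
    u_local = (wn - profile.wn_min) / (profile.wn_max - profile.wn_min)
    poly = np.polynomial.polynomial.polyval(u_local, profile.baseline_coeffs)
    u_abs = (wn - DEFAULT_WN_MIN) / (DEFAULT_WN_MAX - DEFAULT_WN_MIN)
    fluor = profile.fluor_amplitude * np.exp(-profile.fluor_decay * u_abs)
    return poly + profile.mirror_factor * profile.gain * fluor


def analyte_signal(
    concentrations: Mapping[str, float],
    wn: np.ndarray,
    library: AnalytePeakLibrary,
) -> np.ndarray:
    """Noise-free, baseline-free signal: linear in every concentration."""
    signal = np.zeros_like(wn)
    for analyte, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {analyte!r}: {conc}")
        if conc == 0 or analyte not in library:
            continue
        for peak in library[analyte]:
            signal += conc * peak.profile(wn)
    return signal


def synth_spectrum(
    concentrations: Mapping[str, float],
    profile: SpectrometerProfile | None = None,
    library: AnalytePeakLibrary | None = None,
    rng: np.random.Generator | int | None = None,
    meta: dict | None = None,
    signal_scale: float = 1.0,
) -> Spectrum:
    """Synthesise one spectrum for the given analyte concentrations (g/L).

    Deterministic for a fixed seed.  ``signal_scale`` attenuates the analyte
    signal only (used by the rig when part of the optical window holds air).
    """
    profile = profile or default_profile()
    library = library if library is not None else default_library()
    wn = make_axis(profile)
    signal = analyte_signal(concentrations, wn, library)
    intensities = profile.mirror_factor * profile.gain * signal_scale * signal + baseline(profile, wn)
    if profile.noise_sd > 0 or profile.noise_proportional > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        sd = profile.noise_sd + profile.noise_proportional * np.abs(intensities)
        intensities = intensities + gen.normal(0.0, 1.0, wn.size) * sd
    return Spectrum(wn, intensities, dict(meta or {}))


def instrument_profiles(n: int, rng: np.random.Generator | int | None = None) -> list[SpectrometerProfile]:
    """``n`` distinct spectrometer profiles for multi-instrument datasets.

    Instruments differ in wavenumber grid, gain, baseline shape, noise level
    and mirror configuration, emulating a heterogeneous fleet whose spectra
    must be harmonised before joint model training.
    """
    if n < 1:
        raise ValueError("need at least one instrument")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    profiles = [default_profile()]
    grid_choices = [1650, 1800, 1900, 2048, 2150, 2300, 2500]
    for i in range(1, n):
        coeffs = np.asarray(default_profile().baseline_coeffs)
        coeffs = tuple(coeffs * gen.uniform(0.6, 1.4, coeffs.size))
        profiles.append(
            SpectrometerProfile(
                wn_min=float(gen.uniform(60.0, 120.0)),
                wn_max=float(gen.uniform(3100.0, 3400.0)),
                n_points=int(gen.choice(grid_choices)),
                gain=float(gen.uniform(0.6, 1.5)),
                baseline_coeffs=coeffs,
                fluor_amplitude=float(gen.uniform(250.0, 350.0)),
                fluor_decay=float(gen.uniform(2.8, 3.2)),
                noise_sd=float(gen.uniform(0.3, 0.9)),
                mirror_factor=float(gen.choice([1.0, 2.0])),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# File exchange: wide CSV (first column wavenumber) + JSONL metadata sidecar.

def write_spectra_csv(path, spectra: Sequence[Spectrum], sidecar=None) -> None:
    if not spectra:
        raise ValueError("no spectra to write")
    wn = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, wn):
            raise ValueError("wide CSV export requires a shared wavenumber axis")
    data = {"wavenumber": wn}
    for i, s in enumerate(spectra):
        data[f"spectrum_{i}"] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False)
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            for i, s in enumerate(spectra):
                fh.write(json.dumps({"column": f"spectrum_{i}", **s.meta}, default=str) + "\n")


def read_spectra_csv(path, sidecar=None) -> list[Spectrum]:
    frame = pd.read_csv(path)
    wn = frame["wavenumber"].to_numpy()
    metas: dict[str, dict] = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            for line in fh:
                rec = json.loads(line)
                metas[rec.pop("column")] = rec
    out = []
    for col in frame.columns:
        if col == "wavenumber":
            continue
        out.append(Spectrum(wn, frame[col].to_numpy(), metas.get(col, {})))
    return out
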