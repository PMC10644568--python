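"""Raw measurement curves for one tissue sample, and their on-disk bundle.

A complete sample record holds four modality curves:

* impedance spectrum (10 Hz - 3 MHz sweep: frequency, |Z|, phase),
* mechanical loading curve (indentation displacement vs force),
* stress-relaxation trace (normalized load vs time, 150 s hold),
* thermal trace (stepwise heating; source temperature and sense-side RTD
  resistance per step),

plus the sample geometry (nominally a 4 mm cube).  Bundles are directories of
UTF-8 CSV files with mandatory header rows and a JSON sidecar for geometry,
RTD calibration constants and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: default Pt-RTD calibration: resistance at 0 degC and linear coefficient
RTD_R0_OHM = 100.0
RTD_ALPHA_PER_K = 3.85e-3

_BUNDLE_FILES = {
    "impedance": "impedance.csv",
    "loading": "loading.csv",
    "relaxation": "relaxation.csv",
    "thermal": "thermal.csv",
}
_GEOMETRY_FILE = "geometry.json"


class IncompleteBundleError(FileNotFoundError):
    """A modality file is missing from a measurement bundle."""


class BundleFormatError(ValueError):
    """A modality file is present but malformed."""


def _check_grid(name: str, x: np.ndarray, minimum_points: int = 2) -> None:
    if x.size < minimum_points:
        raise BundleFormatError(
            f"{name}: at least {minimum_points} grid points required, got {x.size}"
        )
    if np.any(np.diff(x) <= 0):
        raise BundleFormatError(f"{name}: grid must be strictly increasing")


@dataclass(frozen=True)
class SampleGeometry:
    """Sample dimensions in SI units (defaults: 4 mm cube)."""

    height_m: float = 4e-3         # indentation axis
    thickness_m: float = 4e-3      # heat / current path between the chips
    area_m2: float = 16e-6         # cross-section of that path

    def __post_init__(self) -> None:
        if min(self.height_m, self.thickness_m, self.area_m2) <= 0:
            raise ValueError("all geometry dimensions must be positive")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """|Z| (ohm) and phase (deg) on a strictly increasing frequency grid (Hz)."""

    frequency_hz: np.ndarray
    zmag_ohm: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        for name in ("frequency_hz", "zmag_ohm", "phase_deg"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        _check_grid("impedance frequency", self.frequency_hz)
        if not (self.frequency_hz.size == self.zmag_ohm.size == self.phase_deg.size):
            raise BundleFormatError("impedance columns must have equal length")
        if np.any(self.frequency_hz <= 0):
            raise BundleFormatError("frequencies must be positive")
        if np.any(self.zmag_ohm <= 0):
            raise BundleFormatError("|Z| must be positive")

    @property
    def complex_z(self) -> np.ndarray:
        return self.zmag_ohm * np.exp(1j * np.deg2rad(self.phase_deg))


@dataclass(frozen=True)
class LoadingCurve:
    """Indentation displacement (um, increasing from 0) vs force (mN)."""

    displacement_um: np.ndarray
    force_mn: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "displacement_um", np.asarray(self.displacement_um, float))
        object.__setattr__(self, "force_mn", np.asarray(self.force_mn, float))
        _check_grid("loading displacement", self.displacement_um)
        if self.displacement_um.size != self.force_mn.size:
            raise BundleFormatError("loading columns must have equal length")
        if self.displacement_um[0] < 0:
            raise BundleFormatError("displacement must start at >= 0")


@dataclass(frozen=True)
class RelaxationCurve:
    """Normalized load vs time during the constant-displacement hold."""

    time_s: np.ndarray
    normalized_load: np.ndarray
    start_tolerance: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_s", np.asarray(self.time_s, float))
        object.__setattr__(self, "normalized_load", np.asarray(self.normalized_load, float))
        _check_grid("relaxation time", self.time_s)
        if self.time_s.size != self.normalized_load.size:
            raise BundleFormatError("relaxation columns must have equal length")
        if abs(self.normalized_load[0] - 1.0) > self.start_tolerance:
            raise BundleFormatError("normalized load must start at 1.0")


@dataclass(frozen=True)
class ThermalTrace:
    """Stepwise heating record: one row per 3 degC source-temperature step.

    The sense-side temperature is recorded as the raw RTD resistance; the
    linear RTD law r = R0 * (1 + alpha * T) converts between the two.
    """

    heater_power_mw: np.ndarray
    t_source_c: np.ndarray
    r_sense_ohm: np.ndarray
    rtd_r0_ohm: float = RTD_R0_OHM
    rtd_alpha_per_k: float = RTD_ALPHA_PER_K

    def __post_init__(self) -> None:
        for name in ("heater_power_mw", "t_source_c", "r_sense_ohm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        _check_grid("thermal source temperature", self.t_source_c, minimum_points=1)
        n = self.t_source_c.size
        if not (self.heater_power_mw.size == n == self.r_sense_ohm.size):
            raise BundleFormatError("thermal columns must have equal length")
        if self.rtd_r0_ohm <= 0 or self.rtd_alpha_per_k <= 0:
            raise ValueError("RTD calibration constants must be positive")


@dataclass(frozen=True)
class RawSampleMeasurements:
    """The four raw modality curves plus geometry for one sample."""

    impedance: ImpedanceSpectrum
    loading: LoadingCurve
    relaxation: RelaxationCurve
    thermal: ThermalTrace
    geometry: SampleGeometry = field(default_factory=SampleGeometry)
    provenance: str = ""
    seed: int | None = None


def write_measurement_bundle(m: RawSampleMeasurements, path) -> None:
    """Serialize a sample record as a directory of CSV files + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frequency_hz": m.impedance.frequency_hz,
            "zmag_ohm": m.impedance.zmag_ohm,
            "phase_deg": m.impedance.phase_deg,
        }
    ).to_csv(path / _BUNDLE_FILES["impedance"], index=False)
    pd.DataFrame(
        {"displacement_um": m.loading.displacement_um, "force_mn": m.loading.force_mn}
    ).to_csv(path / _BUNDLE_FILES["loading"], index=False)
    pd.DataFrame(
        {"time_s": m.relaxation.time_s, "normalized_load": m.relaxation.normalized_load}
    ).to_csv(path / _BUNDLE_FILES["relaxation"], index=False)
    pd.DataFrame(
        {
            "heater_power_mw": m.thermal.heater_power_mw,
            "t_source_c": m.thermal.t_source_c,
            "r_sense_ohm": m.thermal.r_sense_ohm,
        }
    ).to_csv(path / _BUNDLE_FILES["thermal"], index=False)
    sidecar = {
        "height_mm": m.geometry.height_m * 1e3,
        "thickness_mm": m.geometry.thickness_m * 1e3,
        "area_mm2": m.geometry.area_m2 * 1e6,
        "rtd_r0_ohm": m.thermal.rtd_r0_ohm,
        "rtd_alpha_per_k": m.thermal.rtd_alpha_per_k,
        "provenance": m.provenance,
        "seed": m.seed,
    }
    (path / _GEOMETRY_FILE).write_text(json.dumps(sidecar, indent=1))


def read_measurement_bundle(path) -> RawSampleMeasurements:
    """Parse a bundle directory written by :func:`write_measurement_bundle`."""
    path = Path(path)
    frames = {}
    for modality, fname in _BUNDLE_FILES.items():
        f = path / fname
        if not f.exists():
            raise IncompleteBundleError(
                f"incomplete bundle at {path}: missing {modality} file {fname!r}"
            )
        frames[modality] = pd.read_csv(f)

    def col(modality: str, name: str) -> np.ndarray:
        frame = frames[modality]
        if name not in frame.columns:
            raise BundleFormatError(f"{modality} file missing column {name!r}")
        return frame[name].to_numpy(float)

    geometry = SampleGeometry()
    r0, alpha, provenance, seed = RTD_R0_OHM, RTD_ALPHA_PER_K, "", None
    sidecar_path = path / _GEOMETRY_FILE
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        geometry = SampleGeometry(
            height_m=sidecar["height_mm"] * 1e-3,
            thickness_m=sidecar["thickness_mm"] * 1e-3,
            area_m2=sidecar["area_mm2"] * 1e-6,
        )
        r0 = sidecar.get("rtd_r0_ohm", RTD_R0_OHM)
        alpha = sidecar.get("rtd_alpha_per_k", RTD_ALPHA_PER_K)
        provenance = sidecar.get("provenance", "")
        seed = sidecar.get("seed")

    return RawSampleMeasurements(
        impedance=ImpedanceSpectrum(
            col("impedance", "frequency_hz"),
            col("impedance", "zmag_ohm"),
            col("impedance", "phase_deg"),
        ),
        loading=LoadingCurve(col("loading", "displacement_um"), col("loading", "force_mn")),
        relaxation=RelaxationCurve(
            col("relaxation", "time_s"), col("relaxation", "normalized_load")
        ),
        thermal=ThermalTrace(
            col("thermal", "heater_power_mw"),
            col("thermal", "t_source_c"),
            col("thermal", "r_sense_ohm"),
            rtd_r0_ohm=r0,
            rtd_alpha_per_k=alpha,
        ),
        geometry=geometry,
        provenance=provenance,
        seed=seed,
    )


def with_provenance(m: RawSampleMeasurements, text: str, seed: int | None = None):
    return replace(m, provenance=text, seed=seed)
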