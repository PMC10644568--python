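"""Extraction of the four biophysical features from raw modality curves.

Each extractor is the exact inverse of the corresponding synthetic-data
generator at zero noise, which is what makes the full pipeline testable end
to end without access to instrument data:

* ``Z`` at 15 kHz — log-frequency linear interpolation of |Z|;
* ``K`` — 1-D steady-state Fourier conduction, K = P d / (A dT), evaluated
  at the terminal 37 degC heating step;
* ``k`` — ordinary least-squares slope of force (mN) vs displacement (um)
  over the 18-22 % strain window (mN/um is numerically kN/m);
* ``%R`` — 100 (1 - F_n(150 s)), the endpoint relaxation of the normalized
  load.

All heater power is assumed to flow through the sample (any constant
partition factor rescales K identically across groups and cancels from every
group comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurements import (
    ImpedanceSpectrum,
    LoadingCurve,
    RawSampleMeasurements,
    RelaxationCurve,
    SampleGeometry,
    ThermalTrace,
)

__all__ = [
    "FeatureVector",
    "ModalityExtractionError",
    "impedance_at",
    "rtd_to_temperature",
    "thermal_conductivity",
    "stiffness",
    "percent_relaxation",
    "extract_features",
]

#: strain window over which the loading-curve slope is evaluated
STIFFNESS_STRAIN_WINDOW = (0.18, 0.22)
#: relaxation endpoint (s)
RELAXATION_ENDPOINT_S = 150.0
#: terminal heating step (degC)
TERMINAL_SOURCE_C = 37.0


class ModalityExtractionError(ValueError):
    """Extraction failed; carries the name of the failing modality."""

    def __init__(self, modality: str, message: str):
        self.modality = modality
        super().__init__(f"{modality}: {message}")


@dataclass(frozen=True)
class FeatureVector:
    Z_15k: float   # ohm
    K: float       # W m^-1 K^-1
    k_stiff: float # kN m^-1
    pctR: float    # %


def impedance_at(s: ImpedanceSpectrum, f: float = 15000.0) -> float:
    """|Z| at frequency ``f``, interpolated linearly in log-frequency."""
    grid = s.frequency_hz
    if not (grid[0] <= f <= grid[-1]):
        raise ValueError(
            f"frequency {f} Hz outside measured range [{grid[0]}, {grid[-1]}]"
        )
    return float(np.interp(np.log(f), np.log(grid), s.zmag_ohm))


def rtd_to_temperature(r: float, r0: float, alpha: float) -> float:
    """Invert the linear RTD law r = r0 (1 + alpha T) -> T in degC."""
    if r <= 0 or r0 <= 0 or alpha <= 0:
        raise ValueError("resistances and alpha must be positive")
    return (r / r0 - 1.0) / alpha


def thermal_conductivity(t: ThermalTrace, g: SampleGeometry) -> float:
    """K = P d / (A (T_source - T_sense)) at the terminal 37 degC step."""
    t_src = float(t.t_source_c[-1])
    if abs(t_src - TERMINAL_SOURCE_C) > 0.5:
        raise ValueError(
            f"terminal source step is {t_src} degC; expected {TERMINAL_SOURCE_C}"
        )
    t_sense = rtd_to_temperature(float(t.r_sense_ohm[-1]), t.rtd_r0_ohm, t.rtd_alpha_per_k)
    dt = t_src - t_sense
    if dt <= 0:
        raise ValueError(
            f"non-physical trace: T_sense ({t_sense:.2f}) >= T_source ({t_src:.2f})"
        )
    p_w = float(t.heater_power_mw[-1]) * 1e-3
    return p_w * g.thickness_m / (g.area_m2 * dt)


def stiffness(
    c: LoadingCurve,
    g: SampleGeometry,
    window: tuple[float, float] = STIFFNESS_STRAIN_WINDOW,
) -> float:
    """OLS slope of force vs displacement over the strain window, in kN/m.

    Strain is indentation depth / initial sample height.  The curve must
    reach the top of the window (nominally 22 % strain).
    """
    height_um = g.height_m * 1e6
    strain = c.displacement_um / height_um
    lo, hi = window
    if strain[-1] < hi:
        raise ValueError(
            f"curve reaches only {100 * strain[-1]:.1f}% strain; "
            f"need >= {100 * hi:.0f}%"
        )
    mask = (strain >= lo) & (strain <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 samples inside the strain window")
    slope = np.polyfit(c.displacement_um[mask], c.force_mn[mask], 1)[0]
    return float(slope)  # mN/um == kN/m


def percent_relaxation(c: RelaxationCurve) -> float:
    """%R = 100 (1 - F_n(150 s)); F_n(150) by linear interpolation."""
    if c.time_s[-1] < RELAXATION_ENDPOINT_S - 1e-9:
        raise ValueError(
            f"trace ends at {c.time_s[-1]} s; need >= {RELAXATION_ENDPOINT_S} s"
        )
    fn_end = float(np.interp(RELAXATION_ENDPOINT_S, c.time_s, c.normalized_load))
    return 100.0 * (1.0 - fn_end)


def extract_features(m: RawSampleMeasurements) -> FeatureVector:
    """All four features from one sample; errors name the failing modality."""

    def attempt(modality, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise ModalityExtractionError(modality, str(exc)) from exc

    return FeatureVector(
        Z_15k=attempt("impedance", impedance_at, m.impedance),
        K=attempt("thermal", thermal_conductivity, m.thermal, m.geometry),
        k_stiff=attempt("loading", stiffness, m.loading, m.geometry),
        pctR=attempt("relaxation", percent_relaxation, m.relaxation),
    )
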