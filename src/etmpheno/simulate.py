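"""Synthetic raw-measurement generator for AN/FA/CA cohorts.

No raw instrument data for the study is public, so every downstream stage is
exercised on synthetic bundles whose *extracted* features follow the
published per-group feature distributions (group mean, and SD recovered as
SEM * sqrt(n)), and whose impedance spectra come from the Cole-type
equivalent circuit with the published per-group element values.

Per sample the generator draws the four feature targets log-normally (which
keeps them positive), draws circuit elements log-normally around the group
nominal values, and then rescales the circuit uniformly (resistances x s,
capacitances / s) so the noise-free spectrum passes exactly through the
drawn impedance target at 15 kHz.  Each modality curve is built so the
corresponding extractor inverts it exactly at zero noise:

* loading: F(d) = C (exp(b d) - 1) with b = 2/height and C chosen so
  dF/dd = k_target at 20 % strain;
* relaxation: F_n(t) = 1 - A (1 - exp(-t/tau)) with the 150 s endpoint
  pinned at pctR_target;
* thermal: T_sense = T_source - P d / (A K_target) per step, reported as
  RTD resistance.

All generators are pure functions of (config, rng): a fixed seed reproduces
the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import CircuitParams, circuit_impedance
from .cohort import GROUPS, CohortTable, TissueRecord, load_cohort_fixture
from .measurements import (
    ImpedanceSpectrum,
    LoadingCurve,
    RawSampleMeasurements,
    RelaxationCurve,
    SampleGeometry,
    ThermalTrace,
)

__all__ = [
    "NoiseConfig",
    "GroupGenConfig",
    "default_group_configs",
    "default_frequency_grid",
    "generate_impedance_spectrum",
    "generate_loading_curve",
    "generate_relaxation_curve",
    "generate_thermal_trace",
    "generate_sample",
    "generate_cohort",
]

#: published per-group nominal circuit elements (C_dl is not quoted in the
#: source text; 1e-7 F affects only the sub-100 Hz region)
GROUP_CIRCUITS = {
    "AN": CircuitParams(C_dl=1e-7, R_e=2.27e4, R_i=1.23e4, R_m=9.27e4, C_m=1.10e-11),
    "FA": CircuitParams(C_dl=1e-7, R_e=3.51e4, R_i=1.30e4, R_m=5.48e6, C_m=1.11e-11),
    "CA": CircuitParams(C_dl=1e-7, R_e=1.75e5, R_i=3.29e4, R_m=6.43e4, C_m=1.02e-10),
}

MAX_LOAD_MN = 30.0          # instrument force cap during indentation
RELAXATION_DURATION_S = 150.0


@dataclass(frozen=True)
class NoiseConfig:
    """Additive/relative measurement noise per modality.

    Magnitudes are placeholders for the unpublished instrument noise,
    bounded well below the maximum 6.5 % coefficient of variation reported
    for repeat measurements.
    """

    zmag_rel: float = 0.02      # relative |Z| noise
    phase_deg: float = 1.0      # additive phase noise, degrees
    force_mn: float = 0.2       # additive force noise, mN
    temp_c: float = 0.05        # RTD temperature noise, degC
    load_norm: float = 0.002    # additive noise on the normalized load

    def __post_init__(self) -> None:
        if min(self.zmag_rel, self.phase_deg, self.force_mn,
               self.temp_c, self.load_norm) < 0:
            raise ValueError("noise levels must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroupGenConfig:
    """Generating distribution for one tissue group.

    Feature means/SDs default to the published group distributions; ``tau``
    (the relaxation time constant, s) is unconstrained by the endpoint
    feature and fixed at 30 s for all groups.
    """

    group: str
    circuit: CircuitParams
    circuit_cv: float           # inter-subject CV of each circuit element
    Z_mean: float               # ohm, at 15 kHz
    Z_sd: float
    K_mean: float               # W m^-1 K^-1
    K_sd: float
    k_mean: float               # kN m^-1
    k_sd: float
    pctR_mean: float            # %
    pctR_sd: float
    tau_s: float = 30.0
    heater_power_mw: float = 5.0
    ambient_c: float = 20.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    geometry: SampleGeometry = field(default_factory=SampleGeometry)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("Z_mean", "K_mean", "k_mean", "pctR_mean", "tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("Z_sd", "K_sd", "k_sd", "pctR_sd", "circuit_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_group_configs(
    noise: NoiseConfig | None = None, circuit_cv: float = 0.10
) -> dict[str, GroupGenConfig]:
    """Per-group configs derived from the bundled cohort (SD = SEM sqrt n)."""
    fixture = load_cohort_fixture()
    noise = noise if noise is not None else NoiseConfig()
    configs = {}
    for g in GROUPS:
        stats = {}
        for modality, prefix in (("Z", "Z"), ("K", "K"), ("k", "k"), ("%R", "pctR")):
            v = fixture.values(modality, g)
            stats[f"{prefix}_mean"] = float(v.mean())
            stats[f"{prefix}_sd"] = float(v.std(ddof=0))  # == SEM * sqrt(n)
        configs[g] = GroupGenConfig(
            group=g, circuit=GROUP_CIRCUITS[g], circuit_cv=circuit_cv,
            noise=noise, **stats,
        )
    return configs


def default_frequency_grid(n: int = 100) -> np.ndarray:
    """Log-spaced measurement grid over the instrument's 10 Hz - 3 MHz sweep."""
    return np.logspace(1.0, np.log10(3e6), n)


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw with the given arithmetic mean and SD (moment-matched)."""
    if sd == 0:
        return mean
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return float(rng.lognormal(mu, np.sqrt(s2)))


def generate_impedance_spectrum(
    p: CircuitParams,
    grid: np.ndarray | None = None,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ImpedanceSpectrum:
    """Forward circuit spectrum on ``grid`` plus measurement noise."""
    grid = default_frequency_grid() if grid is None else np.asarray(grid, float)
    if np.any(grid <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if grid[0] < 10.0 - 1e-9 or grid[-1] > 3e6 + 1e-3:
        raise ValueError("grid must lie within the 10 Hz - 3 MHz sweep")
    noise = noise if noise is not None else NoiseConfig()
    rng = rng if rng is not None else np.random.default_rng()
    z = circuit_impedance(p, grid)
    mag = np.abs(z) * (1.0 + noise.zmag_rel * rng.standard_normal(grid.size))
    phase = np.rad2deg(np.angle(z)) + noise.phase_deg * rng.standard_normal(grid.size)
    return ImpedanceSpectrum(grid, np.maximum(mag, 1e-12), phase)


def generate_loading_curve(
    k_target: float,
    geom: SampleGeometry | None = None,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    step_um: float = 2.0,
) -> LoadingCurve:
    """Exponential contact curve with slope ``k_target`` (kN/m) at 20 % strain.

    F(d) = C (exp(b d) - 1), b = 2/height, C = k_target / (b exp(0.4)).
    The instrument's 30 mN cap truncates the sweep, but never before 24 %
    strain (the stiffness window must stay measurable); for very stiff
    samples the modelled load in the window may therefore exceed the cap.
    """
    if k_target <= 0:
        raise ValueError("k_target must be positive")
    geom = geom if geom is not None else SampleGeometry()
    noise = noise if noise is not None else NoiseConfig()
    rng = rng if rng is not None else np.random.default_rng()
    h_um = geom.height_m * 1e6
    b = 2.0 / h_um                      # 1/um
    c_mn = k_target / (b * np.exp(0.4))  # k_target in mN/um == kN/m
    d_cap = np.log1p(MAX_LOAD_MN / c_mn) / b
    d_end = float(np.clip(d_cap, 0.24 * h_um, 0.45 * h_um))
    disp = np.arange(0.0, d_end, step_um)
    disp = np.append(disp, d_end)  # close the sweep exactly at the cap
    force = c_mn * np.expm1(b * disp)
    force = force + noise.force_mn * rng.standard_normal(disp.size)
    force[0] = max(force[0], 0.0)
    return LoadingCurve(disp, force)


def generate_relaxation_curve(
    pctR_target: float,
    tau: float = 30.0,
    duration: float = RELAXATION_DURATION_S,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    n_points: int = 151,
) -> RelaxationCurve:
    """Exponential relaxation whose 150 s endpoint equals ``pctR_target``.

    F_n(t) = 1 - A (1 - exp(-t/tau)), A = (pctR/100) / (1 - exp(-150/tau)).
    """
    if not 0.0 < pctR_target < 100.0:
        raise ValueError("pctR_target must lie strictly between 0 and 100")
    if tau <= 0:
        raise ValueError("tau must be positive")
    noise = noise if noise is not None else NoiseConfig()
    rng = rng if rng is not None else np.random.default_rng()
    t = np.linspace(0.0, duration, n_points)
    amp = (pctR_target / 100.0) / -np.expm1(-RELAXATION_DURATION_S / tau)
    fn = 1.0 + amp * np.expm1(-t / tau)
    fn = fn + noise.load_norm * rng.standard_normal(t.size)
    return RelaxationCurve(t, fn)


def generate_thermal_trace(
    k_thermal_target: float,
    geom: SampleGeometry | None = None,
    heater_power_mw: float = 5.0,
    t_source_c: np.ndarray | None = None,
    ambient_c: float = 20.0,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ThermalTrace:
    """Stepwise heating trace for a sample of conductivity ``k_thermal_target``.

    ``heater_power_mw`` is the power at the terminal 37 degC step; holding a
    lower source temperature takes proportionally less power,
    P_i = P * (T_i - ambient) / (37 - ambient).  The sense-side temperature
    at each step is T_source - P_i d / (A K), reported through the linear
    RTD law.  Parameter combinations that would push the sense side to or
    below ambient are rejected as non-physical.
    """
    if k_thermal_target <= 0:
        raise ValueError("thermal conductivity target must be positive")
    geom = geom if geom is not None else SampleGeometry()
    noise = noise if noise is not None else NoiseConfig()
    rng = rng if rng is not None else np.random.default_rng()
    steps = (
        np.array([25.0, 28.0, 31.0, 34.0, 37.0])
        if t_source_c is None
        else np.asarray(t_source_c, float)
    )
    if np.any(steps <= ambient_c):
        raise ValueError("source steps must exceed ambient")
    power_mw = heater_power_mw * (steps - ambient_c) / (steps[-1] - ambient_c)
    dt = power_mw * 1e-3 * geom.thickness_m / (geom.area_m2 * k_thermal_target)
    t_sense = steps - dt
    if np.min(t_sense) <= ambient_c:
        raise ValueError(
            f"sense temperature {np.min(t_sense):.2f} degC would not exceed "
            f"ambient ({ambient_c} degC); lower the heater power or raise K"
        )
    t_noisy = t_sense + noise.temp_c * rng.standard_normal(steps.size)
    from .measurements import RTD_ALPHA_PER_K, RTD_R0_OHM

    r_sense = RTD_R0_OHM * (1.0 + RTD_ALPHA_PER_K * t_noisy)
    return ThermalTrace(power_mw, steps, r_sense)


def _draw_valid_k_thermal(cfg: GroupGenConfig, rng, max_tries: int = 100) -> float:
    """Rejection-sample K so the thermal trace stays physical (rare rejections)."""
    dt_limit = 37.0 - cfg.ambient_c - 0.5
    p_w = cfg.heater_power_mw * 1e-3
    for _ in range(max_tries):
        k = _lognormal(rng, cfg.K_mean, cfg.K_sd)
        if p_w * cfg.geometry.thickness_m / (cfg.geometry.area_m2 * k) < dt_limit:
            return k
    raise RuntimeError("could not draw a thermal conductivity consistent with "
                       "the heater power and ambient temperature")


def generate_sample(
    cfg: GroupGenConfig, rng: np.random.Generator, subject_id: str
) -> tuple[RawSampleMeasurements, TissueRecord, CircuitParams]:
    """One synthetic sample: raw curves, ground-truth features, true circuit."""
    z_target = _lognormal(rng, cfg.Z_mean, cfg.Z_sd)
    k_thermal = _draw_valid_k_thermal(cfg, rng)
    k_stiff = _lognormal(rng, cfg.k_mean, cfg.k_sd)
    pctr = float(np.clip(_lognormal(rng, cfg.pctR_mean, cfg.pctR_sd), 1.0, 95.0))

    base = cfg.circuit.as_array()
    drawn = np.array([_lognormal(rng, v, cfg.circuit_cv * v) for v in base])
    p_draw = CircuitParams.from_array(drawn)
    scale = z_target / abs(circuit_impedance(p_draw, 15000.0))
    p_true = p_draw.scaled(scale)

    m = RawSampleMeasurements(
        impedance=generate_impedance_spectrum(p_true, noise=cfg.noise, rng=rng),
        loading=generate_loading_curve(k_stiff, cfg.geometry, cfg.noise, rng),
        relaxation=generate_relaxation_curve(pctr, cfg.tau_s, noise=cfg.noise, rng=rng),
        thermal=generate_thermal_trace(
            k_thermal, cfg.geometry, cfg.heater_power_mw,
            ambient_c=cfg.ambient_c, noise=cfg.noise, rng=rng,
        ),
        geometry=cfg.geometry,
        provenance=f"synthetic {cfg.group} sample",
    )
    truth = TissueRecord(subject_id, cfg.group, z_target, k_thermal, k_stiff, pctr)
    return m, truth, p_true


def generate_cohort(
    configs: dict[str, GroupGenConfig] | None = None,
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[list[RawSampleMeasurements], CohortTable, dict[str, CircuitParams]]:
    """A full synthetic cohort, reproducible for a fixed seed.

    Defaults to the study's cohort shape (14 AN, 4 FA, 10 CA).  Returns the
    raw bundles (ordered as the ground-truth table), the ground-truth
    feature table, and the true circuit elements keyed by sample id.
    """
    configs = configs if configs is not None else default_group_configs()
    n_per_group = n_per_group if n_per_group is not None else {"AN": 14, "FA": 4, "CA": 10}
    for g, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"n_per_group[{g!r}] must be >= 1")
        if g not in configs:
            raise KeyError(f"no generator config for group {g!r}")

    n_total = sum(n_per_group.values())
    streams = np.random.SeedSequence(seed).spawn(n_total)
    measurements: list[RawSampleMeasurements] = []
    records: list[TissueRecord] = []
    circuits: dict[str, CircuitParams] = {}
    i = 0
    for g in GROUPS:
        for j in range(n_per_group.get(g, 0)):
            rng = np.random.default_rng(streams[i])
            sid = f"{g}{j + 1:02d}"
            m, rec, p = generate_sample(configs[g], rng, sid)
            m = replace(m, provenance=f"synthetic {g} sample {sid} (seed {seed})",
                        seed=seed)
            measurements.append(m)
            records.append(rec)
            circuits[sid] = p
            i += 1
    return measurements, CohortTable(records), circuits
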