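import dataclasses

import numpy as np
import pytest

from etmpheno import (
    extract_features,
    impedance_at,
    percent_relaxation,
    rtd_to_temperature,
    stiffness,
    thermal_conductivity,
)
from etmpheno.circuit import circuit_impedance
from etmpheno.features import ModalityExtractionError
from etmpheno.measurements import (
    ImpedanceSpectrum,
    LoadingCurve,
    RelaxationCurve,
    SampleGeometry,
    ThermalTrace,
    RTD_ALPHA_PER_K,
    RTD_R0_OHM,
)
from etmpheno.simulate import (
    GROUP_CIRCUITS,
    NoiseConfig,
    generate_loading_curve,
    generate_relaxation_curve,
    generate_sample,
    generate_thermal_trace,
)

GEOM = SampleGeometry()
ZERO = NoiseConfig.zero()


# ---------------------------------------------------------------- impedance

def test_impedance_at_exact_grid_point():
    s = ImpedanceSpectrum([1e3, 15e3, 1e5], [9.0, 5.0, 2.0], [0, 0, 0])
    assert impedance_at(s, 15000.0) == 5.0


def test_impedance_at_flat_spectrum_any_frequency():
    s = ImpedanceSpectrum(np.logspace(1, 6, 30), np.full(30, 7.5), np.zeros(30))
    for f in (10.0, 123.0, 15000.0, 1e6):
        assert impedance_at(s, f) == pytest.approx(7.5)


def test_impedance_at_outside_grid():
    s = ImpedanceSpectrum([1e3, 1e4], [2.0, 1.0], [0, 0])
    with pytest.raises(ValueError, match="outside"):
        impedance_at(s, 15000.0)


def test_impedance_interpolation_matches_forward_model(rng):
    from etmpheno.simulate import generate_impedance_spectrum

    s = generate_impedance_spectrum(GROUP_CIRCUITS["CA"], noise=ZERO, rng=rng)
    direct = abs(circuit_impedance(GROUP_CIRCUITS["CA"], 15000.0))
    assert impedance_at(s) == pytest.approx(direct, rel=0.005)


# ---------------------------------------------------------------- RTD / thermal

def test_rtd_law():
    assert rtd_to_temperature(RTD_R0_OHM, RTD_R0_OHM, RTD_ALPHA_PER_K) == 0.0
    r37 = RTD_R0_OHM * (1 + 37 * RTD_ALPHA_PER_K)
    assert rtd_to_temperature(r37, RTD_R0_OHM, RTD_ALPHA_PER_K) == pytest.approx(37.0)
    with pytest.raises(ValueError):
        rtd_to_temperature(-1.0, RTD_R0_OHM, RTD_ALPHA_PER_K)


def test_thermal_round_trip_at_an_mean(rng):
    t = generate_thermal_trace(0.45, GEOM, noise=ZERO, rng=rng)
    assert thermal_conductivity(t, GEOM) == pytest.approx(0.45, rel=1e-12)


def test_thermal_hand_computed_example():
    """K = P d / (A dT): with P = 100 mW, d = 4 mm, A = 16 mm^2 and
    K = 0.189, dT = 0.1*0.004/(16e-6*0.189) = 132.275... K by hand."""
    dt = 0.1 * 0.004 / (16e-6 * 0.189)
    t_sense = 37.0 - dt
    trace = ThermalTrace(
        heater_power_mw=[100.0],
        t_source_c=[37.0],
        r_sense_ohm=[RTD_R0_OHM * (1 + RTD_ALPHA_PER_K * t_sense)],
    )
    assert thermal_conductivity(trace, GEOM) == pytest.approx(0.189, rel=1e-9)


def test_thermal_halving_with_doubled_gradient():
    def trace(dt):
        return ThermalTrace([10.0], [37.0], [RTD_R0_OHM * (1 + RTD_ALPHA_PER_K * (37 - dt))])

    k1 = thermal_conductivity(trace(4.0), GEOM)
    k2 = thermal_conductivity(trace(8.0), GEOM)
    assert k2 == pytest.approx(k1 / 2)


def test_thermal_rejects_inverted_gradient():
    trace = ThermalTrace([10.0], [37.0], [RTD_R0_OHM * (1 + RTD_ALPHA_PER_K * 38.0)])
    with pytest.raises(ValueError, match="non-physical"):
        thermal_conductivity(trace, GEOM)


# ---------------------------------------------------------------- stiffness

def test_stiffness_of_exact_linear_curve():
    d = np.linspace(0, 1000, 200)
    assert stiffness(LoadingCurve(d, 0.05 * d), GEOM) == pytest.approx(0.05, rel=1e-9)


def test_stiffness_round_trip_at_ca_mean(rng):
    c = generate_loading_curve(0.076, GEOM, ZERO, rng)
    assert stiffness(c, GEOM) == pytest.approx(0.076, rel=0.01)


def test_stiffness_requires_strain_range():
    d = np.linspace(0, 0.15 * GEOM.height_m * 1e6, 100)  # only 15 % strain
    with pytest.raises(ValueError, match="strain"):
        stiffness(LoadingCurve(d, 0.01 * d), GEOM)


def test_stiffness_subsampling_invariance(rng):
    c = generate_loading_curve(0.02, GEOM, ZERO, rng, step_um=1.0)
    k_full = stiffness(c, GEOM)
    for factor in (2, 4):
        sub = LoadingCurve(c.displacement_um[::factor], c.force_mn[::factor])
        assert stiffness(sub, GEOM) == pytest.approx(k_full, rel=0.02)


# ---------------------------------------------------------------- relaxation

def test_percent_relaxation_constant_load():
    c = RelaxationCurve(np.linspace(0, 150, 51), np.ones(51))
    assert percent_relaxation(c) == 0.0


def test_percent_relaxation_two_point_trace():
    assert percent_relaxation(RelaxationCurve([0.0, 150.0], [1.0, 0.5])) == pytest.approx(50.0)


def test_percent_relaxation_round_trip_at_fa_mean(rng):
    c = generate_relaxation_curve(47.8, tau=30.0, noise=ZERO, rng=rng)
    assert percent_relaxation(c) == pytest.approx(47.8, abs=1e-9)


def test_percent_relaxation_short_trace():
    c = RelaxationCurve(np.linspace(0, 100, 11), np.linspace(1, 0.8, 11))
    with pytest.raises(ValueError, match="150"):
        percent_relaxation(c)


# ---------------------------------------------------------------- composition

def test_extract_features_zero_noise_round_trip(noiseless_configs, rng):
    for g, cfg in noiseless_configs.items():
        m, truth, _ = generate_sample(cfg, rng, f"{g}X")
        fv = extract_features(m)
        assert fv.Z_15k == pytest.approx(truth.Z_15k, rel=0.005)
        assert fv.K == pytest.approx(truth.K, rel=1e-9)
        assert fv.k_stiff == pytest.approx(truth.k_stiff, rel=0.01)
        assert fv.pctR == pytest.approx(truth.pctR, abs=1e-9)


def test_extract_features_names_failing_modality(small_synth):
    ms, _, _ = small_synth
    short = RelaxationCurve(np.linspace(0, 100, 21), np.linspace(1, 0.7, 21))
    broken = dataclasses.replace(ms[0], relaxation=short)
    with pytest.raises(ModalityExtractionError, match="relaxation"):
        extract_features(broken)


def test_extraction_is_deterministic(small_synth):
    ms, _, _ = small_synth
    assert extract_features(ms[0]) == extract_features(ms[0])
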