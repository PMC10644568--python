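"""Equivalent-circuit model of the tissue-electrode impedance.

The tissue is modelled as a single-dispersion Cole-type lumped circuit: the
extracellular resistance ``R_e`` in parallel with the series combination of
the intracellular resistance ``R_i`` and a leaky membrane (membrane
resistance ``R_m`` in parallel with the membrane capacitance ``C_m``).  The
double-layer capacitance ``C_dl`` at each of the two tissue-electrode
interfaces appears in series, contributing ``2 / (j omega C_dl)``:

    Z(omega) = 2/(j omega C_dl) + R_e || (R_i + R_m / (1 + j omega R_m C_m))

with ``a || b = a b / (a + b)``.

Identifiability
---------------
The tissue core is a bilinear function of ``j omega`` and therefore carries
only three independent degrees of freedom — the low-frequency plateau ``R0``,
the high-frequency plateau ``Rinf`` and the dispersion time constant ``tau``
— while it is parameterized by four circuit elements.  A one-dimensional
continuum of positive ``(R_e, R_i, R_m, C_m)`` sets produces *identical*
spectra.  Consequently a fit determines ``(C_dl, R0, Rinf, tau)`` sharply but
the individual elements only up to that flat direction; see
:func:`identifiable_quantities`.

:func:`fit_circuit` resolves the gauge freedom deterministically: after
optimization the solution is slid along the degenerate manifold to the
(unique) member whose ratio ``R_i / R_e`` equals that of the initial guess.
The data cannot constrain this ratio, so it is inherited from the init —
which is why fits are initialized from group-nominal element values, and
why a fit started from a uniformly rescaled version of the true elements
recovers them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .measurements import ImpedanceSpectrum

__all__ = [
    "CircuitParams",
    "FitResult",
    "circuit_impedance",
    "identifiable_quantities",
    "fit_circuit",
    "group_parameter_summary",
]


@dataclass(frozen=True)
class CircuitParams:
    """Elements of the modified Cole circuit (SI units: F and ohm)."""

    C_dl: float  # double-layer capacitance per interface
    R_e: float   # extracellular resistance
    R_i: float   # intracellular resistance
    R_m: float   # membrane resistance
    C_m: float   # membrane capacitance

    def __post_init__(self) -> None:
        if min(self.C_dl, self.R_e, self.R_i, self.R_m, self.C_m) <= 0:
            raise ValueError("all circuit parameters must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.C_dl, self.R_e, self.R_i, self.R_m, self.C_m])

    @classmethod
    def from_array(cls, a) -> "CircuitParams":
        return cls(*(float(v) for v in a))

    def scaled(self, s: float) -> "CircuitParams":
        """Uniform impedance rescale: resistances x s, capacitances / s.

        Leaves the shape of the spectrum unchanged and multiplies Z(omega)
        by exactly s at every frequency.
        """
        return CircuitParams(self.C_dl / s, self.R_e * s, self.R_i * s,
                             self.R_m * s, self.C_m / s)


def circuit_impedance(p: CircuitParams, f) -> np.ndarray | complex:
    """Complex impedance of the circuit at frequency ``f`` (Hz, > 0)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be strictly positive")
    w = 2.0 * np.pi * f_arr
    z_mem = p.R_m / (1.0 + 1j * w * p.R_m * p.C_m)
    branch = p.R_i + z_mem
    core = p.R_e * branch / (p.R_e + branch)
    z = 2.0 / (1j * w * p.C_dl) + core
    return z if np.ndim(f) else complex(z)


def identifiable_quantities(p: CircuitParams) -> dict[str, float]:
    """The spectrally identifiable combinations of the circuit elements.

    Returns ``C_dl`` together with the tissue core's low-frequency plateau
    ``R0 = R_e (R_i + R_m) / (R_e + R_i + R_m)``, high-frequency plateau
    ``Rinf = R_e R_i / (R_e + R_i)`` and dispersion time constant
    ``tau = R_m C_m (R_e + R_i) / (R_e + R_i + R_m)``.
    """
    total = p.R_e + p.R_i + p.R_m
    return {
        "C_dl": p.C_dl,
        "R0": p.R_e * (p.R_i + p.R_m) / total,
        "Rinf": p.R_e * p.R_i / (p.R_e + p.R_i),
        "tau": p.R_m * p.C_m * (p.R_e + p.R_i) / total,
    }


def _gauge_fix(p: CircuitParams, init: CircuitParams) -> CircuitParams:
    """Slide ``p`` along the spectrally flat direction to the manifold member
    with the init's ``R_i / R_e`` ratio (identifiable quantities unchanged).

    Falls back to ``p`` unchanged when no positive member with that ratio
    exists (possible for inits far from the data's manifold).
    """
    q = identifiable_quantities(p)
    a, b, tau = q["R0"], q["Rinf"], q["tau"]
    rho = init.R_i / init.R_e
    r_e = b * (1.0 + rho) / rho
    r_i = rho * r_e
    denom = r_e - a
    if denom <= 0:
        return p
    r_m = (a * (r_e + r_i) - r_e * r_i) / denom
    if not np.isfinite(r_m) or r_m <= 0:
        return p
    c_m = tau * (r_e + r_i + r_m) / (r_m * (r_e + r_i))
    if not np.isfinite(c_m) or c_m <= 0:
        return p
    return CircuitParams(p.C_dl, r_e, r_i, r_m, c_m)


@dataclass(frozen=True)
class FitResult:
    params: CircuitParams
    param_uncertainties: np.ndarray  # 1-sigma, same order/units as params
    residual_norm: float             # RMS of the weighted complex residual
    converged: bool


def _residuals(log10_p: np.ndarray, f: np.ndarray, z: np.ndarray) -> np.ndarray:
    p = CircuitParams.from_array(10.0 ** log10_p)
    r = (circuit_impedance(p, f) - z) / np.abs(z)
    return np.concatenate([r.real, r.imag])


def fit_circuit(
    s: ImpedanceSpectrum,
    init: CircuitParams,
    bounds_decades: float = 3.0,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Weighted complex least-squares fit of the circuit to a spectrum.

    Magnitude and phase are fitted jointly through the complex impedance,
    each point weighted by 1/|Z| (relative error).  Parameters are searched
    in log10 space within ``bounds_decades`` decades of the initial guess;
    ``n_starts`` multi-starts (the init plus seeded log-uniform
    perturbations) guard against local minima.  Solutions whose cost ties
    with the best within 1e-9 relative are resolved in favour of the one
    closest to the init in log space (see the module note on the flat
    direction of the parameterization).

    Requires at least 10 grid points spanning at least 3 decades.
    """
    f = s.frequency_hz
    if f.size < 10:
        raise ValueError(f"need >= 10 grid points to fit, got {f.size}")
    if np.log10(f[-1] / f[0]) < 3.0:
        raise ValueError("spectrum must span at least 3 frequency decades")
    z = s.complex_z

    l0 = np.log10(init.as_array())
    lo, hi = l0 - bounds_decades, l0 + bounds_decades
    rng = np.random.default_rng(seed)
    starts = [l0] + [
        np.clip(l0 + rng.uniform(-1.0, 1.0, size=5), lo, hi)
        for _ in range(max(0, n_starts - 1))
    ]

    solutions = []
    for start in starts:
        try:
            res = least_squares(
                _residuals, start, args=(f, z), bounds=(lo, hi),
                method="trf", x_scale="jac", max_nfev=2000,
            )
        except Exception:
            continue
        if np.all(np.isfinite(res.x)):
            solutions.append(res)
    if not solutions:
        return FitResult(init, np.full(5, np.nan), np.inf, converged=False)

    best_cost = min(r.cost for r in solutions)
    tied = [r for r in solutions if r.cost <= best_cost * (1 + 1e-9) + 1e-300]
    res = min(tied, key=lambda r: float(np.linalg.norm(r.x - l0)))

    params = _gauge_fix(CircuitParams.from_array(10.0 ** res.x), init)
    m = res.fun.size
    residual_norm = float(np.sqrt(2.0 * res.cost / m))
    # 1-sigma from the Jacobian pseudo-inverse (log space -> linear units);
    # huge values along the flat direction are expected and honest.
    try:
        jtj = res.jac.T @ res.jac
        cov_log = np.linalg.pinv(jtj) * max(2.0 * res.cost / max(m - 5, 1), 1e-300)
        sigma_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        uncert = params.as_array() * np.log(10.0) * sigma_log
    except Exception:
        uncert = np.full(5, np.nan)
    converged = bool(res.status > 0)
    return FitResult(params, uncert, residual_norm, converged)


def group_parameter_summary(fits, groups) -> "pd.DataFrame":
    """Per-group mean +/- SEM of fitted circuit elements.

    ``fits`` and ``groups`` are parallel sequences (one fit per sample).
    SEM follows the population-SD convention (divisor n), matching the
    summary convention used throughout this package; a single-member group
    reports SEM 0.
    """
    import pandas as pd

    fits = list(fits)
    groups = list(groups)
    if len(fits) != len(groups):
        raise ValueError("fits and groups must have equal length")
    if not fits:
        raise ValueError("no fits given")
    names = ["C_dl", "R_e", "R_i", "R_m", "C_m"]
    rows = []
    for g in dict.fromkeys(groups):  # preserve first-seen order
        arr = np.array([fr.params.as_array() for fr, gg in zip(fits, groups) if gg == g])
        if arr.size == 0:
            raise ValueError(f"empty group {g!r}")
        n = arr.shape[0]
        for j, name in enumerate(names):
            rows.append(
                {
                    "group": g,
                    "parameter": name,
                    "n": n,
                    "mean": arr[:, j].mean(),
                    "sem": arr[:, j].std(ddof=0) / np.sqrt(n),
                }
            )
    return pd.DataFrame(rows)
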