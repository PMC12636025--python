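"""Eyring transition-state-theory kinetics and progress-curve analysis.

The Eyring equation with unit transmission coefficient,

    k = (k_B·T/h) · exp(−ΔG‡ / R·T) ,

interconverts a first-order rate constant (s⁻¹) and a phenomenological
activation free energy (kcal·mol⁻¹).  Progress curves (product
concentration vs time) yield a turnover frequency from the initial slope, a
total turnover number from the final titer, and — when first-order enzyme
inactivation flattens the curve — a fitted plateau P_∞(1 − e^{−κt}).
A Beer–Lambert helper converts spectrophotometric slopes to rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .constants import KB_OVER_H, R_KCAL

__all__ = [
    "RateMeasurement",
    "ProgressCurve",
    "KineticsSummary",
    "barrier_from_rate",
    "rate_from_barrier",
    "tof_ttn",
    "rate_from_absorbance",
]


@dataclass
class RateMeasurement:
    """A first-order rate constant k (s⁻¹) at temperature T (K)."""

    k: float
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ProgressCurve:
    """Product concentration (μM) vs time (h) at enzyme concentration (μM).

    The enzyme amount may alternatively be given as a mass (mg) with a molar
    mass (g·mol⁻¹) and reaction volume (mL); there is no default molar mass.
    """

    times_h: np.ndarray
    conc_uM: np.ndarray
    enzyme_uM: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        if self.times_h.shape != self.conc_uM.shape:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(self.times_h) <= 0) or np.any(self.times_h < 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if not np.all(np.isfinite(self.conc_uM)):
            raise ValueError("concentrations must be finite")
        if self.enzyme_uM <= 0:
            raise ValueError("enzyme concentration must be positive")

    @classmethod
    def from_enzyme_mass(
        cls,
        times_h,
        conc_uM,
        enzyme_mg: float,
        molar_mass_g_mol: float,
        volume_mL: float,
    ) -> "ProgressCurve":
        enzyme_uM = enzyme_mg / molar_mass_g_mol / (volume_mL * 1e-3) * 1e3
        return cls(times_h, conc_uM, enzyme_uM)


@dataclass
class KineticsSummary:
    """Turnover frequency (s⁻¹), total turnover number, plateau (μM)."""

    tof_s: float
    ttn: float
    plateau_uM: float
    plateau_fit_converged: bool
    k_obs_per_h: float | None = None
    diagnostics: dict = field(default_factory=dict)


def barrier_from_rate(m: RateMeasurement) -> float:
    """Activation free energy ΔG‡ (kcal·mol⁻¹) from an Eyring inversion,
    transmission coefficient 1."""
    return R_KCAL * m.temperature * np.log(KB_OVER_H * m.temperature / m.k)


def rate_from_barrier(dg_act: float, temperature: float) -> float:
    """Eyring rate constant (s⁻¹) for a barrier ΔG‡ (kcal·mol⁻¹) at T (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_OVER_H * temperature * np.exp(-dg_act / (R_KCAL * temperature))


def _plateau_model(t, p_inf, k):
    return p_inf * -np.expm1(-k * t)


def tof_ttn(curve: ProgressCurve, initial_window_h: float | None = None) -> KineticsSummary:
    """Turnover statistics from a progress curve.

    TOF is the least-squares slope of concentration vs time over the initial
    window (default: through the third time point), converted to s⁻¹ and
    divided by the enzyme concentration — an apparent k_cat.  TTN is the
    final product concentration over the enzyme concentration.  The plateau
    is the asymptote of a fitted single-exponential rise; if the fit fails
    to converge the maximum observed concentration is reported instead and
    flagged.
    """
    t, p = curve.times_h, curve.conc_uM
    if initial_window_h is None:
        if t.size < 2:
            raise ValueError("progress curve needs at least 2 points")
        initial_window_h = t[min(2, t.size - 1)]
    mask = t <= initial_window_h + 1e-12
    if mask.sum() < 2:
        raise ValueError("initial window must contain at least 2 points")
    reg = linregress(t[mask], p[mask])
    v0_uM_h = reg.slope
    tof_s = v0_uM_h / 3600.0 / curve.enzyme_uM
    ttn = p[-1] / curve.enzyme_uM

    converged = True
    k_obs = None
    try:
        p0 = [max(p.max(), 1e-9), 1.0 / max(t[-1], 1e-9)]
        popt, _ = curve_fit(_plateau_model, t, p, p0=p0, maxfev=10000)
        plateau = float(popt[0])
        k_obs = float(popt[1])
        if plateau <= 0 or not np.isfinite(plateau):
            raise RuntimeError("non-physical plateau")
    except (RuntimeError, ValueError):
        plateau = float(p.max())
        converged = False
    return KineticsSummary(
        tof_s=float(tof_s),
        ttn=float(ttn),
        plateau_uM=plateau,
        plateau_fit_converged=converged,
        k_obs_per_h=k_obs,
        diagnostics={"v0_uM_per_h": float(v0_uM_h), "r_value": float(reg.rvalue)},
    )


def rate_from_absorbance(
    slope_au_min: float, epsilon_mM_cm: float, pathlength_cm: float = 1.0
) -> float:
    """Beer–Lambert conversion of an absorbance slope (AU·min⁻¹) to a
    chromophore production rate (mM·min⁻¹)."""
    if epsilon_mM_cm <= 0 or pathlength_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    return slope_au_min / (epsilon_mM_cm * pathlength_cm)
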