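"""Harmonic normal-mode analysis and vibrational thermochemistry.

A Cartesian Hessian of the QM subsystem (kcal·mol⁻¹·Å⁻²) is mass-weighted,
optionally purged of overall translation/rotation, and diagonalised.
Eigenvalues map to wavenumbers as sign(λ)·sqrt(|λ|)·conv; negative
wavenumbers encode imaginary modes.  Zero-point energy and the quantum
harmonic vibrational free energy,

    G_vib = Σ_real  h·c·ν̃/2  +  k_B·T·ln(1 − exp(−h·c·ν̃/k_B·T)) ,

are reported per mole in kcal·mol⁻¹.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.linalg import eigh

from .constants import HESS_EV_TO_S2, C_CM_S, WAVENUMBER_TO_KCAL, kt_kcal

__all__ = ["HessianBlock", "NormalModeSet", "normal_modes", "zpe", "vib_free_energy"]

Classification = Literal["minimum", "transition_state", "higher_order"]

#: |ν̃| below this (cm⁻¹) is treated as a null translation/rotation remnant
NULL_MODE_CM = 5.0
#: real modes below this (cm⁻¹) are excluded from the thermal (not ZPE) term
THERMAL_FLOOR_CM = 20.0


@dataclass
class HessianBlock:
    """Symmetric Cartesian second-derivative matrix with per-atom masses.

    ``matrix`` is (3N, 3N) in kcal·mol⁻¹·Å⁻², atom-major (x1,y1,z1,x2,...);
    ``masses`` is length N in amu.  Set ``already_mass_weighted`` when the
    matrix is already in mass-weighted coordinates (kcal·mol⁻¹·Å⁻²·amu⁻¹).
    """

    matrix: np.ndarray
    masses: np.ndarray
    already_mass_weighted: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("hessian must be square")
        if m.shape[0] != 3 * self.masses.size:
            raise ValueError("hessian dimension must be 3 × atom count")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > 1e-6 * scale:
            raise ValueError("hessian is asymmetric beyond tolerance")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return self.masses.size


@dataclass
class NormalModeSet:
    """Wavenumbers in cm⁻¹ sorted ascending (negative = imaginary) and the
    stationary-point classification they imply."""

    wavenumbers: np.ndarray
    classification: Classification

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.wavenumbers < -NULL_MODE_CM))

    def real_modes(self) -> np.ndarray:
        """Real vibrational wavenumbers, null-mode remnants excluded."""
        return self.wavenumbers[self.wavenumbers > NULL_MODE_CM]


def _tr_projector(masses: np.ndarray, coords: np.ndarray | None) -> np.ndarray:
    """Projector onto the complement of mass-weighted translations (+
    rotations when coordinates are given)."""
    n = masses.size
    sqm = np.sqrt(np.repeat(masses, 3))
    vecs = []
    for ax in range(3):
        v = np.zeros(3 * n)
        v[ax::3] = 1.0
        vecs.append(v * sqm)
    if coords is not None:
        com = np.average(coords, axis=0, weights=masses)
        rel = coords - com
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = 1.0
            v = np.cross(np.tile(e, (n, 1)), rel).ravel() * sqm
            if np.linalg.norm(v) > 1e-10:
                vecs.append(v)
    basis = np.array(vecs).T
    q, _ = np.linalg.qr(basis)
    return np.eye(3 * n) - q @ q.T


def normal_modes(
    hessian: HessianBlock,
    project_tr: bool = False,
    coords: np.ndarray | None = None,
) -> NormalModeSet:
    """Diagonalise a (mass-weighted) Hessian into harmonic wavenumbers.

    With ``project_tr`` the three overall translations (and, when ``coords``
    in Å are supplied, the rotations) are projected out before
    diagonalisation, leaving near-zero remnant modes.
    """
    m = hessian.matrix
    if not hessian.already_mass_weighted:
        sqm = np.sqrt(np.repeat(hessian.masses, 3))
        m = m / np.outer(sqm, sqm)
    if project_tr:
        p = _tr_projector(hessian.masses, coords)
        m = p @ m @ p
    lam = eigh(m, eigvals_only=True)  # kcal·mol⁻¹·Å⁻²·amu⁻¹
    omega2 = lam * HESS_EV_TO_S2  # s⁻²
    wavenum = np.sign(omega2) * np.sqrt(np.abs(omega2)) / (2.0 * np.pi * C_CM_S)
    wavenum = np.sort(wavenum)
    n_imag = int(np.sum(wavenum < -NULL_MODE_CM))
    cls: Classification = (
        "minimum" if n_imag == 0 else "transition_state" if n_imag == 1 else "higher_order"
    )
    return NormalModeSet(wavenum, cls)


def zpe(modes: NormalModeSet) -> float:
    """Zero-point energy, kcal·mol⁻¹: Σ h·c·ν̃/2 over real modes only."""
    nu = modes.real_modes()
    return float(0.5 * WAVENUMBER_TO_KCAL * nu.sum())


def vib_free_energy(
    modes: NormalModeSet, temperature: float, thermal_floor: float = THERMAL_FLOOR_CM
) -> float:
    """Quantum harmonic vibrational free energy at T, kcal·mol⁻¹.

    ZPE plus the thermal term k_B·T·ln(1 − e^{−hcν̃/k_BT}) summed over real
    modes; modes below ``thermal_floor`` cm⁻¹ contribute only their ZPE (the
    log term diverges as ν̃ → 0).
    """
    if temperature < 0:
        raise ValueError("temperature must be nonnegative")
    nu = modes.real_modes()
    g = 0.5 * WAVENUMBER_TO_KCAL * nu.sum()
    if temperature > 0:
        kt = kt_kcal(temperature)
        thermal = nu[nu >= thermal_floor]
        g += kt * np.sum(np.log1p(-np.exp(-WAVENUMBER_TO_KCAL * thermal / kt)))
    return float(g)
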