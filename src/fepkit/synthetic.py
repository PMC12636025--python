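"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator takes a frozen spec (including an explicit seed), emulates
the statistical structure of the corresponding real data source, and
returns a machine-readable truth record alongside the data so recovery
tests can compare estimates against construction:

* FEP windows — per-window Gaussian interaction-energy ensembles around a
  prescribed free-energy profile (stand-in for 20 ps of QM/MM MD sampling
  per IRC window);
* titration records — Bernoulli protonation draws along a
  Henderson–Hasselbalch/Hill curve (stand-in for constant-pH neMD/MC
  output);
* progress curves — single-exponential product accumulation with
  first-order enzyme inactivation producing a plateau;
* toy trajectories — frames realising a programmed atom-pair distance, an
  optional unbinding event, and a bath of decoy atoms.

The FEP generator places the interaction share of the truth in the window
*means* with an analytic Gaussian compensation of +σ²/(2·k_B·T) per
increment, so that the exact free-energy increment of the sampling
distribution — mean shift minus σ²/(2k_BT) — equals the truth increment and
the estimator is unbiased for the stored truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import kt_kcal
from .fep import FEPWindow
from .kinetics import ProgressCurve
from .titration import TitrationSeries, hill_fraction
from .traj import Trajectory

__all__ = [
    "SyntheticFEPSpec",
    "SyntheticTitrationSpec",
    "SyntheticProgressSpec",
    "SyntheticTrajectorySpec",
    "double_well",
    "generate_fep_windows",
    "generate_titration",
    "generate_progress",
    "generate_trajectory",
]


def _require(cond: bool, spec: str, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{spec}.{fieldname}: {msg}")


def double_well(depth: float = 10.0, barrier: float = 12.0) -> Callable[[np.ndarray], np.ndarray]:
    """A smooth double-well profile on s ∈ [0, 1] (kcal·mol⁻¹): minima at the
    endpoints (0 and −depth), a barrier of the given height in between."""

    def profile(s):
        s = np.asarray(s, dtype=float)
        return barrier * np.sin(np.pi * s) ** 2 - depth * (3 * s**2 - 2 * s**3)

    return profile


@dataclass(frozen=True)
class SyntheticFEPSpec:
    """Conditions for a synthetic windowed reaction path.

    ``truth_profile`` maps path coordinate s ∈ [0, 1] to ΔG (kcal·mol⁻¹);
    ``qm_fraction`` is the share of each truth increment carried by the
    gas-phase energies, the remainder by interaction-energy means;
    ``noise_sigma`` is the per-window interaction-energy standard deviation;
    ``ar1_rho`` adds optional AR(1) autocorrelation to the samples.
    """

    n_windows: int = 21
    truth_profile: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: double_well(10.0, 12.0)
    )
    qm_fraction: float = 0.5
    noise_sigma: float = 0.5
    n_samples_per_window: int = 2000
    temperature: float = 303.0
    ar1_rho: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_windows >= 2, "SyntheticFEPSpec", "n_windows", "must be ≥ 2")
        _require(self.noise_sigma >= 0, "SyntheticFEPSpec", "noise_sigma", "must be ≥ 0")
        _require(
            self.n_samples_per_window >= 1,
            "SyntheticFEPSpec", "n_samples_per_window", "must be ≥ 1",
        )
        _require(
            0.0 <= self.qm_fraction <= 1.0, "SyntheticFEPSpec", "qm_fraction",
            "must lie in [0, 1]",
        )
        _require(self.temperature > 0, "SyntheticFEPSpec", "temperature", "must be > 0")
        _require(-1 < self.ar1_rho < 1, "SyntheticFEPSpec", "ar1_rho", "must lie in (−1, 1)")


def generate_fep_windows(spec: SyntheticFEPSpec) -> tuple[list[FEPWindow], dict]:
    """Windows at evenly spaced s ∈ [0, 1] plus the exact truth record.

    Gas-phase energies carry ``qm_fraction`` of the truth; interaction-energy
    means carry the rest (with the Gaussian free-energy compensation, see
    module docstring); samples are i.i.d. normal per window, or AR(1) when
    ``ar1_rho`` is set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = np.linspace(0.0, 1.0, spec.n_windows)
    truth = np.asarray(spec.truth_profile(s), dtype=float)
    truth = truth - truth[0]
    kt = kt_kcal(spec.temperature)

    e_qm0 = spec.qm_fraction * truth
    # window interaction means: cumulative (1-f)*truth plus per-increment
    # Gaussian compensation so the exact FEP increment equals the truth share
    comp = spec.noise_sigma**2 / (2.0 * kt)
    mu = (1.0 - spec.qm_fraction) * truth + comp * np.arange(spec.n_windows)

    windows = []
    for i in range(spec.n_windows):
        if spec.ar1_rho != 0.0 and spec.noise_sigma > 0:
            innov_sd = spec.noise_sigma * np.sqrt(1 - spec.ar1_rho**2)
            eps = np.empty(spec.n_samples_per_window)
            eps[0] = rng.normal(0, spec.noise_sigma)
            for k in range(1, spec.n_samples_per_window):
                eps[k] = spec.ar1_rho * eps[k - 1] + rng.normal(0, innov_sd)
        else:
            eps = rng.normal(0, spec.noise_sigma, spec.n_samples_per_window)
        windows.append(FEPWindow(index=i, s=float(s[i]), e_qm0=float(e_qm0[i]), samples=mu[i] + eps))
    truth_record = {
        "s": s.tolist(),
        "dg_truth": truth.tolist(),
        "qm_fraction": spec.qm_fraction,
        "noise_sigma": spec.noise_sigma,
        "temperature": spec.temperature,
        "n_samples_per_window": spec.n_samples_per_window,
        "seed": spec.seed,
    }
    return windows, truth_record


@dataclass(frozen=True)
class SyntheticTitrationSpec:
    """Bernoulli protonation records along a Hill curve for one residue."""

    pka_true: float = 10.5
    hill_true: float = 1.0
    ph_grid: tuple = tuple(np.arange(6.0, 14.01, 0.5))
    n_samples_per_ph: int = 5000
    residue: str = "LYS"
    seed: int = 0

    def validate(self) -> None:
        grid = np.asarray(self.ph_grid, dtype=float)
        _require(grid.size >= 2 and np.all(np.diff(grid) > 0),
                 "SyntheticTitrationSpec", "ph_grid", "must be strictly increasing")
        _require(self.n_samples_per_ph >= 1,
                 "SyntheticTitrationSpec", "n_samples_per_ph", "must be ≥ 1")
        _require(self.hill_true > 0, "SyntheticTitrationSpec", "hill_true", "must be > 0")


def generate_titration(spec: SyntheticTitrationSpec) -> tuple[TitrationSeries, dict]:
    """0/1 protonation draws at each pH with P(protonated) from the base-form
    Hill curve at the spec's true pKa."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.ph_grid, dtype=float)
    p = hill_fraction(grid, spec.pka_true, spec.hill_true)
    samples = [rng.binomial(1, pi, spec.n_samples_per_ph) for pi in p]
    series = TitrationSeries.from_samples(spec.residue, grid, samples)
    truth = {
        "pka_true": spec.pka_true,
        "hill_true": spec.hill_true,
        "n_samples_per_ph": spec.n_samples_per_ph,
        "seed": spec.seed,
    }
    return series, truth


@dataclass(frozen=True)
class SyntheticProgressSpec:
    """Progress curve with first-order enzyme inactivation.

    Mean curve P(t) = (v0/k_inact)·(1 − e^{−k_inact·t}); k_inact = 0
    degenerates to the linear P(t) = v0·t.  Units: μM, hours.
    """

    v0: float = 10.0  # μM·h⁻¹
    k_inact: float = 0.25  # h⁻¹
    t_grid: tuple = (0.0, 1.5, 3.0, 19.0, 48.0, 120.0)
    noise_sigma: float = 0.0  # μM
    enzyme_conc: float = 8.0  # μM
    seed: int = 0

    def validate(self) -> None:
        _require(self.v0 >= 0, "SyntheticProgressSpec", "v0", "must be ≥ 0")
        _require(self.k_inact >= 0, "SyntheticProgressSpec", "k_inact", "must be ≥ 0")
        t = np.asarray(self.t_grid, dtype=float)
        _require(t.size >= 2 and t[0] >= 0 and np.all(np.diff(t) > 0),
                 "SyntheticProgressSpec", "t_grid", "must be nonnegative increasing")
        _require(self.noise_sigma >= 0, "SyntheticProgressSpec", "noise_sigma", "must be ≥ 0")
        _require(self.enzyme_conc > 0, "SyntheticProgressSpec", "enzyme_conc", "must be > 0")


def progress_mean(t: np.ndarray, v0: float, k_inact: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if k_inact == 0.0:
        return v0 * t
    return (v0 / k_inact) * -np.expm1(-k_inact * t)


def generate_progress(spec: SyntheticProgressSpec) -> tuple[ProgressCurve, dict]:
    """Noisy progress curve plus truth (v0, k_inact, plateau, TOF)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.t_grid, dtype=float)
    p = progress_mean(t, spec.v0, spec.k_inact)
    if spec.noise_sigma > 0:
        p = p + rng.normal(0, spec.noise_sigma, t.size)
        p = np.maximum(p, 0.0)
        p[t == 0] = 0.0
    curve = ProgressCurve(t, p, spec.enzyme_conc)
    truth = {
        "v0": spec.v0,
        "k_inact": spec.k_inact,
        "plateau": (spec.v0 / spec.k_inact) if spec.k_inact > 0 else float("inf"),
        "tof_s": spec.v0 / 3600.0 / spec.enzyme_conc,
        "seed": spec.seed,
    }
    return curve, truth


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Toy trajectory realising a programmed distance between a tagged atom
    pair, with optional unbinding (pair distance ≥ 15 Å afterwards).

    ``distance_program``: list of (start_frame, target_distance_Å) pieces,
    constant within each piece; ``distance_noise``: Gaussian jitter (Å).
    """

    n_frames: int = 1000
    n_atoms: int = 10
    distance_program: tuple = ((0, 3.5),)
    distance_noise: float = 0.0
    unbind_frame: int | None = None
    unbound_distance: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_frames >= 1, "SyntheticTrajectorySpec", "n_frames", "must be ≥ 1")
        _require(self.n_atoms >= 2, "SyntheticTrajectorySpec", "n_atoms", "must be ≥ 2")
        if self.unbind_frame is not None:
            _require(0 <= self.unbind_frame < self.n_frames,
                     "SyntheticTrajectorySpec", "unbind_frame", "must be < n_frames")
        _require(self.unbound_distance >= 15.0,
                 "SyntheticTrajectorySpec", "unbound_distance", "must be ≥ 15 Å")
        _require(self.distance_noise >= 0,
                 "SyntheticTrajectorySpec", "distance_noise", "must be ≥ 0")
        starts = [p[0] for p in self.distance_program]
        _require(len(starts) >= 1 and starts[0] == 0 and list(starts) == sorted(starts),
                 "SyntheticTrajectorySpec", "distance_program",
                 "pieces must start at frame 0 and be ordered")


def generate_trajectory(spec: SyntheticTrajectorySpec) -> tuple[Trajectory, dict]:
    """Frames where atoms 0 and 1 realise the distance program along x;
    remaining atoms are a static decoy lattice.  After ``unbind_frame`` the
    tagged pair sits at ``unbound_distance``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    target = np.empty(spec.n_frames)
    for start, dist in spec.distance_program:
        target[start:] = dist
    if spec.unbind_frame is not None:
        target[spec.unbind_frame:] = spec.unbound_distance
    if spec.distance_noise > 0:
        jitter = rng.normal(0, spec.distance_noise, spec.n_frames)
        if spec.unbind_frame is not None:
            # keep the unbound plateau safely above any sane threshold
            jitter[spec.unbind_frame:] = np.clip(jitter[spec.unbind_frame:], -2.0, None)
        target = np.maximum(target + jitter, 0.1)

    coords = np.zeros((spec.n_frames, spec.n_atoms, 3))
    coords[:, 1, 0] = target
    if spec.n_atoms > 2:
        decoys = rng.uniform(-5, 5, (spec.n_atoms - 2, 3)) + np.array([0.0, 8.0, 0.0])
        coords[:, 2:, :] = decoys[None, :, :]
    names = ["A", "B"] + [f"D{i}" for i in range(spec.n_atoms - 2)]
    resids = np.arange(spec.n_atoms) + 1
    traj = Trajectory(coords, names, resids=resids,
                      times_ns=np.arange(spec.n_frames, dtype=float))
    truth = {
        "distance_program": [list(p) for p in spec.distance_program],
        "unbind_frame": spec.unbind_frame,
        "unbound_distance": spec.unbound_distance,
        "seed": spec.seed,
    }
    return traj, truth
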