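"""Free-energy perturbation along a windowed reaction path.

The free-energy change from the reference window ``R`` to window ``j`` is a
gas-phase QM energy difference plus a sum of per-window exponential averages
of QM/MM interaction-energy differences:

    ΔG(s_j) = [E⁰_QM(s_j) − E⁰_QM(s_R)] + Σ_{i=R}^{j−1} g_i ,

where under the default ``zwanzig`` convention each window term is the
standard forward free-energy perturbation

    g_i = −k_B·T · ln ⟨ exp(−ΔE_i / k_B·T) ⟩_i ,

the average running over MM configurations sampled in window ``i``.  The
``as_printed`` convention flips the sign inside the exponential and keeps
the leading minus (a literal transcription of the source formula, which
inverts the Zwanzig identity); it is provided for comparison only.

Two routes supply the perturbation energies ΔE_i:

* **paired** — when a window carries interaction energies re-evaluated at
  the next window's geometry over the *same* MM configurations
  (``samples_next``), ΔE is the per-configuration difference, paired by
  sample index;
* **mean-shift surrogate** — with only each window's own samples, ΔE is the
  window-``i`` fluctuation about its mean plus the mean shift to window
  ``i+1``:  ΔE_k = (x_k − x̄_i) + (x̄_{i+1} − x̄_i).  This keeps the
  window's fluctuation spectrum while centring the perturbation on the
  mean increment.

Statistical errors use first-order (delta-method) propagation of the
variance of exp(−ΔE/k_BT), with the variance of the sample mean taken from
block averaging to absorb autocorrelation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import kt_kcal

__all__ = [
    "FEPWindow",
    "FreeEnergyProfile",
    "zwanzig_increment",
    "fep_profile",
    "window_error",
    "propagate_profile_error",
    "apply_stationary_corrections",
]

Convention = Literal["zwanzig", "as_printed"]


@dataclass
class FEPWindow:
    """One window of the reaction path.

    Parameters
    ----------
    index : int
        Window ordinal along the path.
    s : float
        Mass-weighted path coordinate, amu^{1/2}·Å.
    e_qm0 : float
        Gas-phase QM energy of the window geometry, kcal·mol⁻¹.
    samples : array
        QM/MM interaction energies sampled over MM configurations of this
        window, kcal·mol⁻¹.  Nonempty, finite.
    samples_next : array, optional
        Interaction energies at the *next* window's geometry evaluated on
        the same MM configurations, aligned with ``samples`` by index.
    """

    index: int
    s: float
    e_qm0: float
    samples: np.ndarray
    samples_next: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_1d(np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            raise ValueError(f"window {self.index}: samples must be nonempty")
        if not np.all(np.isfinite(self.samples)) or not np.isfinite(self.e_qm0):
            raise ValueError(f"window {self.index}: energies must be finite")
        if self.samples_next is not None:
            self.samples_next = np.atleast_1d(np.asarray(self.samples_next, dtype=float))
            if self.samples_next.shape != self.samples.shape:
                raise ValueError(
                    f"window {self.index}: samples_next must align with samples"
                )


@dataclass
class FreeEnergyProfile:
    """ΔG vs path coordinate, relative to the reference (first) window."""

    s: np.ndarray
    dg: np.ndarray
    stderr: np.ndarray
    temperature: float
    convention: str = "zwanzig"
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.dg = np.asarray(self.dg, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if not (len(self.s) == len(self.dg) == len(self.stderr)):
            raise ValueError("s, dg and stderr must have equal length")
        if self.dg[0] != 0.0 or self.stderr[0] != 0.0:
            raise ValueError("profile must be zero (with zero error) at the reference")


def zwanzig_increment(
    delta_e: np.ndarray, temperature: float, convention: Convention = "zwanzig"
) -> float:
    """Free-energy increment from perturbation-energy samples.

    ``zwanzig``:    −k_B·T · ln ⟨exp(−ΔE/k_BT)⟩  (standard identity);
    ``as_printed``: −k_B·T · ln ⟨exp(+ΔE/k_BT)⟩.

    Evaluated through log-sum-exp, so |ΔE| up to ~1e4 kcal·mol⁻¹ is safe.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    kt = kt_kcal(temperature)
    sign = -1.0 if convention == "zwanzig" else 1.0
    # -kT * [ logsumexp(sign*dE/kT) - ln n ]
    return -kt * (logsumexp(sign * delta_e / kt) - np.log(delta_e.size))


def _delta_e_samples(win: FEPWindow, nxt: FEPWindow) -> np.ndarray:
    """Perturbation energies for the step win → nxt (paired or surrogate)."""
    if win.samples_next is not None:
        return win.samples_next - win.samples
    mean_i = win.samples.mean()
    mean_next = nxt.samples.mean()
    return (win.samples - mean_i) + (mean_next - mean_i)


def fep_profile(
    windows: Sequence[FEPWindow],
    temperature: float = 303.0,
    convention: Convention = "zwanzig",
    blocks: int = 10,
) -> FreeEnergyProfile:
    """Assemble the free-energy profile over an ordered window list.

    The first window is the reference state.  Errors are per-window standard
    errors (block-averaged delta method) accumulated in quadrature.
    """
    if len(windows) == 0:
        raise ValueError("at least one window is required")
    if convention not in ("zwanzig", "as_printed"):
        raise ValueError(f"unknown convention {convention!r}")
    s = np.array([w.s for w in windows], dtype=float)
    if np.any(np.diff(s) < 0):
        raise ValueError("windows must be ordered by nondecreasing s")

    e0 = np.array([w.e_qm0 for w in windows], dtype=float)
    dg = np.zeros(len(windows))
    errs = np.zeros(max(len(windows) - 1, 0))
    acc = 0.0
    for i in range(len(windows) - 1):
        de = _delta_e_samples(windows[i], windows[i + 1])
        acc += zwanzig_increment(de, temperature, convention)
        dg[i + 1] = (e0[i + 1] - e0[0]) + acc
        errs[i] = window_error(de, temperature, blocks=blocks, convention=convention)
    stderr = propagate_profile_error(errs)
    return FreeEnergyProfile(s, dg, stderr, temperature, convention)


def window_error(
    delta_e: np.ndarray,
    temperature: float,
    blocks: int = 10,
    convention: Convention = "zwanzig",
) -> float:
    """Standard error of one window's free-energy term.

    First-order propagation through g = −k_B·T·ln(Ȳ) with
    Y = exp(∓ΔE/k_BT):  SE(g) = k_B·T · SE(Ȳ)/Ȳ.  SE(Ȳ) is estimated from
    the scatter of block means (default 10 blocks), which inflates the
    error appropriately for autocorrelated samples; fewer than 20 samples
    fall back to the naive i.i.d. estimate with a warning.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    n = delta_e.size
    if n < 2:
        raise ValueError("window error needs at least 2 samples")
    kt = kt_kcal(temperature)
    sign = -1.0 if convention == "zwanzig" else 1.0
    # Work with Y/max(Y) to stay overflow-safe; the ratio SE(Ȳ)/Ȳ is scale-free.
    x = sign * delta_e / kt
    y = np.exp(x - x.max())
    ybar = y.mean()
    if n < 20:
        warnings.warn(
            "fewer than 20 samples: falling back to naive i.i.d. standard error",
            stacklevel=2,
        )
        se_mean = y.std(ddof=1) / np.sqrt(n)
    else:
        nb = min(blocks, n)
        usable = (n // nb) * nb
        block_means = y[:usable].reshape(nb, -1).mean(axis=1)
        se_mean = block_means.std(ddof=1) / np.sqrt(nb)
    return float(kt * se_mean / ybar)


def propagate_profile_error(window_errors: np.ndarray) -> np.ndarray:
    """Cumulative profile errors from independent per-window errors.

    Returns an array one longer than the input: error at the reference is 0
    and error at point j is sqrt(Σ of squared window errors up to j−1).
    """
    window_errors = np.asarray(window_errors, dtype=float)
    if np.any(window_errors < 0):
        raise ValueError("window errors must be nonnegative")
    return np.sqrt(np.concatenate([[0.0], np.cumsum(window_errors**2)]))


def apply_stationary_corrections(
    profile: FreeEnergyProfile,
    corrections: dict[str, float],
    point_labels: dict[str, int],
    reference_label: str,
) -> dict[str, float]:
    """Harmonic vibrational corrections at stationary points.

    Only the labelled stationary points of the profile are corrected (the
    path between them is left raw):  G_corr = ΔG_raw + (G_vib − G_vib,ref).

    Parameters
    ----------
    corrections : map label → vibrational free energy (kcal·mol⁻¹).
    point_labels : map label → profile point index.
    reference_label : label whose correction anchors the others.

    Returns a map label → corrected ΔG.
    """
    if reference_label not in corrections:
        raise KeyError(f"no correction supplied for reference {reference_label!r}")
    out: dict[str, float] = {}
    for label, idx in point_labels.items():
        if label not in corrections:
            raise KeyError(f"no correction supplied for point {label!r}")
        if not 0 <= idx < len(profile.dg):
            raise KeyError(f"label {label!r} points outside the profile")
        out[label] = profile.dg[idx] + (
            corrections[label] - corrections[reference_label]
        )
    return out
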