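"""Stitching per-step free energies into one landscape; effective barrier.

A multi-step catalytic mechanism is reported step-by-step as an activation
free energy ΔG‡ and a reaction free energy ΔG_rxn.  Stitching places each
step's reactant minimum at the previous step's product minimum, so all
stationary points live on one scale anchored at a chosen global reference
minimum (G = 0).  A step may instead declare its values measured from the
global reference (as when a barrier is quoted "from the most stable
inactive reactant state").

The overall effective (rate-determining) barrier is the energetic span

    ΔG‡_eff = max over TS t of [ G(t) − min over minima preceding t of G ] ,

the largest climb from any preceding resting state to a transition state.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .constants import kt_kcal

__all__ = [
    "MechanismStep",
    "StationaryPoint",
    "Landscape",
    "assemble",
    "effective_barrier",
    "boltzmann_fraction",
]

Reference = Literal["step_reactant", "global_reference"]


@dataclass
class MechanismStep:
    """One elementary step: barrier and reaction free energy in kcal·mol⁻¹.

    With ``reference="step_reactant"`` both values are measured from the
    step's own reactant minimum; with ``"global_reference"`` the TS and the
    product minimum are placed at ΔG‡ and ΔG_rxn relative to the global
    reference minimum instead.
    """

    name: str
    dg_act: float
    dg_rxn: float
    reference: Reference = "step_reactant"

    def __post_init__(self) -> None:
        if self.dg_act < 0:
            raise ValueError(f"step {self.name!r}: activation free energy must be ≥ 0")
        if self.reference not in ("step_reactant", "global_reference"):
            raise ValueError(f"step {self.name!r}: unknown reference {self.reference!r}")


@dataclass
class StationaryPoint:
    label: str
    kind: Literal["minimum", "ts"]
    g: float  # kcal·mol⁻¹ relative to the global reference minimum


@dataclass
class Landscape:
    """Alternating minima and transition states on a common energy scale."""

    points: list[StationaryPoint]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("landscape must contain at least one point")
        if self.points[0].kind != "minimum" or self.points[-1].kind != "minimum":
            raise ValueError("landscape must start and end at minima")
        for a, b in zip(self.points, self.points[1:]):
            if a.kind == b.kind:
                raise ValueError("stationary points must strictly alternate")

    @property
    def minima(self) -> list[StationaryPoint]:
        return [p for p in self.points if p.kind == "minimum"]

    @property
    def transition_states(self) -> list[StationaryPoint]:
        return [p for p in self.points if p.kind == "ts"]


def assemble(
    steps: Sequence[MechanismStep],
    global_reference_label: str = "reactant",
    minimum_labels: Sequence[str] | None = None,
) -> Landscape:
    """Stitch ordered mechanism steps into a landscape anchored at 0.

    The first step's reactant is the initial state.  Step names must be
    unique; optional ``minimum_labels`` (length = steps + 1) name the minima,
    otherwise they are derived from step names.
    """
    if not steps:
        raise ValueError("at least one step is required")
    names = [s.name for s in steps]
    if len(set(names)) != len(names):
        raise ValueError("step names must be unique")
    if minimum_labels is None:
        minimum_labels = [global_reference_label] + [f"{s.name}_product" for s in steps]
    if len(minimum_labels) != len(steps) + 1:
        raise ValueError("need one minimum label per step plus the initial state")

    pts: list[StationaryPoint] = [StationaryPoint(minimum_labels[0], "minimum", 0.0)]
    g_min = 0.0  # current (step-reactant) minimum
    for k, step in enumerate(steps):
        if step.reference == "step_reactant":
            g_ts = g_min + step.dg_act
            g_prod = g_min + step.dg_rxn
        else:  # measured from the global reference minimum (G = 0 by anchor)
            g_ts = step.dg_act
            g_prod = step.dg_rxn
        pts.append(StationaryPoint(f"TS_{step.name}", "ts", g_ts))
        pts.append(StationaryPoint(minimum_labels[k + 1], "minimum", g_prod))
        g_min = g_prod
    return Landscape(pts)


def effective_barrier(landscape: Landscape) -> tuple[float, str]:
    """Rate-determining effective barrier and its transition-state label.

    Scans every TS against the lowest minimum preceding it; ties go to the
    earliest TS.
    """
    best: tuple[float, str] | None = None
    lowest_prev = np.inf
    for p in landscape.points:
        if p.kind == "minimum":
            lowest_prev = min(lowest_prev, p.g)
        else:
            span = p.g - lowest_prev
            if best is None or span > best[0] + 1e-12:
                best = (span, p.label)
    if best is None:
        raise ValueError("landscape contains no transition state")
    return best


def boltzmann_fraction(dg: float, temperature: float) -> float:
    """Equilibrium population of the higher state of a two-state system
    separated by ΔG (kcal·mol⁻¹) at temperature T."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    with np.errstate(over="ignore"):
        return float(1.0 / (1.0 + np.exp(dg / kt_kcal(temperature))))
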