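"""Readers and writers for the plain-text formats the pipeline exchanges.

Window files are TSV (window, s, E_qm0, sample_1…sample_n); profiles,
titration series, progress curves and reports are CSV; reaction paths and
trajectories are multi-frame XYZ or multi-model PDB (read through
MDAnalysis); Hessians are whitespace matrices with a masses header; truth
records and configurations are YAML/JSON sidecars.
"""
from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .fep import FEPWindow, FreeEnergyProfile
from .kinetics import ProgressCurve
from .landscape import MechanismStep
from .thermo import HessianBlock
from .titration import TitrationSeries
from .traj import Trajectory

__all__ = [
    "write_windows_tsv", "read_windows_tsv",
    "write_profile_csv", "read_profile_csv",
    "write_titration_csv", "read_titration_csv",
    "write_progress_csv", "read_progress_csv",
    "read_steps", "write_hessian", "read_hessian",
    "read_xyz_frames", "write_xyz_frames",
    "trajectory_from_file", "write_truth", "read_truth",
]


# ---------------------------------------------------------------- FEP windows

def write_windows_tsv(windows: Sequence[FEPWindow], filename: str) -> None:
    n = max(w.samples.size for w in windows)
    cols = ["window", "s", "E_qm0"] + [f"sample_{i+1}" for i in range(n)]
    rows = []
    for w in windows:
        pad = [np.nan] * (n - w.samples.size)
        rows.append([w.index, w.s, w.e_qm0, *w.samples.tolist(), *pad])
    pd.DataFrame(rows, columns=cols).to_csv(filename, sep="\t", index=False)


def read_windows_tsv(filename: str) -> list[FEPWindow]:
    df = pd.read_csv(filename, sep="\t")
    sample_cols = [c for c in df.columns if c.startswith("sample_")]
    windows = []
    for _, row in df.iterrows():
        samples = row[sample_cols].to_numpy(dtype=float)
        samples = samples[np.isfinite(samples)]
        windows.append(
            FEPWindow(int(row["window"]), float(row["s"]), float(row["E_qm0"]), samples)
        )
    return windows


# -------------------------------------------------------------------- profile

def write_profile_csv(profile: FreeEnergyProfile, filename: str) -> None:
    pd.DataFrame(
        {"s": profile.s, "dG_kcal_mol": profile.dg, "stderr_kcal_mol": profile.stderr}
    ).to_csv(filename, index=False)


def read_profile_csv(filename: str, temperature: float = 303.0) -> FreeEnergyProfile:
    df = pd.read_csv(filename)
    return FreeEnergyProfile(
        df["s"].to_numpy(), df["dG_kcal_mol"].to_numpy(),
        df["stderr_kcal_mol"].to_numpy(), temperature,
    )


# ------------------------------------------------------------------ titration

def write_titration_csv(series: TitrationSeries, filename: str) -> None:
    data = {"residue": series.residue, "pH": series.ph, "fraction": series.fraction}
    if series.counts is not None:
        data["n_samples"] = series.counts.astype(int)
    pd.DataFrame(data).to_csv(filename, index=False)


def read_titration_csv(filename: str, residue: str | None = None) -> TitrationSeries:
    df = pd.read_csv(filename)
    if residue is not None:
        df = df[df["residue"] == residue]
        if df.empty:
            raise ValueError(f"no rows for residue {residue!r}")
    res = str(df["residue"].iloc[0])
    counts = df["n_samples"].to_numpy(dtype=float) if "n_samples" in df else None
    return TitrationSeries(res, df["pH"].to_numpy(), df["fraction"].to_numpy(), counts)


# ------------------------------------------------------------- progress curve

def write_progress_csv(curve: ProgressCurve, filename: str) -> None:
    pd.DataFrame({"time_h": curve.times_h, "conc_uM": curve.conc_uM}).to_csv(
        filename, index=False
    )


def read_progress_csv(filename: str, enzyme_uM: float) -> ProgressCurve:
    df = pd.read_csv(filename)
    return ProgressCurve(df["time_h"].to_numpy(), df["conc_uM"].to_numpy(), enzyme_uM)


# ------------------------------------------------------------ mechanism steps

def read_steps(filename: str) -> list[MechanismStep]:
    """Mechanism steps from YAML (list of mappings) or CSV with columns
    name, dg_act, dg_rxn, reference."""
    if filename.endswith((".yaml", ".yml")):
        with open(filename) as fh:
            raw = yaml.safe_load(fh)
        records = raw["steps"] if isinstance(raw, dict) else raw
    else:
        records = pd.read_csv(filename).to_dict("records")
    steps = []
    for r in records:
        ref = r.get("reference", "step_reactant")
        if ref is None or (isinstance(ref, float) and np.isnan(ref)):
            ref = "step_reactant"
        steps.append(
            MechanismStep(str(r["name"]), float(r["dg_act"]), float(r["dg_rxn"]), str(ref))
        )
    return steps


# -------------------------------------------------------------------- hessian

def write_hessian(hessian: HessianBlock, filename: str) -> None:
    with open(filename, "w") as fh:
        fh.write("# masses_amu: " + " ".join(f"{m:.6f}" for m in hessian.masses) + "\n")
        fh.write(f"# mass_weighted: {int(hessian.already_mass_weighted)}\n")
        np.savetxt(fh, hessian.matrix)


def read_hessian(filename: str) -> HessianBlock:
    masses = None
    mass_weighted = False
    with open(filename) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("# masses_amu:"):
            masses = np.array([float(x) for x in ln.split(":", 1)[1].split()])
        elif ln.startswith("# mass_weighted:"):
            mass_weighted = bool(int(ln.split(":", 1)[1]))
        elif ln.strip() and not ln.startswith("#"):
            body.append(ln)
    if masses is None:
        raise ValueError("hessian file lacks the '# masses_amu:' header line")
    matrix = np.loadtxt(body)
    return HessianBlock(np.atleast_2d(matrix), masses, mass_weighted)


# ------------------------------------------------------------------------ XYZ

def write_xyz_frames(labels: Sequence[str], frames: Sequence[np.ndarray],
                     filename: str, comment: str = "") -> None:
    with open(filename, "w") as fh:
        for k, coords in enumerate(frames):
            fh.write(f"{len(labels)}\n{comment} frame {k}\n")
            for lab, (x, y, z) in zip(labels, coords):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(filename: str) -> tuple[list[str], list[np.ndarray]]:
    """Multi-frame XYZ via MDAnalysis: (atom labels, list of (n,3) arrays)."""
    import MDAnalysis as mda

    u = mda.Universe(filename)
    labels = [str(n) for n in u.atoms.names]
    frames = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
    return labels, frames


def trajectory_from_file(filename: str) -> Trajectory:
    """Load a multi-frame XYZ or multi-model PDB file as a Trajectory."""
    import MDAnalysis as mda

    u = mda.Universe(filename)
    coords = np.array([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
    names = [str(n) for n in u.atoms.names]
    resids = resnames = None
    if hasattr(u.atoms, "resids"):
        resids = np.asarray(u.atoms.resids, dtype=int)
    if hasattr(u.atoms, "resnames"):
        resnames = [str(r) for r in u.atoms.resnames]
    return Trajectory(coords, names, resids=resids, resnames=resnames)


# ---------------------------------------------------------------- truth files

def write_truth(record: dict, filename: str) -> None:
    with open(filename, "w") as fh:
        if filename.endswith((".yaml", ".yml")):
            yaml.safe_dump(record, fh)
        else:
            json.dump(record, fh, indent=2)


def read_truth(filename: str) -> dict:
    with open(filename) as fh:
        if filename.endswith((".yaml", ".yml")):
            return yaml.safe_load(fh)
        return json.load(fh)
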