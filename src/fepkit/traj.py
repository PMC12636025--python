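"""Descriptive trajectory analysis: distances, dihedrals, RMSD, waters.

Operates on a light in-memory trajectory (constant atom roster, coordinates
in Å, optional residue metadata and frame times in ns).  Superposition uses
the Kabsch least-squares rotation; dihedrals follow the standard signed
convention wrapped to (−180°, 180°]; water occupancy counts water oxygens
within a cutoff of a site centroid and flags identity exchanges at constant
count; unbinding detection finds the first persistent threshold crossing of
a distance series.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "SeriesSummary",
    "distance_series",
    "dihedral_series",
    "rmsd",
    "per_residue_rmsd",
    "water_occupancy",
    "detect_unbinding",
]


@dataclass
class Trajectory:
    """Ordered frames of labelled atom coordinates.

    ``coords``: (n_frames, n_atoms, 3) in Å; ``names``: atom names;
    ``resids``/``resnames``: optional per-atom residue metadata;
    ``times_ns``: optional nondecreasing frame time stamps.
    """

    coords: np.ndarray
    names: Sequence[str]
    resids: np.ndarray | None = None
    resnames: Sequence[str] | None = None
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.names) != self.n_atoms:
            raise ValueError("names must match atom count")
        if self.resids is not None:
            self.resids = np.asarray(self.resids, dtype=int)
            if self.resids.shape != (self.n_atoms,):
                raise ValueError("resids must match atom count")
        if self.resnames is not None and len(self.resnames) != self.n_atoms:
            raise ValueError("resnames must match atom count")
        if self.times_ns is not None:
            self.times_ns = np.asarray(self.times_ns, dtype=float)
            if self.times_ns.shape != (self.n_frames,):
                raise ValueError("times must match frame count")
            if np.any(np.diff(self.times_ns) < 0):
                raise ValueError("frame times must be nondecreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, name: str, resid: int | None = None) -> int:
        """Index of the (first) atom with this name (and residue id)."""
        for i, nm in enumerate(self.names):
            if nm == name and (resid is None or (self.resids is not None and self.resids[i] == resid)):
                return i
        raise KeyError(f"no atom named {name!r}" + (f" in residue {resid}" if resid else ""))


@dataclass
class SeriesSummary:
    """A per-frame scalar series with its population histogram."""

    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin: tuple[float, float] = field(default=(np.nan, np.nan))

    @classmethod
    def from_values(cls, values: np.ndarray, bin_width: float = 0.1) -> "SeriesSummary":
        values = np.asarray(values, dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            edges = np.array([0.0, bin_width])
            counts = np.array([0])
            return cls(values, edges, counts)
        lo = np.floor(finite.min() / bin_width) * bin_width
        hi = np.ceil(finite.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        nbins = int(round((hi - lo) / bin_width))
        counts, edges = np.histogram(finite, bins=nbins, range=(lo, hi))
        k = int(np.argmax(counts))
        return cls(values, edges, counts, (float(edges[k]), float(edges[k + 1])))


def distance_series(
    traj: Trajectory, atom_a: int | str, atom_b: int | str, bin_width: float = 0.1
) -> SeriesSummary:
    """Euclidean distance between two atoms per frame, with histogram."""
    ia = traj.atom_index(atom_a) if isinstance(atom_a, str) else atom_a
    ib = traj.atom_index(atom_b) if isinstance(atom_b, str) else atom_b
    d = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    return SeriesSummary.from_values(d, bin_width)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, wrapped to (−180, 180].

    Degenerate (collinear) geometries return NaN.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm_b1 = np.linalg.norm(b1)
    if norm_b1 < 1e-12 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return float("nan")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1) / norm_b1
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral_series(
    traj: Trajectory, atoms: Sequence[int | str], bin_width: float = 5.0
) -> SeriesSummary:
    """Signed dihedral (degrees) over four atoms per frame; collinear frames
    yield NaN and are excluded from the histogram."""
    idx = [traj.atom_index(a) if isinstance(a, str) else a for a in atoms]
    if len(set(idx)) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    vals = np.array(
        [dihedral(*(traj.coords[f, i] for i in idx)) for f in range(traj.n_frames)]
    )
    return SeriesSummary.from_values(vals, bin_width)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimally superpose ``mobile`` onto ``reference`` (both (n, 3)).

    Returns the transformed mobile coordinates and the post-fit RMSD.
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    moved = rot.apply(mob_c) + reference.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rms


def rmsd(
    reference: np.ndarray,
    frame: np.ndarray,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> float:
    """RMSD (Å) between two frames over a selection of atom indices.

    With ``superpose`` the frame is first Kabsch-aligned to the reference on
    the selection; without, the raw coordinate deviation is measured.
    """
    reference = np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if selection is not None:
        selection = np.asarray(selection)
        if selection.size == 0:
            raise ValueError("selection must be nonempty")
        reference = reference[selection]
        frame = frame[selection]
    if reference.shape != frame.shape:
        raise ValueError("reference and frame selections are not conformable")
    if reference.shape[0] == 0:
        raise ValueError("selection must be nonempty")
    if superpose:
        _, rms = kabsch_superpose(frame, reference)
        return rms
    return float(np.sqrt(np.mean(np.sum((frame - reference) ** 2, axis=1))))


def per_residue_rmsd(
    reference: np.ndarray,
    frame: np.ndarray,
    resids: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> dict[int, float]:
    """Per-residue RMSD after a single global superposition.

    The frame is Kabsch-fitted to the reference on ``fit_selection`` (all
    atoms when omitted); each residue's RMSD is then measured without
    further fitting, so genuinely displaced residues stand out.
    """
    reference = np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    resids = np.asarray(resids)
    if resids.shape[0] != reference.shape[0]:
        raise ValueError("residue ids must cover every atom")
    fit_idx = np.arange(reference.shape[0]) if fit_selection is None else np.asarray(fit_selection)
    # global fit on the selection, then apply that transform to all atoms
    ref_sel = reference[fit_idx]
    mob_sel = frame[fit_idx]
    rot, _ = Rotation.align_vectors(
        ref_sel - ref_sel.mean(axis=0), mob_sel - mob_sel.mean(axis=0)
    )
    moved = rot.apply(frame - mob_sel.mean(axis=0)) + ref_sel.mean(axis=0)
    out: dict[int, float] = {}
    for rid in np.unique(resids):
        m = resids == rid
        out[int(rid)] = float(
            np.sqrt(np.mean(np.sum((moved[m] - reference[m]) ** 2, axis=1)))
        )
    return out


def water_occupancy(
    traj: Trajectory,
    site_selection: np.ndarray,
    cutoff: float,
    water_resnames: Sequence[str] = ("WAT", "HOH", "SOL", "TIP3"),
    oxygen_prefix: str = "O",
) -> tuple[np.ndarray, list[tuple[int, set, set]]]:
    """Water oxygens within ``cutoff`` Å of the site centroid, per frame.

    Returns per-frame counts and the exchange events — frames where the set
    of occupying water residues changes while the count stays constant —
    as ``(frame, left, entered)`` tuples.
    """
    if traj.resnames is None or traj.resids is None:
        raise ValueError("water occupancy needs residue names and ids")
    resnames = np.asarray(traj.resnames)
    is_wat_o = np.array(
        [
            rn in water_resnames and nm.startswith(oxygen_prefix)
            for rn, nm in zip(resnames, traj.names)
        ]
    )
    wat_idx = np.where(is_wat_o)[0]
    if wat_idx.size == 0:
        warnings.warn("no water oxygens found in the atom roster", stacklevel=2)
        return np.zeros(traj.n_frames, dtype=int), []
    counts = np.zeros(traj.n_frames, dtype=int)
    occupants: list[frozenset] = []
    for f in range(traj.n_frames):
        center = traj.coords[f, site_selection].mean(axis=0)
        d = np.linalg.norm(traj.coords[f, wat_idx] - center, axis=1)
        inside = wat_idx[d <= cutoff]
        counts[f] = inside.size
        occupants.append(frozenset(int(traj.resids[i]) for i in inside))
    events = []
    for f in range(1, traj.n_frames):
        if counts[f] == counts[f - 1] and occupants[f] != occupants[f - 1]:
            events.append(
                (f, set(occupants[f - 1] - occupants[f]), set(occupants[f] - occupants[f - 1]))
            )
    return counts, events


def detect_unbinding(
    series: SeriesSummary | np.ndarray, threshold: float = 10.0, persistence: int = 50
) -> int | None:
    """First frame from which the series stays above ``threshold`` for at
    least ``persistence`` consecutive frames; ``None`` if it never does."""
    if persistence < 1:
        raise ValueError("persistence must be ≥ 1")
    values = series.values if isinstance(series, SeriesSummary) else np.asarray(series)
    above = values > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            return i - persistence + 1
    return None
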