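"""Mass-weighted path coordinate along an IRC-style sequence of structures.

An intrinsic reaction coordinate delivered as an ordered list of QM-subsystem
geometries is condensed to a single arc-length-like coordinate

    s_i = s_{i-1} + sqrt( Σ_j m_j · |r_{j,i} - r_{j,i-1}|² )

with per-atom masses m_j in amu and coordinates in Å, so s carries units of
amu^{1/2}·Å.  The structures are assumed to share a common frame of
reference (as consecutive IRC points do); no superposition is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .elements import masses_for

__all__ = ["QMStructure", "IRCPath", "compute_path_coordinate", "path_from_xyz"]


class ConformabilityError(ValueError):
    """Structures along a path do not share atom count, labels or masses."""


@dataclass
class QMStructure:
    """One geometry of the QM subsystem.

    Parameters
    ----------
    labels : sequence of str
        Atom labels (element symbols or unique names).
    coords : (n_atoms, 3) array
        Cartesian coordinates in Å.
    masses : (n_atoms,) array
        Atomic masses in amu, strictly positive.
    """

    labels: Sequence[str]
    coords: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("structure must contain at least one atom")
        if len(self.labels) != n or self.masses.shape != (n,):
            raise ConformabilityError("labels, coords and masses disagree in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.masses <= 0) or not np.all(np.isfinite(self.masses)):
            raise ValueError("masses must be positive and finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class IRCPath:
    """Ordered sequence of conformable QM structures, optionally with
    precomputed path-coordinate values (amu^{1/2}·Å, nondecreasing, s[0]=0)."""

    structures: list[QMStructure]
    s: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("path must contain at least one structure")
        ref = self.structures[0]
        for st in self.structures[1:]:
            if st.n_atoms != ref.n_atoms:
                raise ConformabilityError("structures differ in atom count")
            if list(st.labels) != list(ref.labels):
                raise ConformabilityError("structures differ in atom labels")
            if not np.allclose(st.masses, ref.masses):
                raise ConformabilityError("structures differ in masses")
        if self.s is not None:
            self.s = np.asarray(self.s, dtype=float)
            if self.s.shape != (len(self.structures),):
                raise ValueError("precomputed s length must match path length")
            if self.s[0] != 0.0 or np.any(np.diff(self.s) < 0):
                raise ValueError("precomputed s must be nondecreasing with s[0] = 0")

    def __len__(self) -> int:
        return len(self.structures)


def compute_path_coordinate(path: IRCPath) -> np.ndarray:
    """Cumulative mass-weighted path coordinate for every structure.

    Returns an array of the same length as the path with ``s[0] = 0`` and

        s[i] = s[i-1] + sqrt( Σ_j m_j (Δx² + Δy² + Δz²) )

    where Δ is taken between structures ``i`` and ``i-1``.  If the path
    carries precomputed values they are returned unchanged.
    """
    if path.s is not None:
        return path.s.copy()
    masses = path.structures[0].masses
    s = np.zeros(len(path))
    for i in range(1, len(path)):
        d = path.structures[i].coords - path.structures[i - 1].coords
        s[i] = s[i - 1] + np.sqrt(float(np.sum(masses[:, None] * d * d)))
    return s


def path_from_xyz(filename: str) -> IRCPath:
    """Build an :class:`IRCPath` from a multi-frame XYZ file, inferring
    masses from the element symbols."""
    from .io import read_xyz_frames

    labels, frames = read_xyz_frames(filename)
    masses = masses_for(labels)
    structures = [QMStructure(labels, f, masses) for f in frames]
    return IRCPath(structures)
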