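"""Standard atomic masses (amu) for the elements that occur in QM
subsystems of organic enzymatic reactions, plus a helper to map labels."""
from __future__ import annotations

import numpy as np

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Mn": 54.938, "Fe": 55.845, "Co": 58.933,
    "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "Se": 78.971, "Br": 79.904,
    "I": 126.90,
}


def element_of(label: str) -> str:
    """Element symbol for an atom label such as ``CA``, ``Cl3`` or ``h``."""
    stripped = "".join(c for c in label if c.isalpha())
    if not stripped:
        raise KeyError(f"no element in atom label {label!r}")
    two = stripped[:2].capitalize()
    if two in ATOMIC_MASSES:
        return two
    one = stripped[0].upper()
    if one in ATOMIC_MASSES:
        return one
    raise KeyError(f"unknown element for atom label {label!r}")


def masses_for(labels) -> np.ndarray:
    """Array of atomic masses (amu) matching a sequence of atom labels."""
    return np.array([ATOMIC_MASSES[element_of(l)] for l in labels])
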