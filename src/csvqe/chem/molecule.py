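"""Molecular geometries and the standard XYZ text format (Angstrom)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import ANGSTROM_TO_BOHR, ATOMIC_NUMBER


@dataclass
class MolecularGeometry:
    atoms: list[str]
    coordinates: np.ndarray          # (n_atoms, 3), Angstrom
    charge: int = 0
    multiplicity: int = 1
    basis: str = "sto-3g"

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, float))
        if len(self.atoms) != len(self.coordinates):
            raise ValueError("coordinate count must equal atom count")

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coordinates * ANGSTROM_TO_BOHR

    @property
    def atomic_numbers(self) -> list[int]:
        return [ATOMIC_NUMBER[a] for a in self.atoms]

    @property
    def n_electrons(self) -> int:
        return sum(self.atomic_numbers) - self.charge

    def nuclear_repulsion(self) -> float:
        Z = self.atomic_numbers
        R = self.coords_bohr
        e = 0.0
        for i in range(len(Z)):
            for j in range(i):
                e += Z[i] * Z[j] / np.linalg.norm(R[i] - R[j])
        return e


def n2_geometry(r_angstrom: float) -> MolecularGeometry:
    """Collinear N2 along z with separation r (Angstrom), singlet."""
    return MolecularGeometry(
        ["N", "N"], np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_angstrom]])
    )


def h2_geometry(r_angstrom: float) -> MolecularGeometry:
    return MolecularGeometry(
        ["H", "H"], np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_angstrom]])
    )


def read_xyz(path, charge: int = 0, multiplicity: int = 1,
             basis: str = "sto-3g") -> MolecularGeometry:
    """Standard XYZ dialect: count line, comment line, ``El x y z`` in Angstrom."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    atoms, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        atoms.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if len(atoms) != n:
        raise ValueError("XYZ atom count does not match header")
    return MolecularGeometry(atoms, np.array(coords), charge, multiplicity, basis)


def write_xyz(path, geom: MolecularGeometry, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(geom.atoms)}\n{comment}\n")
        for a, xyz in zip(geom.atoms, geom.coordinates):
            fh.write(f"{a} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
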