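"""Snapshot geometry handling: spherical cut and three-layer assignment.

An MD snapshot is one solute molecule plus many solvent molecules.  The
protocol retains every solvent molecule with at least one atom inside a
sphere (default 22 Å) centered on the solute center of mass, then assigns
each retained molecule to the frozen-density (FDE) layer if its nearest atom
is within the shell cutoff (3 or 5 Å) of any solute atom, and to the
polarizable MM layer otherwise.  Cuts are molecule-wise (any-atom, inclusive
distances) so fragments stay intact for the charge constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import _SYMBOL_TO_Z


@dataclass
class Molecule:
    """A rigid molecule in a snapshot: element symbols + positions (Å)."""

    elements: list[str]
    positions: np.ndarray  # (n, 3), Å
    name: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.positions):
            raise ValueError("elements/positions length mismatch")

    def __len__(self) -> int:
        return len(self.elements)

    def masses(self) -> np.ndarray:
        # nuclear charge as a mass proxy is not adequate; use standard masses
        return np.array([_ATOMIC_MASS.get(e, float(_SYMBOL_TO_Z.get(e, 1)))
                         for e in self.elements])

    def center_of_mass(self) -> np.ndarray:
        m = self.masses()
        return m @ self.positions / m.sum()


_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45,
}


@dataclass
class Snapshot:
    solute: Molecule
    solvent: list[Molecule]
    identifier: str = ""


@dataclass
class LayerPartition:
    """Assignment of every retained molecule to {QM solute, FDE, MM}."""

    solute: Molecule
    fde_molecules: list[Molecule]
    mm_molecules: list[Molecule]
    cutoff: float          # Å, FDE shell
    sphere_radius: float   # Å, spherical cut

    @property
    def n_retained(self) -> int:
        return 1 + len(self.fde_molecules) + len(self.mm_molecules)


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(a[:, None] - b[None, :], axis=-1)))


def spherical_cut(snapshot: Snapshot, radius: float = 22.0,
                  center: np.ndarray | None = None) -> list[Molecule]:
    """Retain solvent molecules with any atom within ``radius`` of the center.

    The center defaults to the solute center of mass; the solute itself is
    always retained (implicitly — it is carried by the snapshot).
    """
    if snapshot.solute is None or len(snapshot.solute) == 0:
        raise ValueError("snapshot has no solute")
    if center is None:
        center = snapshot.solute.center_of_mass()
    center = np.asarray(center, dtype=float)
    kept = []
    for mol in snapshot.solvent:
        d = np.linalg.norm(mol.positions - center, axis=1)
        if np.any(d <= radius):
            kept.append(mol)
    return kept


def assign_layers(retained: list[Molecule], solute: Molecule,
                  cutoff: float = 3.0,
                  sphere_radius: float = 22.0) -> LayerPartition:
    """Split retained solvent into FDE shell and MM bulk.

    A molecule joins the FDE layer iff its minimum interatomic distance to
    the solute is ≤ cutoff (inclusive, matching "within"); the FDE set is
    therefore monotone in the cutoff.
    """
    fde, mm = [], []
    sol_pos = solute.positions
    for mol in retained:
        if _min_distance(mol.positions, sol_pos) <= cutoff:
            fde.append(mol)
        else:
            mm.append(mol)
    return LayerPartition(solute=solute, fde_molecules=fde, mm_molecules=mm,
                          cutoff=cutoff, sphere_radius=sphere_radius)
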