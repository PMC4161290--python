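"""Molecular structure and trajectory containers.

Internal units are nanometres for all coordinates; PDB I/O converts
Angstrom <-> nm at the boundary.  Residues are numbered continuously
1..N across the chains of a complex (the original author-assigned PDB
numbering, when one exists, is retained as metadata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: standard atomic masses, u
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}
DEFAULT_MASS = 12.011


def mass_of(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``position`` is in nm, ``partial_charge`` in units of the elementary
    charge, ``radius`` in nm and ``b_factor`` in A^2 (the conventional
    crystallographic unit).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    partial_charge: float = 0.0
    radius: float = 0.0
    b_factor: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: radius must be >= 0")
        object.__setattr__(self, "position", pos)


class Structure:
    """An ordered collection of atoms with residue/chain topology.

    Parameters
    ----------
    atoms : sequence of Atom
    monomer_assignment : dict, optional
        Map residue_index -> monomer label.  Defaults to one monomer per
        chain (label = chain id).
    disulfides : list of (int, int), optional
        Residue-index pairs joined by disulfide bridges.
    original_residue_ids : dict, optional
        Map continuous residue_index -> author-assigned (chain, resid).
    """

    def __init__(self, atoms, monomer_assignment=None, disulfides=None,
                 original_residue_ids=None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("Structure requires at least one atom")
        self._atoms = atoms
        self._coords = np.array([a.position for a in atoms], dtype=float)
        self.disulfides = list(disulfides or [])
        self.original_residue_ids = dict(original_residue_ids or {})
        if monomer_assignment is None:
            monomer_assignment = {}
            for a in atoms:
                monomer_assignment.setdefault(a.residue_index, a.chain_id)
        self.monomer_assignment = dict(monomer_assignment)
        missing = {a.residue_index for a in atoms} - set(self.monomer_assignment)
        if missing:
            raise ValueError(f"residues without monomer label: {sorted(missing)}")

    # -- basic access -------------------------------------------------
    @property
    def atoms(self) -> list[Atom]:
        return self._atoms

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array in nm (a copy-free view; do not mutate)."""
        return self._coords

    def __len__(self):
        return len(self._atoms)

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self._atoms])

    @property
    def atom_names(self) -> np.ndarray:
        return np.array([a.name for a in self._atoms])

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self._atoms])

    @property
    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self._atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(a.element) for a in self._atoms])

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for a in self._atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self._atoms])

    @property
    def monomer_labels(self) -> np.ndarray:
        """Per-atom monomer label."""
        return np.array([self.monomer_assignment[a.residue_index]
                         for a in self._atoms])

    @property
    def n_residues(self) -> int:
        return len({a.residue_index for a in self._atoms})

    def residues(self):
        """Yield (residue_index, residue_name, chain_id, [atoms]) in order."""
        seen: dict[int, list[Atom]] = {}
        order = []
        for a in self._atoms:
            if a.residue_index not in seen:
                seen[a.residue_index] = []
                order.append(a.residue_index)
            seen[a.residue_index].append(a)
        for idx in order:
            grp = seen[idx]
            yield idx, grp[0].residue_name, grp[0].chain_id, grp

    def atom_index(self, residue_index: int, name: str):
        """Position of the named atom of a residue in the atom list, or None."""
        for i, a in enumerate(self._atoms):
            if a.residue_index == residue_index and a.name == name:
                return i
        return None

    # -- derived structures -------------------------------------------
    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A new Structure sharing topology but with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self._coords.shape:
            raise ValueError("coordinate array shape mismatch")
        atoms = [Atom(a.serial, a.name, a.element, a.residue_name,
                      a.residue_index, a.chain_id, c, a.partial_charge,
                      a.radius, a.b_factor)
                 for a, c in zip(self._atoms, coords)]
        return Structure(atoms, self.monomer_assignment, self.disulfides,
                         self.original_residue_ids)

    def transformed(self, rotation: np.ndarray = None,
                    translation: np.ndarray = None) -> "Structure":
        coords = self._coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return self.with_coords(coords)

    def center_of_mass(self, mask=None) -> np.ndarray:
        m = self.masses
        x = self._coords
        if mask is not None:
            m, x = m[mask], x[mask]
        if m.sum() <= 0:
            raise ValueError("zero total mass")
        return (m[:, None] * x).sum(axis=0) / m.sum()


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; ``times`` is in
    microseconds and must be strictly increasing.
    """

    topology: Structure
    coords: np.ndarray
    times: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("atom count differs between topology and frames")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times length must match frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))
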