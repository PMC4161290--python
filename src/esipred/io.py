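"""Structure and trajectory file I/O (PDB subset, XYZ).

PDB files are parsed and written through biotite; this module converts
between biotite atom arrays and the package's nm-based containers and
applies the continuous 1..N residue renumbering used throughout.
"""

from __future__ import annotations

import os

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .structure import Atom, Structure, Trajectory

NM_PER_ANGSTROM = 0.1

#: residues treated as solvent/heteroatoms and skipped by default
WATER_NAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3"}

#: S-S distance below which two cysteine sulfurs count as a disulfide, nm
DISULFIDE_CUTOFF = 0.25


class PDBParseError(ValueError):
    pass


def _atom_array_to_structure(arr, keep_hetero=False, monomers=None):
    """Convert a biotite AtomArray (coords in A) to a Structure (nm)."""
    if not keep_hetero:
        mask = ~arr.hetero & ~np.isin(arr.res_name, list(WATER_NAMES))
        if mask.sum() == 0:
            mask = ~np.isin(arr.res_name, list(WATER_NAMES))
        arr = arr[mask]
    if arr.array_length() == 0:
        raise PDBParseError("no atoms after filtering")

    # continuous residue renumbering across chains, in file order
    residue_map: dict[tuple, int] = {}
    original: dict[int, tuple] = {}
    res_index = np.empty(arr.array_length(), dtype=int)
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i] if hasattr(arr, "ins_code") else "")
        if key not in residue_map:
            residue_map[key] = len(residue_map) + 1
            original[residue_map[key]] = (str(arr.chain_id[i]), int(arr.res_id[i]))
        res_index[i] = residue_map[key]

    b = arr.b_factor if "b_factor" in arr.get_annotation_categories() else np.zeros(arr.array_length())
    atoms = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]) or str(arr.atom_name[i])[:1]
        atoms.append(Atom(
            serial=i + 1,
            name=str(arr.atom_name[i]),
            element=elem.upper(),
            residue_name=str(arr.res_name[i]),
            residue_index=int(res_index[i]),
            chain_id=str(arr.chain_id[i]),
            position=arr.coord[i] * NM_PER_ANGSTROM,
            b_factor=float(b[i]),
        ))

    structure = Structure(atoms, monomer_assignment=monomers,
                          original_residue_ids=original)
    structure.disulfides = _detect_disulfides(structure)
    return structure


def _detect_disulfides(structure: Structure):
    sg = [(a.residue_index, a.position) for a in structure.atoms
          if a.residue_name == "CYS" and a.name == "SG"]
    pairs = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if np.linalg.norm(sg[i][1] - sg[j][1]) <= DISULFIDE_CUTOFF:
                pairs.append((sg[i][0], sg[j][0]))
    return pairs


def read_pdb(path, mode="single", keep_hetero=False, monomers=None):
    """Read a PDB file.

    Parameters
    ----------
    path : str or Path
    mode : {"single", "multi_model"}
        "single" returns the first model as a :class:`Structure`;
        "multi_model" returns a :class:`Trajectory` over all models.
    keep_hetero : bool
        Retain HETATM records (water is always dropped).
    monomers : dict, optional
        residue_index -> monomer label override.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise PDBParseError(f"{path}: empty file")
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # biotite raises various error types
        raise PDBParseError(f"{path}: {exc}") from exc

    if mode == "single":
        try:
            arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
        except Exception as exc:
            raise PDBParseError(f"{path}: {exc}") from exc
        return _atom_array_to_structure(arr, keep_hetero, monomers)
    elif mode == "multi_model":
        try:
            stack = pdb.get_structure(extra_fields=["b_factor"])
        except Exception as exc:
            raise PDBParseError(f"{path}: {exc}") from exc
        if isinstance(stack, bst.AtomArray):
            stack = bst.stack([stack])
        template = _atom_array_to_structure(stack[0], keep_hetero, monomers)
        # apply the same atom filter to every model
        if not keep_hetero:
            mask = ~stack.hetero & ~np.isin(stack.res_name, list(WATER_NAMES))
            if mask.sum() == 0:
                mask = ~np.isin(stack.res_name, list(WATER_NAMES))
            stack = stack[..., mask]
        coords = stack.coord * NM_PER_ANGSTROM
        return Trajectory(template, coords)
    raise ValueError(f"unknown mode {mode!r}")


def _structure_to_atom_array(structure: Structure):
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = structure.coords / NM_PER_ANGSTROM
    arr.chain_id = structure.chain_ids
    arr.res_id = structure.residue_indices
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = structure.atom_names
    arr.element = structure.elements
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("b_factor", structure.b_factors)
    return arr


def write_pdb(obj, path):
    """Write a Structure (single model) or Trajectory (multi-model) PDB."""
    pdb = PDBFile()
    if isinstance(obj, Structure):
        pdb.set_structure(_structure_to_atom_array(obj))
    elif isinstance(obj, Trajectory):
        arrays = [_structure_to_atom_array(obj.frame(i)) for i in range(obj.n_frames)]
        pdb.set_structure(bst.stack(arrays))
    else:
        raise TypeError("write_pdb expects a Structure or Trajectory")
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------
# XYZ trajectories (element x y z per line, coordinates in Angstrom)

def write_xyz(trajectory: Trajectory, path):
    with open(path, "w") as fh:
        elements = trajectory.topology.elements
        for f in range(trajectory.n_frames):
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(f"frame {f} time_us {trajectory.times[f]:.6f}\n")
            for el, xyz in zip(elements, trajectory.coords[f] / NM_PER_ANGSTROM):
                fh.write(f"{el:<3s} {xyz[0]:12.5f} {xyz[1]:12.5f} {xyz[2]:12.5f}\n")
    return path


def read_xyz(path):
    """Read an XYZ trajectory into a Trajectory with minimal topology."""
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise PDBParseError(f"{path}:{i+1}: expected atom count") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise PDBParseError(f"{path}:{i+1}: truncated frame")
        els, xyz = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise PDBParseError(f"{path}:{i+3+j}: malformed record")
            els.append(parts[0].upper())
            xyz.append([float(p) for p in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise PDBParseError(f"{path}:{i+1}: inconsistent atom list")
        frames.append(np.asarray(xyz) * NM_PER_ANGSTROM)
        i += 2 + n
    if not frames:
        raise PDBParseError(f"{path}: empty file")
    atoms = [Atom(serial=k + 1, name=el, element=el, residue_name="UNK",
                  residue_index=1, chain_id="A", position=frames[0][k])
             for k, el in enumerate(elements)]
    template = Structure(atoms)
    return Trajectory(template, np.stack(frames))


def export_site_inventory(inventory, path):
    """Write a site inventory as TSV (site_id, residue_index, kind, polarity, gb)."""
    import pandas as pd
    rows = [{"site_id": s.site_id, "residue_index": s.residue_index,
             "kind": s.kind, "polarity": s.polarity,
             "gb_intrinsic": s.gb_intrinsic} for s in inventory.sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
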