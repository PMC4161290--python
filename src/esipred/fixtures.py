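"""Deterministic synthetic structures and trajectories.

Every generator is reproducible from its arguments and seed and emits
structures consumable by the rest of the package, so each analysis
stage can be exercised with analytically known ground truth and no
external downloads.  None of these aim for realistic protein geometry
beyond what their target tests require.
"""

from __future__ import annotations

import numpy as np

from .sites import (ANCHOR_ATOMS, IonizableSite, ONE_TO_THREE, SiteInventory,
                    insulin_dimer_chains)
from .structure import Atom, Structure, Trajectory
# ideal backbone geometry, Angstrom / degrees
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_C_N_CA = 121.7
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_CA_C_O = 120.8


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """n approximately equidistributed points on a sphere (nm)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return radius * np.column_stack([np.sin(phi) * np.cos(theta),
                                     np.sin(phi) * np.sin(theta),
                                     np.cos(phi)])


def _nerf(a, b, c, bond, angle, dihedral):
    """Place atom D bonded to C given internal coordinates (deg, A)."""
    angle = np.radians(angle)
    dihedral = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(angle),
                               np.sin(angle) * np.cos(dihedral),
                               np.sin(angle) * np.sin(dihedral)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(n_res: int, phi: float, psi: float,
                   residue_names=None, chain_id: str = "A",
                   first_residue: int = 1, serial_start: int = 1):
    """Ideal-geometry peptide backbone (N, CA, C, O per residue).

    Dihedrals are uniform (phi, psi) with trans peptide bonds; returns
    a list of Atom in nm.
    """
    if n_res < 2:
        raise ValueError("need at least two residues")
    if residue_names is None:
        residue_names = ["ALA"] * n_res
    N = np.array([0.0, 0.0, 0.0])
    CA = N + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(_ANGLE_N_CA_C)
    C = CA + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords = [{"N": N, "CA": CA, "C": C}]
    for i in range(1, n_res):
        prev = coords[-1]
        Nn = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N,
                   _ANGLE_CA_C_N, psi)
        CAn = _nerf(prev["CA"], prev["C"], Nn, _BOND_N_CA,
                    _ANGLE_C_N_CA, 180.0)
        Cn = _nerf(prev["C"], Nn, CAn, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        coords.append({"N": Nn, "CA": CAn, "C": Cn})
    for i, res in enumerate(coords):
        res["O"] = _nerf(res["N"], res["CA"], res["C"], _BOND_C_O,
                         _ANGLE_CA_C_O, psi + 180.0)

    atoms = []
    serial = serial_start
    for i, res in enumerate(coords):
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(serial=serial, name=name,
                              element=name[0],
                              residue_name=residue_names[i],
                              residue_index=first_residue + i,
                              chain_id=chain_id,
                              position=res[name] * 0.1))  # A -> nm
            serial += 1
    return atoms


def make_ideal_helix(n_res: int = 15, phi: float = -57.0,
                     psi: float = -47.0) -> Structure:
    """A uniform alpha-helix (backbone only)."""
    return Structure(build_backbone(n_res, phi, psi))


def make_extended_chain(n_res: int = 10) -> Structure:
    """A fully extended chain (phi = psi = 180)."""
    return Structure(build_backbone(n_res, 180.0, 180.0))


def _ks_inter_strand_bonds(bb1, bb2, cutoff=-0.5):
    """Count Kabsch-Sander H-bonds between two strand backbones.

    ``bb`` is a dict of (n, 3) arrays N, H, C, O in Angstrom (H may
    contain NaN rows for chain-leading amides).
    """
    count = 0
    for don, acc in ((bb1, bb2), (bb2, bb1)):
        r_on = np.linalg.norm(acc["O"][None] - don["N"][:, None], axis=2)
        r_ch = np.linalg.norm(acc["C"][None] - don["H"][:, None], axis=2)
        r_oh = np.linalg.norm(acc["O"][None] - don["H"][:, None], axis=2)
        r_cn = np.linalg.norm(acc["C"][None] - don["N"][:, None], axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = 0.084 * 332 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        e = np.where(np.isnan(e), 0.0, e)
        count += int((e < cutoff).sum())
    return count


def _strand_backbone_arrays(atoms):
    """Per-residue N, CA, C, O (+ inferred H) arrays in Angstrom."""
    res: dict[int, dict] = {}
    for a in atoms:
        res.setdefault(a.residue_index, {})[a.name] = a.position * 10.0
    order = sorted(res)
    bb = {k: np.array([res[i][k] for i in order]) for k in "N CA C O".split()}
    h = np.full((len(order), 3), np.nan)
    for k in range(1, len(order)):
        co = bb["C"][k - 1] - bb["O"][k - 1]
        h[k] = bb["N"][k] + co / np.linalg.norm(co)
    bb["H"] = h
    return bb


_BETA_PAIR_CACHE: dict[int, Structure] = {}


def make_beta_pair(n_res: int = 8) -> Structure:
    """Two-stranded antiparallel beta pair.

    The second strand is the first one flipped about the strand axis
    and shifted; the placement is chosen at construction time (grid
    search over rigid offsets) to maximise the number of
    Kabsch-Sander backbone hydrogen bonds between the strands.
    """
    if n_res in _BETA_PAIR_CACHE:
        return _BETA_PAIR_CACHE[n_res]
    strand = build_backbone(n_res, -135.0, 135.0, chain_id="A")
    coords = np.array([a.position for a in strand])
    # align the strand axis (first CA -> last CA) with x
    ca = coords[1::4]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    v = np.cross(axis, [1.0, 0.0, 0.0])
    s = np.linalg.norm(v)
    if s > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - axis[0]) / s**2)
        coords = (coords - ca[0]) @ R.T
    strand = [Atom(a.serial, a.name, a.element, a.residue_name,
                   a.residue_index, a.chain_id, coords[k])
              for k, a in enumerate(strand)]
    bb1 = _strand_backbone_arrays(strand)

    best = None
    for flip in (np.diag([-1.0, -1.0, 1.0]), np.diag([-1.0, 1.0, -1.0])):
        flipped = coords @ flip
        center = coords[:, 0].mean() - flipped[:, 0].mean()
        for dy in np.arange(0.40, 0.58, 0.02):
            for dx in np.arange(-0.45, 0.46, 0.03):
                for dz in np.arange(-0.2, 0.21, 0.05):
                    shift = np.array([dx + center, dy, dz])
                    bb2 = {k: (v @ flip + shift * 10.0) if k != "H" else None
                           for k, v in bb1.items()}
                    bb2["H"] = bb1["H"] @ flip + shift * 10.0
                    n_bonds = _ks_inter_strand_bonds(bb1, bb2)
                    if best is None or n_bonds > best[0]:
                        best = (n_bonds, flip, shift)

    _, flip, shift = best
    coords2 = coords @ flip + shift
    atoms = list(strand)
    for k, a in enumerate(strand):
        atoms.append(Atom(serial=len(strand) + k + 1, name=a.name,
                          element=a.element, residue_name=a.residue_name,
                          residue_index=n_res + a.residue_index,
                          chain_id="B", position=coords2[k]))
    result = Structure(atoms)
    _BETA_PAIR_CACHE[n_res] = result
    return result


def make_charged_shell(n_sites: int, radius: float, gb_values=None,
                       seed: int = 0, jitter: float = 0.0):
    """Proton-accepting sites spread on a sphere (analytic testbed).

    Each site is a single lysine-like nitrogen bead; the apparent
    basicity at any charge is computable by direct Coulomb sums over
    the known coordinates, which makes this the oracle system for
    charge-prediction tests.  Returns ``(structure, inventory)``.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if gb_values is None:
        gb_values = np.full(n_sites, 900.0)
    gb_values = np.asarray(gb_values, dtype=float)
    rng = np.random.default_rng(seed)
    pos = fibonacci_sphere(n_sites, radius)
    if jitter > 0:
        pos = pos + rng.normal(0, jitter, pos.shape)
    atoms = [Atom(serial=i + 1, name="NZ", element="N", residue_name="LYS",
                  residue_index=i + 1, chain_id="A", position=pos[i])
             for i in range(n_sites)]
    structure = Structure(atoms)
    inventory = SiteInventory([
        IonizableSite(0, i + 1, "K", "proton_accepting", i + 1,
                      float(gb_values[i]))
        for i in range(n_sites)])
    return structure, inventory


_TOY_CYCLE = "GREQA"  # gly, arg, glu, gln, ala


def make_toy_dimer(n_res_per_monomer: int = 5, seed: int = 0):
    """Two-chain toy complex with known ground truth.

    Each monomer is an extended backbone whose sequence cycles through
    G, R, E, Q, A, plus one side-chain anchor atom per ionizable
    residue.  A single inter-monomer carbon pair sits at exactly
    0.5 nm.  Returns ``(structure, truth)`` where truth records the
    constructed site and contact counts.
    """
    if n_res_per_monomer < 3:
        raise ValueError("need at least three residues per monomer")
    n = n_res_per_monomer
    seq = [_TOY_CYCLE[i % len(_TOY_CYCLE)] for i in range(n)]
    names = [ONE_TO_THREE[a] for a in seq]

    atoms = []
    serial = 1
    for m, (chain, zoff) in enumerate((("A", 0.0), ("B", 3.0))):
        backbone = build_backbone(n, 180.0, 180.0, residue_names=names,
                                  chain_id=chain, first_residue=m * n + 1,
                                  serial_start=serial)
        shift = np.array([0.0, 0.0, zoff])
        for a in backbone:
            atoms.append(Atom(a.serial, a.name, a.element, a.residue_name,
                              a.residue_index, a.chain_id,
                              a.position + shift))
        serial += len(backbone)
        # side-chain anchors 0.3 nm above each ionizable residue's CA
        for i, letter in enumerate(seq):
            if letter in ("R", "E", "Q"):
                ca = next(x for x in backbone
                          if x.residue_index == m * n + i + 1
                          and x.name == "CA")
                anchor = ANCHOR_ATOMS[letter]
                atoms.append(Atom(serial, anchor,
                                  "N" if anchor.startswith("N") else "C",
                                  ONE_TO_THREE[letter], ca.residue_index,
                                  chain, ca.position + shift
                                  + np.array([0.0, 0.3, 0.0])))
                serial += 1
    # one designated inter-monomer carbon pair at 0.5 nm, far from the rest
    bridge = np.array([0.0, 3.0, 1.5])
    atoms.append(Atom(serial, "CB", "C", names[-1], n, "A", bridge))
    atoms.append(Atom(serial + 1, "CB", "C", names[0], n + 1, "B",
                      bridge + np.array([0.5, 0.0, 0.0])))

    structure = Structure(atoms)
    n_r = sum(1 for a in seq if a == "R")
    n_q = sum(1 for a in seq if a == "Q")
    n_e = sum(1 for a in seq if a == "E")
    truth = {
        "n_base_gas": 2 * (1 + n_r + n_q),     # N-term + R + Q per chain
        "n_acid_gas": 2 * (1 + n_e),           # C-term + E per chain
        "n_base_solution": 2 * (1 + n_r),
        "n_acid_solution": 2 * (1 + n_e),
        "inter_monomer_carbon_contacts_060": 1,
        "n_term_sites": 2, "c_term_sites": 2,
    }
    return structure, truth


def make_insulin_dimer_model(seed: int = 0, radius: float = 2.1,
                             jitter: float = 0.02) -> Structure:
    """Synthetic coarse-grained surface model of the human insulin dimer.

    A stand-in for the crystal structure: the dimer's 102 residues
    (chains A/B of each monomer, numbered continuously) are placed as
    one bead each on a sphere whose radius reflects the complex's
    reported aqueous size (equivalent-sphere radius of Rg = 1.37 nm
    plus a side-chain arm).  The bead carries the residue identity, so
    the gas-phase ionizable-site inventory derived from it is exactly
    the sequence-derived one (18 proton-accepting, 12 deprotonatable
    sites); only the geometry is synthetic.
    """
    chains = insulin_dimer_chains()
    chain_ids = ["A", "B", "C", "D"]
    n_total = sum(len(c) for c in chains)
    rng = np.random.default_rng(seed)
    pos = fibonacci_sphere(n_total, radius)
    if jitter > 0:
        pos = pos + rng.normal(0, jitter, pos.shape)
    atoms = []
    idx = 0
    monomers = {}
    for cid, chain in zip(chain_ids, chains):
        for aa in chain:
            atoms.append(Atom(serial=idx + 1, name="CA", element="C",
                              residue_name=ONE_TO_THREE[aa],
                              residue_index=idx + 1, chain_id=cid,
                              position=pos[idx]))
            monomers[idx + 1] = "I" if idx < n_total // 2 else "II"
            idx += 1
    return Structure(atoms, monomer_assignment=monomers)


def make_trajectory(base_structure: Structure, mode: str, n_frames: int,
                    seed: int = 0, **params) -> Trajectory:
    """Synthetic trajectories over a fixed topology.

    Modes: ``rigid`` (random rigid rotations+translations; the
    essential-dynamics null), ``oscillation`` (one atom oscillates
    along x; a pure essential mode), ``jitter`` (isotropic Gaussian
    noise; RMSF ground truth), ``random_walk`` (per-atom diffusion;
    the high-cosine-content regime).
    """
    if n_frames < 2:
        raise ValueError("trajectories need at least 2 frames")
    rng = np.random.default_rng(seed)
    base = base_structure.coords
    frames = np.empty((n_frames, base.shape[0], 3))
    if mode == "rigid":
        from scipy.spatial.transform import Rotation
        frames[0] = base
        for f in range(1, n_frames):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(0, params.get("translation", 1.0), 3)
            frames[f] = base @ R.T + t
    elif mode == "oscillation":
        amp = params.get("amplitude", 0.5)
        atom = params.get("atom", 0)
        cycles = params.get("cycles", 3)
        for f in range(n_frames):
            frames[f] = base
            frames[f] = base.copy()
            frames[f][atom, 0] += amp * np.sin(
                2 * np.pi * cycles * f / (n_frames - 1))
    elif mode == "jitter":
        sigma = params.get("sigma", 0.05)
        frames[:] = base[None] + rng.normal(0, sigma, frames.shape)
    elif mode == "random_walk":
        step = params.get("step", 0.05)
        frames[0] = base
        for f in range(1, n_frames):
            frames[f] = frames[f - 1] + rng.normal(0, step,
                                                   base.shape)
    else:
        raise ValueError(f"unknown trajectory mode {mode!r}")
    return Trajectory(base_structure, frames)
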