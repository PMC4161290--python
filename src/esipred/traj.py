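"""Structural observables over gas-phase trajectories.

Rigid-body superposition (Kabsch), radius of gyration, RMSD/RMSF and
crystallographic B-factors, geometric hydrogen bonds, inter-monomer
carbon contacts, centre-of-mass angles, essential dynamics analysis
and the Hess cosine-content convergence diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import Structure, Trajectory


# ---------------------------------------------------------------------
# superposition / RMSD

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights=None):
    """Optimal least-squares rigid superposition of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference.
    The rotation is proper (det = +1).  Collinear/degenerate inputs
    fall back to a translation-only fit with a warning.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must share shape (n, 3)")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # degenerate if the points span fewer than 2 dimensions
    if P.shape[0] < 3 or S[1] < 1e-12 * max(S[0], 1e-300):
        warnings.warn("degenerate (collinear) input; translation-only fit")
        R = np.eye(3)
    else:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return R, t, rmsd


def rmsd(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    """Minimum RMSD between two conformations (after superposition)."""
    return kabsch_superpose(a, b, weights)[2]


def superpose_trajectory(trajectory: Trajectory, reference=None,
                         weights=None) -> Trajectory:
    """Superpose every frame onto a reference coordinate set."""
    ref = trajectory.coords[0] if reference is None else np.asarray(reference)
    out = np.empty_like(trajectory.coords)
    for f in range(trajectory.n_frames):
        R, t, _ = kabsch_superpose(trajectory.coords[f], ref, weights)
        out[f] = trajectory.coords[f] @ R.T + t
    return Trajectory(trajectory.topology, out, trajectory.times)


# ---------------------------------------------------------------------
# size / flexibility

def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the centre of mass (nm)."""
    x = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one atom")
    if m.sum() <= 0:
        raise ValueError("zero total mass")
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rmsf_and_bfactor(trajectory: Trajectory, selection=None,
                     align: bool = True):
    """Per-atom RMSF (nm) and B-factor (A^2) about the mean structure.

    B = (8 pi^2 / 3) * RMSF_A^2 with RMSF expressed in Angstrom.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    traj = superpose_trajectory(trajectory) if align else trajectory
    coords = traj.coords if selection is None else traj.coords[:, selection]
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    b = (8 * np.pi ** 2 / 3) * (rmsf * 10.0) ** 2
    return rmsf, b


# ---------------------------------------------------------------------
# interactions

#: default geometric hydrogen-bond criterion
HBOND_DISTANCE_CUTOFF = 0.35  # nm, donor-acceptor
HBOND_ANGLE_CUTOFF = 30.0     # degrees, H-D-A


def find_donors_acceptors(structure: Structure, bond_cutoff: float = 0.125):
    """Polar-atom inventory: donors as (D, H) index pairs (N/O with a
    covalently bound hydrogen), acceptors as N/O indices."""
    elements = structure.elements
    coords = structure.coords
    heavy = np.flatnonzero(np.isin(elements, ["N", "O"]))
    hydro = np.flatnonzero(elements == "H")
    donors = []
    if len(heavy) and len(hydro):
        d = cdist(coords[heavy], coords[hydro])
        for hi, h in enumerate(hydro):
            j = np.argmin(d[:, hi])
            if d[j, hi] <= bond_cutoff:
                donors.append((int(heavy[j]), int(h)))
    acceptors = [int(i) for i in heavy]
    return donors, acceptors


def hydrogen_bonds(structure: Structure, donors=None, acceptors=None,
                   d_cut: float = HBOND_DISTANCE_CUTOFF,
                   angle_cut: float = HBOND_ANGLE_CUTOFF,
                   groups=None):
    """Geometric hydrogen bonds in one frame.

    Criterion: donor-acceptor distance <= d_cut and H-D-A angle
    <= angle_cut; pairs within the same residue are excluded.
    ``groups`` restricts to bonds between two atom-index sets
    (either direction), e.g. for inter-monomer counts.

    Returns ``(count, bonds)`` with bonds as (donor, hydrogen,
    acceptor) index triples.
    """
    if donors is None or acceptors is None:
        auto_d, auto_a = find_donors_acceptors(structure)
        donors = donors if donors is not None else auto_d
        acceptors = acceptors if acceptors is not None else auto_a
    coords = structure.coords
    res = structure.residue_indices
    ga = gb = None
    if groups is not None:
        ga, gb = (np.asarray(g) for g in groups)
    bonds = []
    for d_idx, h_idx in donors:
        dv = coords[d_idx]
        hv = coords[h_idx]
        for a_idx in acceptors:
            if a_idx == d_idx or res[a_idx] == res[d_idx]:
                continue
            if groups is not None:
                if not ((d_idx in ga and a_idx in gb) or
                        (d_idx in gb and a_idx in ga)):
                    continue
            r = np.linalg.norm(coords[a_idx] - dv)
            if r > d_cut or r == 0:
                continue
            v1 = hv - dv
            v2 = coords[a_idx] - dv
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang <= angle_cut:
                bonds.append((d_idx, h_idx, a_idx))
    return len(bonds), bonds


def carbon_contacts(structure: Structure, cutoff: float = 0.60) -> int:
    """Inter-monomer carbon-carbon pairs within ``cutoff`` nm."""
    labels = structure.monomer_labels
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("carbon contacts need at least two monomers")
    carbon = structure.elements == "C"
    count = 0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            a = structure.coords[carbon & (labels == uniq[i])]
            b = structure.coords[carbon & (labels == uniq[j])]
            if len(a) and len(b):
                count += int((cdist(a, b) <= cutoff).sum())
    return count


def com_angle(structure: Structure, group_a, group_vertex, group_b) -> float:
    """Angle (degrees) at the vertex group's centre of mass between the
    COMs of two flanking groups."""
    coms = []
    for g in (group_a, group_vertex, group_b):
        g = np.asarray(g)
        if g.size == 0:
            raise ValueError("empty group")
        coms.append(structure.center_of_mass(g))
    a, v, b = coms
    va, vb = a - v, b - v
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("vertex COM coincides with a flanking COM")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------
# essential dynamics

@dataclass
class EDAResult:
    eigenvectors: np.ndarray   # (3n, k), columns orthonormal
    eigenvalues: np.ndarray    # (k,), nm^2, descending
    projections: np.ndarray    # (n_frames, k), nm
    mean_coords: np.ndarray    # (n, 3)

    def cosine_content(self, component: int = 0) -> float:
        return cosine_content(self.projections[:, component], index=1)


def eda(trajectory: Trajectory, selection=None, reference=None,
        n_components: int | None = None, tol: float = 1e-6,
        max_iter: int = 50) -> EDAResult:
    """Essential dynamics: PCA of the coordinate covariance after
    iterative superposition onto the converged mean structure."""
    if trajectory.n_frames < 2:
        raise ValueError("EDA needs at least two frames")
    coords = trajectory.coords if selection is None \
        else trajectory.coords[:, selection]
    n_frames, n_atoms, _ = coords.shape

    ref = coords[0] if reference is None else np.asarray(reference)
    aligned = coords.copy()
    for _ in range(max_iter):
        for f in range(n_frames):
            R, t, _ = kabsch_superpose(aligned[f], ref)
            aligned[f] = aligned[f] @ R.T + t
        new_mean = aligned.mean(axis=0)
        if np.abs(new_mean - ref).max() < tol:
            ref = new_mean
            break
        ref = new_mean

    X = aligned.reshape(n_frames, 3 * n_atoms) - ref.reshape(-1)
    cov = X.T @ X / (n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    k = n_components or min(n_frames - 1, 3 * n_atoms)
    if n_components is not None and n_components > n_frames - 1:
        warnings.warn("fewer informative components than requested; truncated")
        k = n_frames - 1
    projections = X @ evecs[:, :k]
    return EDAResult(evecs[:, :k], evals[:k], projections, ref)


def cosine_content(projection, index: int = 1) -> float:
    """Hess cosine content of a principal-component projection.

    c_i = (2/T) (int cos(i pi t / T) p(t) dt)^2 / int p(t)^2 dt on the
    uniform time grid of the series (trapezoid rule).  Values near 1
    signal random-diffusion-like, unconverged sampling.
    """
    p = np.asarray(projection, dtype=float)
    if p.ndim != 1 or len(p) < 4:
        raise ValueError("need a 1-D series of length >= 4")
    norm = np.trapezoid(p * p)
    if norm == 0:
        raise ValueError("zero-variance projection")
    T = len(p) - 1
    t = np.arange(len(p))
    num = np.trapezoid(np.cos(index * np.pi * t / T) * p)
    return float(2.0 / T * num ** 2 / norm)


# ---------------------------------------------------------------------
# summary table

def summarize_trajectory(trajectory: Trajectory, config: dict | None = None
                         ) -> pd.DataFrame:
    """Per-frame structural property table.

    ``config`` toggles columns: rg (default on), rg_per_monomer,
    com_distance, hbonds, hbonds_inter, contacts, ccs (off by default;
    slower) with optional sub-dicts of keyword arguments.
    """
    config = dict(config or {})
    topo = trajectory.topology
    masses = topo.masses
    labels = topo.monomer_labels
    uniq = list(np.unique(labels))
    rows = []
    for f in range(trajectory.n_frames):
        frame = trajectory.frame(f)
        row = {"frame": f, "time_us": trajectory.times[f]}
        if config.get("rg", True):
            row["rg_nm"] = radius_of_gyration(frame.coords, masses)
        if config.get("rg_per_monomer", False):
            for lab in uniq:
                m = labels == lab
                row[f"rg_{lab}_nm"] = radius_of_gyration(
                    frame.coords[m], masses[m])
        if config.get("com_distance", False) and len(uniq) >= 2:
            a = frame.center_of_mass(labels == uniq[0])
            b = frame.center_of_mass(labels == uniq[1])
            row["com_distance_nm"] = float(np.linalg.norm(a - b))
        if config.get("hbonds", False):
            row["n_hbonds"], _ = hydrogen_bonds(frame)
        if config.get("hbonds_inter", False) and len(uniq) >= 2:
            ga = np.flatnonzero(labels == uniq[0])
            gb = np.flatnonzero(labels == uniq[1])
            row["n_hbonds_inter"], _ = hydrogen_bonds(frame, groups=(ga, gb))
        if config.get("contacts", False) and len(uniq) >= 2:
            row["n_contacts"] = carbon_contacts(
                frame, cutoff=config.get("contact_cutoff", 0.60))
        if config.get("ccs", False):
            from .ccs import pa_ccs
            res = pa_ccs(frame, rng=config.get("seed", 0),
                         **config.get("ccs_params", {}))
            row["ccs_nm2"] = res.mean
        rows.append(row)
    return pd.DataFrame(rows)
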