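"""Trajectory observables: superposition, Rg, RMSF, bonds, EDA, cosine."""

import numpy as np
import pytest

from esipred import (carbon_contacts, com_angle, cosine_content, eda,
                     hydrogen_bonds, kabsch_superpose, radius_of_gyration,
                     rmsd, rmsf_and_bfactor, summarize_trajectory,
                     superpose_trajectory)
from esipred.fixtures import make_trajectory
from esipred.structure import Atom, Structure, Trajectory

from conftest import simple_structure


# ---------------------------------------------------------------------
# Kabsch superposition

def test_kabsch_identical_sets_zero_rmsd():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    R, t, r = kabsch_superpose(pts, pts)
    assert r == pytest.approx(0.0, abs=1e-12)
    assert R == pytest.approx(np.eye(3), abs=1e-10)


def test_kabsch_recovers_constructed_transform():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12, 3))
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    moved = pts @ Rz.T + np.array([1.0, -2.0, 0.5])
    R, t, r = kabsch_superpose(moved, pts)
    assert r == pytest.approx(0.0, abs=1e-10)
    assert R @ Rz == pytest.approx(np.eye(3), abs=1e-10)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_kabsch_collinear_translation_only():
    mobile = np.array([[-0.5, 0, 0], [0.5, 0, 0]])
    ref = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
    with pytest.warns(UserWarning, match="degenerate"):
        R, t, r = kabsch_superpose(mobile, ref)
    assert r == pytest.approx(0.5)


def test_rmsd_symmetry():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
    assert rmsd(a, b) == pytest.approx(rmsd(b, a), rel=1e-9)
    assert rmsd(a, a) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------
# radius of gyration

def test_rg_single_atom_zero():
    assert radius_of_gyration([[1.0, 2.0, 3.0]], [12.0]) == 0.0


def test_rg_two_equal_masses():
    assert radius_of_gyration([[0, 0, 0], [2.0, 0, 0]],
                              [1.0, 1.0]) == pytest.approx(1.0)


def test_rg_square_closed_form():
    s = 0.7
    pts = [[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]]
    assert radius_of_gyration(pts, [1.0] * 4) == pytest.approx(s / np.sqrt(2))


def test_rg_zero_mass_errors():
    with pytest.raises(ValueError):
        radius_of_gyration([[0, 0, 0]], [0.0])


# ---------------------------------------------------------------------
# RMSF / B-factor

def test_rmsf_static_trajectory_zero(toy_dimer):
    s, _ = toy_dimer
    traj = Trajectory(s, np.repeat(s.coords[None], 5, axis=0))
    rmsf, b = rmsf_and_bfactor(traj)
    assert np.all(rmsf == pytest.approx(0.0, abs=1e-12))
    assert np.all(b == pytest.approx(0.0, abs=1e-10))


def test_bfactor_closed_form_at_1_angstrom():
    # RMSF 0.1 nm = 1 A -> B = 8 pi^2 / 3
    rmsf_nm = np.array([0.1])
    b = (8 * np.pi ** 2 / 3) * (rmsf_nm * 10) ** 2
    assert b[0] == pytest.approx(26.319, abs=1e-2)
    # and through the API: two frames displaced +/- 0.1 nm about the mean
    s = simple_structure([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]])
    coords = np.repeat(s.coords[None], 2, axis=0)
    coords[0, 0, 0] -= 0.1
    coords[1, 0, 0] += 0.1
    traj = Trajectory(s, coords)
    rmsf, b = rmsf_and_bfactor(traj, align=False)
    assert rmsf[0] == pytest.approx(0.1, rel=1e-9)
    assert b[0] == pytest.approx(8 * np.pi ** 2 / 3, rel=1e-9)


def test_rmsf_gaussian_jitter_sigma_sqrt3(toy_dimer):
    s, _ = toy_dimer
    sigma = 0.05
    traj = make_trajectory(s, "jitter", 10_000, seed=4, sigma=sigma)
    rmsf, _ = rmsf_and_bfactor(traj, align=False)
    assert rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.02)


def test_rmsf_single_frame_errors(toy_dimer):
    s, _ = toy_dimer
    with pytest.raises(ValueError):
        rmsf_and_bfactor(Trajectory(s, s.coords[None]))


# ---------------------------------------------------------------------
# hydrogen bonds

def _hbond_frame(acceptor_pos):
    atoms = [
        Atom(1, "N", "N", "GLY", 1, "A", [0.0, 0.0, 0.0]),
        Atom(2, "H", "H", "GLY", 1, "A", [0.1, 0.0, 0.0]),
        Atom(3, "O", "O", "GLY", 2, "A", acceptor_pos),
    ]
    return Structure(atoms)


def test_hbond_linear_geometry_counts():
    s = _hbond_frame([0.3, 0.0, 0.0])
    n, bonds = hydrogen_bonds(s)
    assert n == 1
    assert bonds[0] == (0, 1, 2)


def test_hbond_perpendicular_geometry_rejected():
    s = _hbond_frame([0.0, 0.3, 0.0])
    n, _ = hydrogen_bonds(s)
    assert n == 0


def test_hbond_distance_cutoff():
    s = _hbond_frame([0.4, 0.0, 0.0])
    assert hydrogen_bonds(s)[0] == 0
    assert hydrogen_bonds(s, d_cut=0.45)[0] == 1


def test_hbond_no_hydrogens_zero(toy_dimer):
    s, _ = toy_dimer  # backbone-only fixture carries no hydrogens
    assert hydrogen_bonds(s)[0] == 0


def test_hbond_atom_reordering_invariant():
    atoms = [
        Atom(1, "O", "O", "GLY", 2, "A", [0.3, 0.0, 0.0]),
        Atom(2, "N", "N", "GLY", 1, "A", [0.0, 0.0, 0.0]),
        Atom(3, "H", "H", "GLY", 1, "A", [0.1, 0.0, 0.0]),
    ]
    assert hydrogen_bonds(Structure(atoms))[0] == 1


# ---------------------------------------------------------------------
# contacts

def test_carbon_contacts_by_construction(toy_dimer):
    s, truth = toy_dimer
    assert carbon_contacts(s) == truth["inter_monomer_carbon_contacts_060"]


def test_carbon_contacts_cutoff_sensitivity(toy_dimer):
    s, _ = toy_dimer  # the constructed pair sits at exactly 0.5 nm
    assert carbon_contacts(s, cutoff=0.45) == 0


def test_carbon_contacts_matches_bruteforce():
    rng = np.random.default_rng(3)
    a = rng.uniform(0, 1.5, (20, 3))
    b = rng.uniform(0, 1.5, (20, 3))
    atoms = [Atom(i + 1, "C", "C", "ALA", 1, "A", p) for i, p in enumerate(a)]
    atoms += [Atom(21 + i, "C", "C", "ALA", 2, "B", p)
              for i, p in enumerate(b)]
    s = Structure(atoms)
    oracle = sum(np.linalg.norm(x - y) <= 0.6 for x in a for y in b)
    assert carbon_contacts(s) == oracle


def test_carbon_contacts_single_monomer_errors():
    s = simple_structure([[0, 0, 0], [0.5, 0, 0]])
    s.monomer_assignment = {1: "A", 2: "A"}
    with pytest.raises(ValueError):
        carbon_contacts(s)


# ---------------------------------------------------------------------
# COM angle

def test_com_angle_collinear_180():
    s = simple_structure([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    assert com_angle(s, [0], [1], [2]) == pytest.approx(180.0)


def test_com_angle_right_angle():
    s = simple_structure([[0, 1, 0], [0, 0, 0], [1, 0, 0]])
    assert com_angle(s, [0], [1], [2]) == pytest.approx(90.0)


def test_com_angle_matches_bruteforce(toy_dimer):
    s, _ = toy_dimer
    rng = np.random.default_rng(6)
    idx = rng.permutation(s.n_atoms)
    ga, gv, gb = idx[:5], idx[5:10], idx[10:15]
    m = s.masses
    coms = [np.average(s.coords[g], axis=0, weights=m[g])
            for g in (ga, gv, gb)]
    va, vb = coms[0] - coms[1], coms[2] - coms[1]
    expected = np.degrees(np.arccos(
        np.dot(va, vb) / np.linalg.norm(va) / np.linalg.norm(vb)))
    assert com_angle(s, ga, gv, gb) == pytest.approx(expected, rel=1e-9)


def test_com_angle_coincident_coms_error():
    s = simple_structure([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError):
        com_angle(s, [0], [1], [2])


# ---------------------------------------------------------------------
# essential dynamics

def test_eda_rigid_motion_removed(toy_dimer):
    s, _ = toy_dimer
    traj = make_trajectory(s, "rigid", 8, seed=2)
    res = eda(traj)
    assert res.eigenvalues.max() < 1e-12


def test_eda_single_mode_dominates(toy_dimer):
    s, _ = toy_dimer
    traj = make_trajectory(s, "oscillation", 60, amplitude=0.4, atom=0)
    res = eda(traj)
    assert res.eigenvalues[0] / res.eigenvalues.sum() > 0.99
    # leading eigenvector concentrates on the moving atom's x coordinate
    v = res.eigenvectors[:, 0].reshape(-1, 3)
    assert abs(v[0, 0]) > 0.95


def test_eda_duplicated_frames_zero_covariance(toy_dimer):
    s, _ = toy_dimer
    traj = Trajectory(s, np.repeat(s.coords[None], 4, axis=0))
    res = eda(traj)
    assert res.eigenvalues.max() == pytest.approx(0.0, abs=1e-15)


def test_eda_trace_conservation():
    s = simple_structure(np.random.default_rng(9).normal(size=(5, 3)))
    traj = make_trajectory(s, "jitter", 40, seed=9, sigma=0.05)
    res = eda(traj)  # 3n = 15 components < n_frames
    aligned = superpose_trajectory(traj, reference=res.mean_coords)
    # realign onto the converged EDA mean before computing total variance
    X = aligned.coords.reshape(40, -1)
    X = X - X.mean(axis=0)
    total_var = (X ** 2).sum() / (40 - 1)
    assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)
    # eigenvectors orthonormal
    V = res.eigenvectors
    assert V.T @ V == pytest.approx(np.eye(V.shape[1]), abs=1e-8)


# ---------------------------------------------------------------------
# cosine content

def test_cosine_content_defining_mode():
    t = np.arange(1001)
    p = np.cos(np.pi * t / 1000)
    assert cosine_content(p, 1) == pytest.approx(1.0, abs=1e-3)


def test_cosine_content_orthogonal_mode():
    t = np.arange(1001)
    p = np.cos(2 * np.pi * t / 1000)
    assert cosine_content(p, 1) == pytest.approx(0.0, abs=1e-3)


def test_cosine_content_random_walk_high(toy_dimer):
    """Unconverged diffusive sampling shows near-unity cosine content."""
    s, _ = toy_dimer
    values = []
    for seed in range(20):
        traj = make_trajectory(s, "random_walk", 1000, seed=seed, step=0.02)
        res = eda(traj, n_components=1)
        values.append(cosine_content(res.projections[:, 0], 1))
    assert np.median(values) > 0.5


def test_cosine_content_zero_variance_errors():
    with pytest.raises(ValueError):
        cosine_content(np.zeros(10), 1)


# ---------------------------------------------------------------------
# summary table

def test_summary_static_trajectory_zero_std(toy_dimer):
    s, _ = toy_dimer
    traj = Trajectory(s, np.repeat(s.coords[None], 3, axis=0))
    table = summarize_trajectory(traj, {"rg": True, "com_distance": True,
                                        "contacts": True})
    assert table["rg_nm"].std(ddof=0) == pytest.approx(0.0, abs=1e-15)
    assert table["com_distance_nm"].std(ddof=0) == pytest.approx(0.0,
                                                                 abs=1e-15)
    assert table["n_contacts"].nunique() == 1


def test_summary_two_frame_means(toy_dimer):
    s, _ = toy_dimer
    coords = np.stack([s.coords, s.coords * 1.1])
    traj = Trajectory(s, coords)
    table = summarize_trajectory(traj, {"rg": True})
    m = s.masses
    rg0 = radius_of_gyration(coords[0], m)
    rg1 = radius_of_gyration(coords[1], m)
    assert table["rg_nm"].mean() == pytest.approx((rg0 + rg1) / 2, rel=1e-12)


def test_summary_disabled_property_absent(toy_dimer):
    s, _ = toy_dimer
    traj = Trajectory(s, np.repeat(s.coords[None], 2, axis=0))
    table = summarize_trajectory(traj, {"rg": False, "com_distance": True})
    assert "rg_nm" not in table.columns
    assert "com_distance_nm" in table.columns
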