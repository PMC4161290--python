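"""Reduced gas-phase energy model with gas-phase-basicity correction.

The ranking of protonation microstates at fixed net charge is governed
by the competition between Coulomb repulsion of the placed charges and
the intrinsic gas-phase basicity (GB) of the sites holding protons.
The model here assigns +/-1e point charges to ionizable-site anchor
atoms and evaluates

    E_corr = E_FF + E_GB,   E_GB = - sum_{occupied sites} GB(site)

where E_FF is a non-bonded reduced force-field energy (vacuum Coulomb,
no cutoff, plus an optional 12-6 Lennard-Jones term) or an externally
supplied value from a structure-relaxation engine.  Attaching a proton
to a site lowers the energy by that site's GB, so higher-GB sites are
favoured at fixed charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .protonation import ProtonationState
from .sites import SiteInventory
from .structure import Structure
from .tables import load_gb_table

#: e^2 / (4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458

#: generic per-element 12-6 parameters (sigma nm, epsilon kJ/mol)
DEFAULT_LJ = {
    "H": (0.242, 0.125), "C": (0.350, 0.276), "N": (0.325, 0.711),
    "O": (0.296, 0.879), "S": (0.355, 1.046), "P": (0.374, 0.837),
}


@dataclass
class EnergyModel:
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT
    lj_params: dict = field(default_factory=lambda: dict(DEFAULT_LJ))
    gb_table: dict = field(default_factory=load_gb_table)
    include_lj: bool = False

    def __post_init__(self):
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if any(v <= 0 for v in self.gb_table.values()):
            raise ValueError("GB values must be positive")


def site_charges(structure: Structure, state: ProtonationState,
                 inventory: SiteInventory,
                 include_background: bool = True) -> np.ndarray:
    """Per-atom charge vector (e) for a protonation state.

    Occupied proton-accepting sites contribute +1e at their anchor
    atom; unoccupied deprotonatable sites contribute -1e.  Background
    partial charges stored on the atoms (zero by default) are added
    when ``include_background``.
    """
    q = np.array([a.partial_charge for a in structure.atoms]) \
        if include_background else np.zeros(structure.n_atoms)
    q = q.astype(float).copy()
    idx = inventory.anchor_indices(structure)
    occ = state.occupancy_array
    base = inventory.base_mask
    q[idx[base & occ]] += 1.0
    q[idx[~base & ~occ]] -= 1.0
    return q


def coulomb_energy(structure: Structure, charges: np.ndarray,
                   model: EnergyModel) -> float:
    """Pairwise vacuum Coulomb energy, no cutoff (kJ/mol)."""
    charges = np.asarray(charges, dtype=float)
    if charges.shape[0] != structure.n_atoms:
        raise ValueError("charges must align with atoms")
    nz = np.flatnonzero(charges)
    if len(nz) < 2:
        return 0.0
    x = structure.coords[nz]
    qq = charges[nz]
    d = pdist(x)
    if np.any(d == 0):
        raise ValueError("coincident charged atoms (r = 0)")
    iu = np.triu_indices(len(nz), 1)
    prod = (qq[:, None] * qq[None, :])[iu]
    return float(model.coulomb_constant / model.dielectric *
                 np.sum(prod / d))


def lj_energy(structure: Structure, model: EnergyModel,
              exclusions=None) -> float:
    """12-6 Lennard-Jones sum with Lorentz-Berthelot combination.

    ``exclusions`` is an iterable of atom-index pairs (bonded 1-2/1-3
    neighbours) removed from the sum.
    """
    elements = structure.elements
    missing = sorted(set(elements) - set(model.lj_params))
    if missing:
        raise KeyError(f"no Lennard-Jones parameters for element(s) {missing}")
    sigma = np.array([model.lj_params[e][0] for e in elements])
    eps = np.array([model.lj_params[e][1] for e in elements])
    n = structure.n_atoms
    if n < 2:
        return 0.0
    d = squareform(pdist(structure.coords))
    iu = np.triu_indices(n, 1)
    sig = 0.5 * (sigma[:, None] + sigma[None, :])
    epsij = np.sqrt(eps[:, None] * eps[None, :])
    mask = np.ones((n, n), dtype=bool)
    for i, j in (exclusions or []):
        mask[i, j] = mask[j, i] = False
    r = d[iu]
    keep = mask[iu] & (r > 0)
    sr6 = (sig[iu][keep] / r[keep]) ** 6
    return float(np.sum(4 * epsij[iu][keep] * (sr6**2 - sr6)))


def gb_correction(state: ProtonationState, inventory: SiteInventory,
                  model: EnergyModel) -> float:
    """GB energy term: -GB summed over proton-holding sites (kJ/mol)."""
    occ = state.occupancy_array
    gb = np.empty(inventory.n_sites)
    for i, s in enumerate(inventory.sites):
        gb[i] = s.gb_intrinsic if s.gb_intrinsic > 0 else _table_gb(model, s.kind)
    return float(-(gb[occ]).sum())


def _table_gb(model: EnergyModel, kind: str) -> float:
    try:
        return model.gb_table[kind]
    except KeyError as exc:
        raise KeyError(f"site kind {kind!r} missing from GB table") from exc


def corrected_energy(structure: Structure, state: ProtonationState,
                     inventory: SiteInventory, model: EnergyModel,
                     e_ff: float | None = None) -> float:
    """GB-corrected total energy E_corr = E_FF + E_GB (kJ/mol).

    E_FF defaults to the reduced-model non-bonded energy (site-charge
    Coulomb, plus Lennard-Jones if the model enables it); an externally
    computed value may be passed instead (relaxer contract).
    """
    if e_ff is None:
        charges = site_charges(structure, state, inventory)
        e_ff = coulomb_energy(structure, charges, model)
        if model.include_lj:
            e_ff += lj_energy(structure, model)
    return float(e_ff) + gb_correction(state, inventory, model)


def energy_rank_r2(delta_a, delta_b) -> float:
    """Squared Pearson correlation between two relative-energy vectors."""
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in input vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def pair_probability(delta_ref, delta_test, ref_window: float,
                     thresholds) -> np.ndarray:
    """Probability that near-degenerate reference pairs stay close in a
    test energy scale.

    For every conformer pair (i, j) with |dref_i - dref_j| < ref_window,
    the curve value at threshold t is the fraction of those pairs with
    |dtest_i - dtest_j| <= t.
    """
    ref = np.asarray(delta_ref, dtype=float)
    test = np.asarray(delta_test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("reference and test vectors must align")
    if ref_window <= 0:
        raise ValueError("ref_window must be positive")
    iu = np.triu_indices(len(ref), 1)
    dref = np.abs(ref[:, None] - ref[None, :])[iu]
    dtest = np.abs(test[:, None] - test[None, :])[iu]
    qualifying = dref < ref_window
    if not np.any(qualifying):
        raise ValueError("no reference pairs inside ref_window")
    thresholds = np.asarray(thresholds, dtype=float)
    return np.array([(dtest[qualifying] <= t).mean() for t in thresholds])
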