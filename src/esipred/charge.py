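"""Apparent gas-phase basicity and main-charge-state prediction.

A protein ion can accept a further proton only while some site's
apparent basicity — its intrinsic GB reduced by the Coulomb work of
adding +1e next to the charges already present — exceeds the GB of the
solvent it was sprayed from.  Fitting GB_app against net charge q and
intersecting the line with the solvent GB therefore predicts the
maximum (main) charge state observed in ESI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import EnergyModel
from .protonation import ProtonationState
from .sites import SiteInventory
from .structure import Structure

#: gas-phase basicity of water, kJ/mol
WATER_GB = 660.3


def gb_app(structure: Structure, state: ProtonationState,
           inventory: SiteInventory, model: EnergyModel) -> float:
    """Apparent gas-phase basicity of an ion in a given microstate.

    Maximum over the unoccupied proton-accepting sites i of
    GB(i) - dE_coul(i), where dE_coul(i) is the Coulomb energy of
    adding +1e at site i against the charges the state already places
    (+1e on protonated bases, -1e on deprotonated acids).
    """
    occ = state.occupancy_array
    base = inventory.base_mask
    candidates = np.flatnonzero(base & ~occ)
    if len(candidates) == 0:
        raise ValueError("no unoccupied proton-accepting site (q = n_base)")
    pos = inventory.anchor_positions(structure)
    site_q = np.zeros(inventory.n_sites)
    site_q[base & occ] = 1.0
    site_q[~base & ~occ] = -1.0
    charged = np.flatnonzero(site_q)

    best = -np.inf
    for i in candidates:
        gb_i = inventory.sites[i].gb_intrinsic
        if gb_i <= 0:
            gb_i = model.gb_table[inventory.sites[i].kind]
        if len(charged):
            r = np.linalg.norm(pos[charged] - pos[i], axis=1)
            if np.any(r == 0):
                raise ValueError("candidate site coincides with a charge")
            de = model.coulomb_constant / model.dielectric * \
                np.sum(site_q[charged] / r)
        else:
            de = 0.0
        best = max(best, gb_i - de)
    return float(best)


@dataclass
class GBAppCurve:
    """Per-charge-state mean and spread of GB_app."""

    qs: np.ndarray
    mean: np.ndarray       # kJ/mol
    std: np.ndarray        # kJ/mol
    n_samples: np.ndarray
    solvent_gb: float = WATER_GB

    def __post_init__(self):
        self.qs = np.asarray(self.qs, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        if np.any(self.n_samples < 1) or np.any(self.std < 0):
            raise ValueError("need >= 1 sample per q and std >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.qs, "gb_app_mean": self.mean,
                             "gb_app_std": self.std, "n": self.n_samples})


def build_curve(samples: dict, inventory: SiteInventory, model: EnergyModel,
                solvent_gb: float = WATER_GB) -> GBAppCurve:
    """GB_app curve from per-charge ensembles.

    ``samples`` maps q -> iterable of (structure, state) snapshots
    (e.g. the lowest-energy state evaluated over relaxed conformers).
    Charges with zero samples are excluded with a warning.
    """
    qs, means, stds, ns = [], [], [], []
    for q in sorted(samples):
        vals = [gb_app(s, st, inventory, model) for s, st in samples[q]]
        if not vals:
            warnings.warn(f"charge q={q} has no samples; excluded")
            continue
        qs.append(q)
        means.append(np.mean(vals))
        stds.append(np.std(vals))
        ns.append(len(vals))
    if len(qs) < 2:
        raise ValueError("need at least 2 charge states with samples")
    return GBAppCurve(np.array(qs), np.array(means), np.array(stds),
                      np.array(ns), solvent_gb)


@dataclass
class ChargePrediction:
    intercept: float     # kJ/mol
    slope: float         # kJ/mol per charge
    crossing: float      # real-valued intersection
    q_star: int          # predicted main charge
    solvent_gb: float

    def to_dict(self) -> dict:
        return {"a": self.intercept, "b": self.slope,
                "crossing": self.crossing, "q_star": self.q_star,
                "solvent_gb": self.solvent_gb}


def predict_main_charge(curve: GBAppCurve, rounding: str = "nearest",
                        weighted: bool = False) -> ChargePrediction:
    """Predict the main charge from the GB_app-vs-q line.

    Fits GB_app = a + b q by least squares (inverse-variance weighted
    if requested and stds are positive) and intersects with the
    solvent GB.  ``rounding``: "nearest" (default; ties round up) or
    "floor" (largest charge not exceeding the crossing).
    """
    if len(curve.qs) < 2:
        raise ValueError("need at least 2 points to fit a line")
    w = None
    if weighted and np.all(curve.std > 0):
        w = 1.0 / curve.std**2
    b, a = np.polyfit(curve.qs, curve.mean, 1, w=w)
    if b >= 0:
        raise ValueError(
            "GB_app does not decrease with charge (slope >= 0); "
            "unphysical curve")
    crossing = (curve.solvent_gb - a) / b
    if rounding == "nearest":
        q_star = int(np.floor(crossing + 0.5))
    elif rounding == "floor":
        q_star = int(np.floor(crossing))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return ChargePrediction(float(a), float(b), float(crossing), q_star,
                            curve.solvent_gb)


def predict_charge_state(structure: Structure, inventory=None, model=None,
                         q_range=range(1, 16), seed: int = 0,
                         n_snapshots: int = 10, jitter: float = 0.02,
                         solvent_gb: float = WATER_GB, max_steps: int = 2000,
                         mc_config=None):
    """End-to-end main-charge prediction for a complex.

    Runs the protonation-state MC at each charge in ``q_range``,
    evaluates GB_app for the lowest-energy state over a small ensemble
    of jittered conformer snapshots, fits the GB_app line and
    intersects it with the solvent GB.

    Returns ``(prediction, curve, sweep)``.
    """
    import numpy as np

    from .energetics import EnergyModel
    from .mc import MCConfig, sweep_charges
    from .sites import identify_sites

    if inventory is None:
        inventory = identify_sites(structure, "gas_phase")
    if model is None:
        model = EnergyModel()
    if mc_config is None:
        mc_config = MCConfig(max_steps=max_steps, patience=10, seed=seed,
                             record_trace=False)
    sweep = sweep_charges(structure, inventory, q_range, model, mc_config)
    rng = np.random.default_rng(seed)
    samples = {}
    for q, res in sweep.results.items():
        if q >= inventory.n_base:  # no free basic site left: GB_app undefined
            continue
        snaps = [(res.best_structure, res.best_state)]
        for _ in range(n_snapshots - 1):
            jit = res.best_structure.coords + rng.normal(
                0, jitter, res.best_structure.coords.shape)
            snaps.append((res.best_structure.with_coords(jit),
                          res.best_state))
        samples[q] = snaps
    curve = build_curve(samples, inventory, model, solvent_gb)
    return predict_main_charge(curve), curve, sweep
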