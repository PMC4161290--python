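"""DSSP-like secondary-structure assignment (reduced {H, E, C} alphabet).

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
energy

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol

(distances in Angstrom) and assigned when E < -0.5 kcal/mol.  Amide
hydrogens absent from the input (the usual case for X-ray structures)
are placed 1.0 A from N along the C(prev)->O(prev) direction reversed,
as in DSSP.  Helices come from consecutive i -> i+4 bonded turns,
strands from parallel/antiparallel bridge patterns.
"""

from __future__ import annotations

import logging

import numpy as np

from .structure import Structure

log = logging.getLogger(__name__)

KS_ENERGY_CUTOFF = -0.5   # kcal/mol
KS_FACTOR = 0.084 * 332   # kcal/mol * Angstrom
NH_BOND_LENGTH = 1.0      # Angstrom


def _backbone(structure: Structure):
    """Per-residue backbone atom coordinates in Angstrom.

    Returns (residue order, dict res -> {N, CA, C, O, H or None, chain}).
    Residues with missing backbone atoms are dropped with a warning.
    """
    per_res: dict[int, dict] = {}
    order = []
    for idx, name, chain, atoms in structure.residues():
        entry = {"chain": chain, "name": name}
        for a in atoms:
            if a.name in ("N", "CA", "C", "O", "H", "HN"):
                key = "H" if a.name == "HN" else a.name
                entry[key] = a.position * 10.0  # nm -> Angstrom
        per_res[idx] = entry
        order.append(idx)
    return order, per_res


def _place_hydrogens(order, per_res):
    for k, idx in enumerate(order):
        entry = per_res[idx]
        if "H" in entry:
            continue
        if k == 0 or per_res[order[k - 1]]["chain"] != entry["chain"]:
            entry["H"] = None  # chain-leading amide: no defined H
            continue
        prev = per_res[order[k - 1]]
        if "C" not in prev or "O" not in prev or "N" not in entry:
            entry["H"] = None
            continue
        co = prev["C"] - prev["O"]
        n = np.linalg.norm(co)
        entry["H"] = entry["N"] + NH_BOND_LENGTH * co / n if n > 0 else None


def kabsch_sander_energy(donor: dict, acceptor: dict) -> float:
    """H-bond energy (kcal/mol) for NH(donor) ... O=C(acceptor)."""
    N, H = donor.get("N"), donor.get("H")
    C, O = acceptor.get("C"), acceptor.get("O")
    if N is None or H is None or C is None or O is None:
        return 0.0
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing atoms: no bond
        return 0.0
    return KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def backbone_hbonds(structure: Structure):
    """Boolean matrix hb[i, j]: NH of residue-rank i donates to C=O of
    residue-rank j (Kabsch-Sander energy below threshold)."""
    order, per_res = _backbone(structure)
    _place_hydrogens(order, per_res)
    n = len(order)
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        di = per_res[order[i]]
        if any(key not in di or di.get(key) is None
               for key in ("N", "H")):
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            aj = per_res[order[j]]
            if "C" not in aj or "O" not in aj:
                continue
            if kabsch_sander_energy(di, aj) < KS_ENERGY_CUTOFF:
                hb[i, j] = True
    return order, hb


def secondary_structure(structure: Structure):
    """Assign per-residue labels in {H, E, C} plus helix/sheet fractions.

    Returns ``(labels, fractions)`` with labels as a dict
    residue_index -> label and fractions as
    ``{"helix": float, "sheet": float}``.
    """
    order, per_res = _backbone(structure)
    missing = [idx for idx in order
               if not all(k in per_res[idx] for k in ("N", "CA", "C", "O"))]
    for idx in missing:
        log.warning("residue %d missing backbone atoms; labelled C", idx)

    order_hb, hb = backbone_hbonds(structure)
    n = len(order_hb)
    labels = {idx: "C" for idx in order}

    # alpha-helix: two consecutive i -> i+4 turns label i+1..i+4
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hb[i + 4, i]:
            turn4[i] = True
    for i in range(n - 5):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, i + 5):
                labels[order_hb[k]] = "H"

    # beta bridges (Kabsch-Sander patterns); hb[a, b]: NH(a) -> CO(b)
    def bonded(a, b):
        return 0 <= a < n and 0 <= b < n and hb[a, b]

    bridge = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 3, n):
            parallel = (bonded(j, i - 1) and bonded(i + 1, j)) or \
                       (bonded(i, j - 1) and bonded(j + 1, i))
            antiparallel = (bonded(i, j) and bonded(j, i)) or \
                           (bonded(j + 1, i - 1) and bonded(i + 1, j - 1))
            if parallel or antiparallel:
                bridge[i] = bridge[j] = True
    for i in range(n):
        if bridge[i] and labels[order_hb[i]] != "H":
            labels[order_hb[i]] = "E"
    for idx in missing:
        labels[idx] = "C"

    values = list(labels.values())
    total = len(values) or 1
    fractions = {"helix": values.count("H") / total,
                 "sheet": values.count("E") / total}
    return labels, fractions
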