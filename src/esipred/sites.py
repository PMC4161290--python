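"""Ionizable-site identification.

Two rules are supported:

* ``gas_phase`` — the residue types allowed to gain or lose a proton in
  vacuo: the N-terminus, C-terminus and R, K, H, Q, D, E side chains
  (glutamine's amide is proton-accepting in the gas phase).
* ``solution`` — the conventional titratable set at aqueous pH: acidic
  E, D and C-terminal groups; basic R, K, H and N-terminal groups
  (Q excluded).

Proton-accepting ("base") sites carry +1e when they hold a proton and
are neutral otherwise; deprotonatable ("acid") sites are neutral when
they hold their proton and carry -1e otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import Structure
from .tables import load_gb_table

log = logging.getLogger(__name__)

BASIC_KINDS = ("N-term", "R", "K", "H", "Q")
ACIDIC_KINDS = ("C-term", "D", "E")

_GAS_RESIDUES = {"ARG": "R", "LYS": "K", "HIS": "H", "GLN": "Q",
                 "ASP": "D", "GLU": "E"}
_SOLUTION_RESIDUES = {"ARG": "R", "LYS": "K", "HIS": "H",
                      "ASP": "D", "GLU": "E"}

#: side-chain anchor atom per kind (charged-group terminal heavy atom)
ANCHOR_ATOMS = {"R": "CZ", "K": "NZ", "H": "NE2", "Q": "NE2",
                "D": "CG", "E": "CD", "N-term": "N", "C-term": "C"}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: human insulin primary sequence (one monomer = chains A + B)
INSULIN_CHAIN_A = "GIVEQCCTSICSLYQLENYCN"
INSULIN_CHAIN_B = "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"


def insulin_dimer_chains() -> list[str]:
    """The four chains of the human insulin dimer (A, B, A, B)."""
    return [INSULIN_CHAIN_A, INSULIN_CHAIN_B, INSULIN_CHAIN_A, INSULIN_CHAIN_B]


@dataclass(frozen=True)
class IonizableSite:
    site_id: int
    residue_index: int
    kind: str
    polarity: str  # "proton_accepting" | "deprotonatable"
    anchor_atom: int | None = None  # atom serial, None for sequence-only sites
    gb_intrinsic: float = 0.0  # kJ/mol

    def __post_init__(self):
        expected = ("proton_accepting" if self.kind in BASIC_KINDS
                    else "deprotonatable")
        if self.polarity != expected:
            raise ValueError(
                f"site kind {self.kind} must have polarity {expected}")


@dataclass
class SiteInventory:
    sites: list[IonizableSite] = field(default_factory=list)

    def __post_init__(self):
        self.sites = sorted(self.sites,
                            key=lambda s: (s.residue_index, s.kind))
        self.sites = [IonizableSite(i, s.residue_index, s.kind, s.polarity,
                                    s.anchor_atom, s.gb_intrinsic)
                      for i, s in enumerate(self.sites)]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_base(self) -> int:
        return sum(1 for s in self.sites if s.polarity == "proton_accepting")

    @property
    def n_acid(self) -> int:
        return sum(1 for s in self.sites if s.polarity == "deprotonatable")

    @property
    def base_mask(self) -> np.ndarray:
        return np.array([s.polarity == "proton_accepting" for s in self.sites])

    @property
    def gb_values(self) -> np.ndarray:
        return np.array([s.gb_intrinsic for s in self.sites])

    def anchor_indices(self, structure: Structure) -> np.ndarray:
        """Atom-list indices of each site's anchor in ``structure``."""
        serial_to_idx = {a.serial: i for i, a in enumerate(structure.atoms)}
        idx = []
        for s in self.sites:
            if s.anchor_atom is None or s.anchor_atom not in serial_to_idx:
                raise ValueError(f"site {s.site_id} has no anchor in structure")
            idx.append(serial_to_idx[s.anchor_atom])
        return np.array(idx, dtype=int)

    def anchor_positions(self, structure: Structure) -> np.ndarray:
        return structure.coords[self.anchor_indices(structure)]


def _anchor_serial(res_atoms, kind):
    """Anchor atom serial for a residue, with CA / first-atom fallback."""
    wanted = ANCHOR_ATOMS[kind]
    for a in res_atoms:
        if a.name == wanted:
            return a.serial
    for a in res_atoms:
        if a.name == "CA":
            return a.serial
    return res_atoms[0].serial


def identify_sites(structure: Structure, rule: str = "gas_phase",
                   gb_table: dict | None = None) -> SiteInventory:
    """Locate ionizable sites in a structure under the given rule.

    One site per qualifying residue plus one per chain terminus;
    unknown residue codes are skipped with a log entry.  Ordering is
    deterministic (by residue index, then kind).
    """
    if rule not in ("gas_phase", "solution"):
        raise ValueError(f"unknown rule {rule!r}")
    res_map = _GAS_RESIDUES if rule == "gas_phase" else _SOLUTION_RESIDUES
    if gb_table is None:
        gb_table = load_gb_table()

    residues = list(structure.residues())
    # chain termini: first and last residue of each chain in file order
    chain_first: dict[str, int] = {}
    chain_last: dict[str, int] = {}
    for idx, name, chain, atoms in residues:
        chain_first.setdefault(chain, idx)
        chain_last[chain] = idx

    sites = []
    for idx, name, chain, atoms in residues:
        if name not in STANDARD_RESIDUES:
            log.warning("residue %s %d not recognised; skipped", name, idx)
            continue
        if idx == chain_first[chain]:
            sites.append(IonizableSite(0, idx, "N-term", "proton_accepting",
                                       _anchor_serial(atoms, "N-term"),
                                       gb_table["N-term"]))
        if idx == chain_last[chain]:
            sites.append(IonizableSite(0, idx, "C-term", "deprotonatable",
                                       _anchor_serial(atoms, "C-term"),
                                       gb_table["C-term"]))
        kind = res_map.get(name)
        if kind is not None:
            polarity = ("proton_accepting" if kind in BASIC_KINDS
                        else "deprotonatable")
            sites.append(IonizableSite(0, idx, kind, polarity,
                                       _anchor_serial(atoms, kind),
                                       gb_table[kind]))
    return SiteInventory(sites)


def inventory_from_sequence(chains: list[str], rule: str = "gas_phase",
                            gb_table: dict | None = None) -> SiteInventory:
    """Build a (coordinate-free) site inventory from one-letter chains.

    Residues are numbered continuously across chains, matching the
    structure-based convention.  Useful for combinatorial counting when
    no coordinates are needed.
    """
    if rule not in ("gas_phase", "solution"):
        raise ValueError(f"unknown rule {rule!r}")
    if gb_table is None:
        gb_table = load_gb_table()
    gas_letters = {"R", "K", "H", "Q", "D", "E"}
    sol_letters = {"R", "K", "H", "D", "E"}
    letters = gas_letters if rule == "gas_phase" else sol_letters

    sites = []
    idx = 0
    for chain in chains:
        first = idx + 1
        last = idx + len(chain)
        for offset, aa in enumerate(chain):
            idx += 1
            if aa not in ONE_TO_THREE:
                log.warning("unknown residue letter %r at %d; skipped", aa, idx)
                continue
            if idx == first:
                sites.append(IonizableSite(0, idx, "N-term",
                                           "proton_accepting", None,
                                           gb_table["N-term"]))
            if idx == last:
                sites.append(IonizableSite(0, idx, "C-term",
                                           "deprotonatable", None,
                                           gb_table["C-term"]))
            if aa in letters:
                polarity = ("proton_accepting" if aa in BASIC_KINDS
                            else "deprotonatable")
                sites.append(IonizableSite(0, idx, aa, polarity, None,
                                           gb_table[aa]))
    return SiteInventory(sites)
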