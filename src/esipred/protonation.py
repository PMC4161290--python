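"""Protonation microstates at fixed net charge.

Occupancy convention (shared by both polarities): a site's bit is 1
when the site *holds a proton* — a protonated (cationic) base or a
neutral acid — and 0 when it does not — a neutral base or an anionic
acid.  The net charge is then

    q = (#occupied proton-accepting sites) - (#unoccupied deprotonatable sites)

which depends on the occupancy vector only through its total count:
with ``k`` occupied sites out of ``n_base + n_acid``,
``q = k - n_acid``.  Counting microstates at fixed q is therefore the
single binomial C(n_base + n_acid, q + n_acid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .sites import SiteInventory


@dataclass(frozen=True)
class ProtonationState:
    """A proton-occupancy vector over a site inventory."""

    occupancy: tuple  # of 0/1 ints, one per site
    inventory: SiteInventory

    def __post_init__(self):
        occ = tuple(int(bool(b)) for b in self.occupancy)
        if len(occ) != self.inventory.n_sites:
            raise ValueError("occupancy length must equal number of sites")
        object.__setattr__(self, "occupancy", occ)

    @property
    def occupancy_array(self) -> np.ndarray:
        return np.array(self.occupancy, dtype=bool)

    def to_tokens(self) -> str:
        """Serialize as one token per site: '+' charged base, '-' charged
        acid, '0' neutral site."""
        out = []
        for occ, site in zip(self.occupancy, self.inventory.sites):
            if site.polarity == "proton_accepting":
                out.append("+" if occ else "0")
            else:
                out.append("0" if occ else "-")
        return "".join(out)

    @classmethod
    def from_tokens(cls, tokens: str, inventory: SiteInventory):
        occ = []
        for tok, site in zip(tokens, inventory.sites):
            if site.polarity == "proton_accepting":
                occ.append(1 if tok == "+" else 0)
            else:
                occ.append(0 if tok == "-" else 1)
        return cls(tuple(occ), inventory)


def net_charge(state: ProtonationState) -> int:
    """Net charge q = occupied bases - unoccupied acids."""
    occ = state.occupancy_array
    base = state.inventory.base_mask
    return int(occ[base].sum() - (~occ[~base]).sum())


def count_states(inventory, q: int) -> int:
    """Exact number of protonation microstates at net charge q.

    ``inventory`` may be a SiteInventory or an (n_base, n_acid) pair.
    Uses exact integer arithmetic; returns 0 for infeasible q.
    """
    if isinstance(inventory, SiteInventory):
        n_base, n_acid = inventory.n_base, inventory.n_acid
    else:
        n_base, n_acid = inventory
    if n_base < 0 or n_acid < 0:
        raise ValueError("site counts must be non-negative")
    k = q + n_acid  # total occupied sites
    if k < 0 or k > n_base + n_acid:
        return 0
    return math.comb(n_base + n_acid, k)


def enumerate_states(inventory: SiteInventory, q: int, cap: int = 10**6):
    """Yield every microstate at net charge q exactly once.

    Raises if the state count exceeds ``cap`` (use the MC sampler for
    such inventories).
    """
    total = count_states(inventory, q)
    if total > cap:
        raise ValueError(
            f"{total} states at q={q} exceeds enumeration cap {cap}; "
            "use the Monte Carlo sampler instead")
    n = inventory.n_sites
    k = q + inventory.n_acid
    if total == 0:
        return
    for occupied in combinations(range(n), k):
        occ = [0] * n
        for i in occupied:
            occ[i] = 1
        yield ProtonationState(tuple(occ), inventory)


def propose_move(state: ProtonationState, rng: np.random.Generator,
                 restart: bool = False):
    """Propose a charge-preserving move.

    The default kernel relocates a single proton from a uniformly
    chosen occupied site to a uniformly chosen unoccupied site, which
    keeps the net charge fixed and is ergodic over the fixed-q state
    space.  With ``restart=True`` a fresh uniform state at the same q
    is drawn instead.

    Returns ``(new_state, moved)``; ``moved`` is False when no legal
    move exists (the state is unique at this charge).
    """
    occ = np.asarray(state.occupancy)
    occupied = np.flatnonzero(occ == 1)
    empty = np.flatnonzero(occ == 0)
    if len(occupied) == 0 or len(empty) == 0:
        return state, False
    if restart:
        new = np.zeros_like(occ)
        chosen = rng.choice(len(occ), size=len(occupied), replace=False)
        new[chosen] = 1
        return ProtonationState(tuple(int(x) for x in new), state.inventory), True
    src = occupied[rng.integers(len(occupied))]
    dst = empty[rng.integers(len(empty))]
    new = occ.copy()
    new[src] = 0
    new[dst] = 1
    return ProtonationState(tuple(int(x) for x in new), state.inventory), True


def random_state(inventory: SiteInventory, q: int,
                 rng: np.random.Generator) -> ProtonationState:
    """A uniformly random microstate at net charge q."""
    if count_states(inventory, q) == 0:
        raise ValueError(f"no microstates at q={q} for this inventory")
    n = inventory.n_sites
    k = q + inventory.n_acid
    occ = np.zeros(n, dtype=int)
    occ[rng.choice(n, size=k, replace=False)] = 1
    return ProtonationState(tuple(int(x) for x in occ), inventory)
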