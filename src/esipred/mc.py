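"""Metropolis Monte Carlo over protonation states.

Each iteration proposes a single-proton relocation at fixed net charge,
hands the trial state to a pluggable structure relaxer (which returns a
possibly updated structure and its force-field energy), evaluates the
GB-corrected energy and applies the Metropolis test.  The run stops
when it fails to accept a new protonation state for ``patience``
consecutive iterations (the convergence rule), or at ``max_steps``.

Reproducibility: one seeded generator drives the whole run; the draw
order per iteration is (proposal source, proposal destination,
relaxer noise if any, acceptance uniform).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import (EnergyModel, corrected_energy, coulomb_energy,
                         lj_energy, site_charges)
from .protonation import (ProtonationState, count_states, propose_move,
                          random_state)
from .sites import SiteInventory
from .structure import Structure

log = logging.getLogger(__name__)

#: molar gas constant, kJ mol^-1 K^-1
GAS_CONSTANT = 8.314462618e-3


@dataclass
class MCConfig:
    temperature: float = 300.0  # K
    max_steps: int = 5000
    patience: int | None = 10   # None disables the convergence stop
    seed: int = 0
    relaxer: str = "rigid"
    relaxer_params: dict = field(default_factory=dict)
    multi_start: bool = True  # restart from fresh random states until max_steps
    record_trace: bool = True
    record_states: bool = False  # keep the per-step accepted-state chain

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class MCResult:
    best_state: ProtonationState
    best_energy: float
    best_structure: Structure
    energy_trace: np.ndarray
    accepted_steps: int
    steps_run: int
    converged: bool
    state_chain: list = None
    trace: pd.DataFrame = None


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion at temperature T (kJ/mol input)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / (GAS_CONSTANT * temperature))


# ---------------------------------------------------------------------
# Relaxer plugins: relax(structure, state, rng) -> (structure', e_ff)

def _reduced_e_ff(structure, state, inventory, model):
    e = coulomb_energy(structure, site_charges(structure, state, inventory),
                       model)
    if model.include_lj:
        e += lj_energy(structure, model)
    return e


def make_relaxer(name: str, model: EnergyModel, inventory: SiteInventory,
                 **params):
    """Build a relaxer callable from its registered name."""
    if name == "rigid":
        def relax(structure, state, rng):
            e = _reduced_e_ff(structure, state, inventory, model)
            if not np.isfinite(e):
                raise ValueError("relaxer produced non-finite energy")
            return structure, e
        return relax
    if name == "jitter-minimize":
        sigma = params.get("sigma", 0.01)       # nm
        n_iter = params.get("n_iter", 20)
        step0 = params.get("step", 1e-4)        # nm^2 mol kJ^-1

        def relax(structure, state, rng):
            coords = structure.coords + rng.normal(0, sigma,
                                                   structure.coords.shape)
            charges = site_charges(structure, state, inventory)
            nz = np.flatnonzero(charges)

            def energy(x):
                s = structure.with_coords(x)
                return _reduced_e_ff(s, state, inventory, model)

            def grad(x):
                g = np.zeros_like(x)
                for a in nz:
                    diff = x[a] - x[nz]
                    r = np.linalg.norm(diff, axis=1)
                    mask = r > 0
                    contrib = (-model.coulomb_constant / model.dielectric *
                               charges[a] * charges[nz][mask] /
                               r[mask] ** 3)[:, None] * diff[mask]
                    g[a] = contrib.sum(axis=0)
                return g

            e = energy(coords)
            step = step0
            for _ in range(n_iter):
                trial = coords - step * grad(coords)
                e_trial = energy(trial)
                if e_trial <= e:
                    coords, e = trial, e_trial
                    step *= 1.2
                else:
                    step *= 0.5
            if not np.isfinite(e):
                raise ValueError("relaxer produced non-finite energy")
            return structure.with_coords(coords), e
        return relax
    raise KeyError(f"unknown relaxer {name!r}")


def run_mc(structure: Structure, inventory: SiteInventory, q: int,
           model: EnergyModel, config: MCConfig,
           initial_state: ProtonationState | None = None,
           relaxer=None) -> MCResult:
    """Explore the fixed-q protonation-state space by Metropolis MC.

    One sampling chain starts from a random microstate and ends when
    ``patience`` consecutive iterations fail to accept a new state.
    With ``multi_start`` (the default) fresh chains are launched from
    new random initial states until the ``max_steps`` budget is spent,
    and the best state over all chains is reported — mirroring the
    random generation of initial protonation states in the underlying
    protocol.  With ``patience=None`` a single chain runs the full
    budget (useful for stationarity checks).
    """
    if count_states(inventory, q) < 1:
        raise ValueError(f"charge q={q} is infeasible for this inventory")
    rng = np.random.default_rng(config.seed)
    if relaxer is None:
        relaxer = make_relaxer(config.relaxer, model, inventory,
                               **config.relaxer_params)

    best_state = best_e = best_structure = None
    trace: list[float] = []
    rows: list[dict] = []
    chain = [] if config.record_states else None
    accepted = 0
    steps = 0
    converged = False
    first = True

    while steps < config.max_steps:
        if first and initial_state is not None:
            current = initial_state
        else:
            current = random_state(inventory, q, rng)
        first = False
        cur_structure, e_ff = relaxer(structure, current, rng)
        if not np.isfinite(e_ff):
            raise ValueError("relaxer returned non-finite energy at start")
        cur_e = corrected_energy(cur_structure, current, inventory, model,
                                 e_ff)
        if best_e is None or cur_e < best_e:
            best_state, best_e, best_structure = current, cur_e, cur_structure
        trace.append(cur_e)
        if chain is not None:
            chain.append(current)
        failures = 0
        converged = False

        while steps < config.max_steps:
            steps += 1
            proposal, moved = propose_move(current, rng)
            if not moved:
                failures += 1
                accepted_flag = False
                delta = 0.0
            else:
                try:
                    new_structure, e_ff = relaxer(cur_structure, proposal, rng)
                except Exception as exc:
                    raise RuntimeError(
                        f"relaxer failed at step {steps}: {exc}") from exc
                new_e = corrected_energy(new_structure, proposal, inventory,
                                         model, e_ff)
                delta = new_e - cur_e
                accepted_flag = metropolis_accept(delta, config.temperature,
                                                  rng)
                if accepted_flag:
                    current, cur_e, cur_structure = (proposal, new_e,
                                                     new_structure)
                    accepted += 1
                    failures = 0
                    # equal-energy ties keep the incumbent best
                    if cur_e < best_e:
                        best_state, best_e, best_structure = (
                            current, cur_e, cur_structure)
                else:
                    failures += 1
            trace.append(cur_e)
            if chain is not None:
                chain.append(current)
            if config.record_trace:
                rows.append({"step": steps,
                             "proposed_state": proposal.to_tokens(),
                             "delta_e": delta, "accepted": accepted_flag,
                             "e_corr": cur_e})
            if config.patience is not None and failures >= config.patience:
                converged = True
                break
        if config.patience is None or not config.multi_start:
            break

    return MCResult(
        best_state=best_state, best_energy=best_e,
        best_structure=best_structure,
        energy_trace=np.asarray(trace), accepted_steps=accepted,
        steps_run=steps, converged=converged, state_chain=chain,
        trace=pd.DataFrame(rows) if config.record_trace else None)


@dataclass
class SweepResult:
    results: dict       # q -> MCResult
    errors: dict        # q -> Exception

    def report(self) -> pd.DataFrame:
        """Lowest-energy state per charge state, one row per q."""
        rows = []
        for q in sorted(self.results):
            r = self.results[q]
            rows.append({"q": q, "state": r.best_state.to_tokens(),
                         "e_corr": r.best_energy,
                         "steps": r.steps_run, "converged": r.converged})
        return pd.DataFrame(rows)


def sweep_charges(structure: Structure, inventory: SiteInventory,
                  q_list, model: EnergyModel, config: MCConfig) -> SweepResult:
    """Independent seeded MC runs for each requested charge state."""
    q_list = list(q_list)
    if not q_list:
        raise ValueError("q_list must be non-empty")
    seen = []
    for q in q_list:
        if q in seen:
            warnings.warn(f"duplicate charge q={q} ignored")
        else:
            seen.append(q)

    results, errors = {}, {}
    for q in seen:
        cfg = MCConfig(temperature=config.temperature,
                       max_steps=config.max_steps, patience=config.patience,
                       seed=config.seed + q, relaxer=config.relaxer,
                       relaxer_params=config.relaxer_params,
                       multi_start=config.multi_start,
                       record_trace=config.record_trace,
                       record_states=config.record_states)
        try:
            results[q] = run_mc(structure, inventory, q, model, cfg)
        except Exception as exc:
            log.warning("charge q=%d failed: %s", q, exc)
            errors[q] = exc
    return SweepResult(results, errors)
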