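"""Reduced energy model: Coulomb, Lennard-Jones, GB correction, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esipred import (EnergyModel, corrected_energy,
                     coulomb_energy, energy_rank_r2, enumerate_states,
                     gb_correction, lj_energy, pair_probability,
                     site_charges)
from esipred.protonation import ProtonationState
from esipred.sites import IonizableSite, SiteInventory

from conftest import simple_structure


def two_site_inventory(gb1=880.0, gb2=900.0):
    return SiteInventory([
        IonizableSite(0, 1, "K", "proton_accepting", 1, gb1),
        IonizableSite(0, 2, "K", "proton_accepting", 2, gb2)])


# ---------------------------------------------------------------------
# Coulomb

def test_coulomb_two_unit_charges_at_1nm(model):
    s = simple_structure([[0, 0, 0], [1.0, 0, 0]])
    e = coulomb_energy(s, np.array([1.0, 1.0]), model)
    assert e == pytest.approx(138.935, abs=1e-3)


def test_coulomb_zero_charge_pair(model):
    s = simple_structure([[0, 0, 0], [1.0, 0, 0]])
    assert coulomb_energy(s, np.array([1.0, 0.0]), model) == 0.0


def test_coulomb_opposite_charges_at_half_nm(model):
    s = simple_structure([[0, 0, 0], [0.5, 0, 0]])
    e = coulomb_energy(s, np.array([1.0, -1.0]), model)
    assert e == pytest.approx(-277.871, abs=1e-3)


def test_coulomb_coincident_charges_error(model):
    s = simple_structure([[0, 0, 0], [0, 0, 0]])
    with pytest.raises(ValueError):
        coulomb_energy(s, np.array([1.0, 1.0]), model)


@given(st.floats(0.1, 10.0), st.floats(-2, 2), st.floats(-2, 2))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_coulomb_scales_with_dielectric_and_charges(eps, q1, q2):
    s = simple_structure([[0, 0, 0], [0.7, 0, 0]])
    base = coulomb_energy(s, np.array([1.0, 1.0]), EnergyModel())
    scaled = coulomb_energy(s, np.array([q1, q2]),
                            EnergyModel(dielectric=eps))
    assert scaled == pytest.approx(base * q1 * q2 / eps, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------
# Lennard-Jones

def test_lj_zero_at_sigma(model):
    sigma = model.lj_params["C"][0]
    s = simple_structure([[0, 0, 0], [sigma, 0, 0]])
    assert lj_energy(s, model) == pytest.approx(0.0, abs=1e-12)


def test_lj_minimum_at_rmin(model):
    sigma, eps = model.lj_params["C"]
    s = simple_structure([[0, 0, 0], [2 ** (1 / 6) * sigma, 0, 0]])
    assert lj_energy(s, model) == pytest.approx(-eps, rel=1e-9)


def test_lj_three_atoms_matches_pair_sum(model):
    pts = np.array([[0, 0, 0], [0.4, 0, 0], [0.1, 0.45, 0]])
    s = simple_structure(pts)
    sigma, eps = model.lj_params["C"]

    def pair(r):
        sr6 = (sigma / r) ** 6
        return 4 * eps * (sr6 ** 2 - sr6)

    oracle = sum(pair(np.linalg.norm(pts[i] - pts[j]))
                 for i in range(3) for j in range(i + 1, 3))
    assert lj_energy(s, model) == pytest.approx(oracle, rel=1e-12)


def test_lj_missing_element_errors(model):
    s = simple_structure([[0, 0, 0], [1, 0, 0]], elements=["C", "XX"])
    with pytest.raises(KeyError, match="XX"):
        lj_energy(s, model)


def test_lj_exclusions_remove_bonded_pairs(model):
    s = simple_structure([[0, 0, 0], [0.2, 0, 0]])
    assert lj_energy(s, model, exclusions=[(0, 1)]) == 0.0


# ---------------------------------------------------------------------
# GB correction and E_corr

def test_gb_correction_empty_state(model):
    inv = two_site_inventory()
    state = ProtonationState((0, 0), inv)
    assert gb_correction(state, inv, model) == 0.0


def test_gb_correction_sums_occupied_sites(model):
    inv = two_site_inventory(880.0, 900.0)
    state = ProtonationState((1, 1), inv)
    assert gb_correction(state, inv, model) == pytest.approx(-1780.0)


def test_gb_correction_difference_between_states(model):
    inv = two_site_inventory(880.0, 900.0)
    low = ProtonationState((1, 0), inv)   # proton on GB 880
    high = ProtonationState((0, 1), inv)  # proton on GB 900
    d = gb_correction(low, inv, model) - gb_correction(high, inv, model)
    assert d == pytest.approx(20.0)


def test_corrected_energy_ranking_matches_enumeration_oracle(model):
    # 2 sites 0.8 nm apart: at q=1 the higher-GB site must win
    s = simple_structure([[0, 0, 0], [0.8, 0, 0]], elements=["N", "N"])
    inv = two_site_inventory(880.0, 900.0)
    energies = {st.occupancy: corrected_energy(s, st, inv, model)
                for st in enumerate_states(inv, 1)}
    assert energies[(0, 1)] < energies[(1, 0)]
    assert energies[(0, 1)] == pytest.approx(-900.0)


def test_corrected_energy_accepts_external_eff(model):
    s = simple_structure([[0, 0, 0], [0.8, 0, 0]], elements=["N", "N"])
    inv = two_site_inventory()
    state = ProtonationState((1, 0), inv)
    e = corrected_energy(s, state, inv, model, e_ff=123.0)
    assert e == pytest.approx(123.0 - 880.0)


def test_global_gb_shift_preserves_ranking_at_fixed_q(model):
    s = simple_structure([[0, 0, 0], [0.8, 0, 0], [0.3, 0.6, 0]],
                         elements=["N", "N", "N"])
    inv = SiteInventory([
        IonizableSite(0, i + 1, "K", "proton_accepting", i + 1, gb)
        for i, gb in enumerate([880.0, 900.0, 930.0])])
    shifted = SiteInventory([
        IonizableSite(0, i + 1, "K", "proton_accepting", i + 1, gb + 50.0)
        for i, gb in enumerate([880.0, 900.0, 930.0])])
    e1 = [corrected_energy(s, st, inv, model)
          for st in enumerate_states(inv, 1)]
    e2 = [corrected_energy(s, st, shifted, model)
          for st in enumerate_states(shifted, 1)]
    assert np.argsort(e1).tolist() == np.argsort(e2).tolist()


def test_corrected_energy_rotation_invariant(model):
    s = simple_structure([[0, 0, 0], [0.8, 0, 0], [0.3, 0.6, 0]],
                         elements=["N", "N", "N"])
    inv = SiteInventory([
        IonizableSite(0, i + 1, "K", "proton_accepting", i + 1, 900.0)
        for i in range(3)])
    state = ProtonationState((1, 1, 0), inv)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    s2 = s.transformed(rotation=R, translation=np.array([1.0, -2.0, 3.0]))
    assert corrected_energy(s2, state, inv, model) == pytest.approx(
        corrected_energy(s, state, inv, model), rel=1e-10)


def test_site_charges_sign_convention(model, toy_dimer):
    from esipred import identify_sites
    s, _ = toy_dimer
    inv = identify_sites(s, "gas_phase")
    all_on = ProtonationState((1,) * inv.n_sites, inv)
    q = site_charges(s, all_on, inv)
    # every base protonated (+1 each), every acid neutral
    assert q.sum() == pytest.approx(inv.n_base)
    all_off = ProtonationState((0,) * inv.n_sites, inv)
    q = site_charges(s, all_off, inv)
    assert q.sum() == pytest.approx(-inv.n_acid)


# ---------------------------------------------------------------------
# energy-comparison statistics

def test_r2_identical_and_anticorrelated_vectors():
    v = np.array([1.0, 3.0, -2.0, 5.0])
    assert energy_rank_r2(v, v) == pytest.approx(1.0)
    assert energy_rank_r2(v, -v) == pytest.approx(1.0)


def test_r2_independent_samples_low():
    rng = np.random.default_rng(60)
    a, b = rng.standard_normal(60), rng.standard_normal(60)
    assert energy_rank_r2(a, b) < 0.15


def test_r2_zero_variance_errors():
    with pytest.raises(ValueError):
        energy_rank_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pair_probability_perfect_agreement():
    v = np.array([0.0, 2.0, 5.0, 9.0, 11.0])
    curve = pair_probability(v, v, ref_window=10.0, thresholds=[10.0])
    assert curve[0] == pytest.approx(1.0)


def test_pair_probability_all_pairs_outside():
    ref = np.array([0.0, 1.0, 2.0])
    test = np.array([0.0, 100.0, 200.0])
    curve = pair_probability(ref, test, ref_window=5.0,
                             thresholds=[1.0, 10.0])
    assert np.all(curve == 0.0)


def test_pair_probability_matches_bruteforce_oracle():
    ref = np.array([0.0, 3.0, 8.0, 14.0, 21.0])
    test = np.array([0.0, 6.0, 5.0, 30.0, 18.0])
    window, thresholds = 10.0, [2.0, 6.0, 12.0, 40.0]
    # independent brute force over all C(5,2) pairs
    pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    qual = [(i, j) for i, j in pairs if abs(ref[i] - ref[j]) < window]
    expected = [sum(abs(test[i] - test[j]) <= t for i, j in qual) / len(qual)
                for t in thresholds]
    got = pair_probability(ref, test, window, thresholds)
    assert got == pytest.approx(expected)


def test_pair_probability_no_qualifying_pairs_errors():
    with pytest.raises(ValueError):
        pair_probability([0.0, 100.0], [0.0, 1.0], 10.0, [5.0])
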