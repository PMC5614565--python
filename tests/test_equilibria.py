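"""Solver correctness: closed forms, oracle agreement, conservation, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fixed_point_single_site, oracle_fraction_unbound, oracle_solve
from wrcbind import (
    EquilibriumState,
    MechanismSpec,
    MixtureSpec,
    bound_stoichiometry,
    fraction_unbound,
    predict_fraction_unbound,
    solve,
    solve_cyclic_two_site,
    solve_gst_dimer,
    solve_sequential_two_site,
    solve_single_site,
)
from wrcbind.equilibria import KINDS
from wrcbind.errors import ParameterDomainError, UndefinedObservableError

BIG = 1e12  # numerical stand-in for an infinite dissociation constant


# ---------------------------------------------------------------------------
# mechanism / mixture validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad_kd", [0.0, -1.0, float("inf"), float("nan")])
def test_nonpositive_or_nonfinite_constants_rejected(bad_kd):
    with pytest.raises(ParameterDomainError):
        MechanismSpec.single_site(bad_kd)
    with pytest.raises(ParameterDomainError):
        solve_single_site(MixtureSpec(0.1, 1.0), bad_kd)


def test_mechanism_requires_exactly_its_parameters():
    with pytest.raises(ParameterDomainError):
        MechanismSpec("single_site", {"K_D_D": 1.0, "K_D_A": 2.0})
    with pytest.raises(ParameterDomainError):
        MechanismSpec("sequential_two_site", {"K_D_D": 1.0})
    with pytest.raises(ParameterDomainError):
        MechanismSpec("no_such_model", {"K_D_D": 1.0})


def test_negative_totals_rejected():
    with pytest.raises(ParameterDomainError):
        MixtureSpec(-0.1, 1.0)


# ---------------------------------------------------------------------------
# single site
# ---------------------------------------------------------------------------

def test_single_site_no_ligand():
    state = solve_single_site(MixtureSpec(0.1, 0.0), kd=0.265)
    assert state.free_receptor == pytest.approx(0.1, abs=0)
    assert state.species["WR"] == 0.0


def test_single_site_half_saturation_without_depletion():
    # trace receptor: free ligand ~ total, so occupancy at [R] = K_D is 1/2
    state = solve_single_site(MixtureSpec(1e-6, 0.265), kd=0.265)
    bound_fraction = state.species["WR"] / state.receptor_total
    assert bound_fraction == pytest.approx(0.5, abs=1e-5)


def test_single_site_matches_damped_fixed_point():
    state = solve_single_site(MixtureSpec(0.1, 0.5), kd=0.265)
    wr = fixed_point_single_site(0.1, 0.5, 0.265)
    assert state.species["WR"] == pytest.approx(wr, abs=1e-9)


# ---------------------------------------------------------------------------
# sequential two-site
# ---------------------------------------------------------------------------

def test_sequential_reduces_to_single_site_when_second_site_is_dead():
    mix = MixtureSpec(0.1, 1.0)
    seq = solve_sequential_two_site(mix, kd_d=0.169, kd_ad=BIG)
    single = solve_single_site(mix, kd=0.169)
    assert fraction_unbound(seq) == pytest.approx(fraction_unbound(single), rel=1e-6)


def test_sequential_matches_nested_bisection_oracle():
    state = solve_sequential_two_site(MixtureSpec(0.1, 1.0), kd_d=0.169, kd_ad=0.262)
    expected = oracle_fraction_unbound(
        "sequential_two_site", {"K_D_D": 0.169, "K_D_A_D": 0.262}, 0.1, 1.0
    )
    assert fraction_unbound(state) == pytest.approx(expected, abs=1e-8)


def test_sequential_no_receptor():
    state = solve_sequential_two_site(MixtureSpec(0.0, 5.0), kd_d=0.1, kd_ad=0.2)
    assert state.free_ligand == pytest.approx(5.0)
    assert all(v == pytest.approx(0.0, abs=1e-15) for v in state.species.values())


# ---------------------------------------------------------------------------
# cyclic two-site
# ---------------------------------------------------------------------------

def test_cyclic_alpha_one_factorizes_site_occupancies():
    state = solve_cyclic_two_site(MixtureSpec(0.1, 10.0), kd_d=0.265, kd_a=11.52, alpha=1.0)
    r = state.free_ligand
    p_d = r / (r + 0.265)
    p_a = r / (r + 11.52)
    both = state.species["WR_DA"] / state.receptor_total
    assert both == pytest.approx(p_d * p_a, abs=1e-10)


def test_cyclic_matches_nested_bisection_oracle():
    params = {"K_D_D": 0.265, "K_D_A": 11.52, "alpha": 1.0}
    state = solve_cyclic_two_site(MixtureSpec(0.1, 10.0), 0.265, 11.52, 1.0)
    w, r, species = oracle_solve("cyclic_two_site", params, 0.1, 10.0)
    assert state.free_receptor == pytest.approx(w, abs=1e-8)
    for name in ("WR_D", "WR_A", "WR_DA"):
        assert state.species[name] == pytest.approx(species[name], abs=1e-8)


def test_cyclic_reduces_to_single_site_when_a_site_is_dead():
    mix = MixtureSpec(0.1, 1.0)
    cyc = solve_cyclic_two_site(mix, kd_d=0.265, kd_a=BIG, alpha=1.0)
    single = solve_single_site(mix, kd=0.265)
    assert fraction_unbound(cyc) == pytest.approx(fraction_unbound(single), rel=1e-6)


# ---------------------------------------------------------------------------
# GST-dimer
# ---------------------------------------------------------------------------

def test_gst_dimer_reduces_to_single_site_binding_of_the_dimer():
    # with the second WRC site dead, G2 + W <-> G2W with K_D_A; the dimer
    # total (half the monomer total) plays the ligand role
    w_tot, r_tot = 0.1, 3.0
    gst = solve_gst_dimer(MixtureSpec(w_tot, r_tot), kd_a=11.52, kd_aprime=BIG)
    single = solve_single_site(MixtureSpec(w_tot, r_tot / 2.0), kd=11.52)
    assert fraction_unbound(gst) == pytest.approx(fraction_unbound(single), rel=1e-6)


def test_gst_dimer_matches_nested_bisection_oracle():
    state = solve_gst_dimer(MixtureSpec(0.1, 20.0), kd_a=11.52, kd_aprime=0.033)
    expected = oracle_fraction_unbound(
        "gst_dimer", {"K_D_A": 11.52, "K_D_Aprime": 0.033}, 0.1, 20.0
    )
    assert fraction_unbound(state) == pytest.approx(expected, abs=1e-8)


def test_gst_dimer_no_ligand():
    state = solve_gst_dimer(MixtureSpec(0.1, 0.0), kd_a=11.52, kd_aprime=0.033)
    assert state.free_receptor == pytest.approx(0.1, abs=0)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def test_fraction_unbound_limits():
    no_ligand = solve_single_site(MixtureSpec(0.1, 0.0), kd=0.265)
    assert fraction_unbound(no_ligand) == 1.0
    saturated = solve_single_site(MixtureSpec(0.1, 1e4 * 0.265), kd=0.265)
    assert fraction_unbound(saturated) < 1e-2
    mid = solve_single_site(MixtureSpec(0.1, 0.5), kd=0.265)
    assert fraction_unbound(mid) == pytest.approx(
        oracle_fraction_unbound("single_site", {"K_D_D": 0.265}, 0.1, 0.5), abs=1e-8
    )


def test_fraction_unbound_requires_receptor():
    state = solve_sequential_two_site(MixtureSpec(0.0, 5.0), 0.1, 0.2)
    with pytest.raises(UndefinedObservableError):
        fraction_unbound(state)


def test_bound_stoichiometry_fully_double_bound():
    state = EquilibriumState(
        mechanism_kind="cyclic_two_site",
        receptor_total=0.1,
        ligand_total=1.0,
        free_receptor=0.0,
        free_ligand=0.8,
        species={"WR_D": 0.0, "WR_A": 0.0, "WR_DA": 0.1},
    )
    assert bound_stoichiometry(state) == pytest.approx(2.0)


def test_bound_stoichiometry_hand_algebra_at_equal_kds():
    # alpha = 1 and free r = K_D_D = K_D_A: each site half occupied, so the
    # mean Rac per total WRC is p_D + p_A = 1 exactly.  Choosing
    # R_tot = kd + W_tot makes the solved free ligand land on kd.
    kd, w_tot = 0.5, 0.2
    state = solve_cyclic_two_site(MixtureSpec(w_tot, kd + w_tot), kd, kd, 1.0)
    assert state.free_ligand == pytest.approx(kd, rel=1e-12)
    assert bound_stoichiometry(state) == pytest.approx(1.0, abs=1e-10)


def test_bound_stoichiometry_no_ligand_is_zero():
    state = solve_cyclic_two_site(MixtureSpec(0.1, 0.0), 0.265, 11.52, 1.0)
    assert bound_stoichiometry(state) == 0.0


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def _mechanism(kind, k1, k2, alpha):
    if kind == "single_site":
        return MechanismSpec.single_site(k1)
    if kind == "sequential_two_site":
        return MechanismSpec.sequential_two_site(k1, k2)
    if kind == "cyclic_two_site":
        return MechanismSpec.cyclic_two_site(k1, k2, alpha)
    return MechanismSpec.gst_dimer(k1, k2)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    kind=st.sampled_from(KINDS),
    wexp=st.floats(-4, 3),
    rexp=st.floats(-4, 3),
    k1exp=st.floats(-3, 3),
    k2exp=st.floats(-3, 3),
    aexp=st.floats(-2, 2),
)
def test_conservation_holds_across_parameter_sweep(kind, wexp, rexp, k1exp, k2exp, aexp):
    mech = _mechanism(kind, 10.0**k1exp, 10.0**k2exp, 10.0**aexp)
    state = solve(mech, MixtureSpec(10.0**wexp, 10.0**rexp))
    res_w, res_r = state.conservation_residuals()
    assert res_w <= 1e-9
    assert res_r <= 1e-9
    assert state.free_receptor >= 0 and state.free_ligand >= 0
    assert all(v >= 0 for v in state.species.values())


@pytest.mark.parametrize(
    "kind,params",
    [
        ("single_site", {"K_D_D": 0.265}),
        ("sequential_two_site", {"K_D_D": 0.169, "K_D_A_D": 0.262}),
        ("cyclic_two_site", {"K_D_D": 0.265, "K_D_A": 11.52, "alpha": 1.0}),
        ("gst_dimer", {"K_D_A": 11.52, "K_D_Aprime": 0.033}),
    ],
)
def test_fraction_unbound_monotone_in_ligand_total(kind, params):
    mech = MechanismSpec(kind, params)
    ligand = np.geomspace(1e-3, 1e3, 50)
    frac = [fraction_unbound(solve(mech, MixtureSpec(0.1, r))) for r in ligand]
    assert np.all(np.diff(frac) <= 1e-12)


@pytest.mark.parametrize(
    "kind,params",
    [
        ("single_site", {"K_D_D": 0.265}),
        ("sequential_two_site", {"K_D_D": 0.169, "K_D_A_D": 0.262}),
        ("cyclic_two_site", {"K_D_D": 0.265, "K_D_A": 11.52, "alpha": 2.0}),
        ("gst_dimer", {"K_D_A": 11.52, "K_D_Aprime": 0.033}),
    ],
)
def test_vectorized_prediction_matches_scalar_solvers(kind, params):
    mech = MechanismSpec(kind, params)
    ligand = np.geomspace(0.01, 140.0, 12)
    vec = predict_fraction_unbound(mech, ligand, 0.1)
    scalar = [fraction_unbound(solve(mech, MixtureSpec(0.1, r))) for r in ligand]
    np.testing.assert_allclose(vec, scalar, atol=1e-10)


def test_state_json_round_trip():
    state = solve_cyclic_two_site(MixtureSpec(0.1, 1.0), 0.265, 11.52, 1.5)
    back = EquilibriumState.from_json(state.to_json())
    assert back == state
    assert set(back.species) == {"WR_D", "WR_A", "WR_DA"}
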