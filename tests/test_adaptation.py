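"""Adaptation kinetics: steady states, collapse function, fixed points."""

import numpy as np
import pytest
from scipy.optimize import brentq

import chemomwc as cm
from chemomwc.adaptation import methylation_at_activity, steady_state


ALL_MODELS = ["power-h3", "power-h2", "power-h1", "mm-feedback",
              "mm-nofeedback", "cheb-mutant"]


def test_registry_names_and_unknown_model():
    assert set(ALL_MODELS) == set(cm.MODEL_NAMES)
    with pytest.raises(KeyError, match="power-h3"):
        cm.get_model("no-such-model")


@pytest.mark.parametrize("name", ALL_MODELS)
@pytest.mark.parametrize("a", [0.2, 1.0 / 3.0, 0.5, 0.7])
def test_solve_gB_balances_kinetics_exactly(name, a):
    spec = cm.get_model(name, g_R=0.0069, a=a)
    assert abs(cm.dm_dt(a, 2.0, spec)) < 1e-12


@pytest.mark.parametrize("name, a", [("power-h3", 1.0 / 3.0),
                                     ("power-h2", 0.5),
                                     ("cheb-mutant", 0.5)])
def test_solve_gB_closed_form_matches_root_finding(name, a):
    spec = cm.get_model(name, g_R=0.0069)
    gB_closed = cm.solve_gB(spec.g_R, a, spec)
    import dataclasses

    def balance(gB):
        return cm.dm_dt(a, 1.0, dataclasses.replace(spec, g_B=gB))

    gB_root = brentq(balance, 1e-8, 10.0, xtol=1e-14)
    assert abs(gB_closed - gB_root) < 1e-12


def test_solve_gB_reference_ratios():
    # h=1 at a=1/2: symmetric balance; h=3 at a=1/3: (1-a)/a^3 = 18
    spec1 = cm.get_model("power-h1", g_R=0.01)
    assert cm.solve_gB(0.01, 0.5, spec1) == pytest.approx(0.01, rel=1e-14)
    spec3 = cm.get_model("power-h3", g_R=0.01)
    assert cm.solve_gB(0.01, 1.0 / 3.0, spec3) == pytest.approx(0.18, rel=1e-12)


def test_dm_dt_limits_and_validation():
    spec = cm.get_model("power-h3", a=1.0 / 3.0)
    assert cm.dm_dt(0.0, 1.0, spec) == pytest.approx(spec.g_R)
    assert cm.dm_dt(1.0, 1.0, spec) == pytest.approx(-spec.g_B)
    with pytest.raises(ValueError):
        cm.dm_dt(1.2, 1.0, spec)
    with pytest.raises(ValueError):
        cm.dm_dt(0.5, -1.0, spec)


def test_imprecise_site_factors_never_make_rates_negative(params):
    spec = cm.get_model("power-h3", a=1.0 / 3.0, imprecise=True)
    # methylation-only direction at A=0 stays non-negative even above M_max
    for m in (0.0, 1.0, spec.M_max, spec.M_max + 1.0):
        assert cm.dm_dt(0.0, m, spec) >= 0.0
        assert cm.dm_dt(1.0, m, spec) <= 0.0


def test_adapted_methylation_closed_form_and_round_trip(params):
    # at a = 1/2 and L = 0 the free energy vanishes: m = -intercept/slope
    m_half = cm.adapted_methylation(0.0, 0.5, params)
    assert m_half == pytest.approx(-params.fm_intercept / params.fm_slope,
                                   rel=1e-12)
    for L, a in [(0.0, 1 / 3), (0.1, 1 / 3), (0.5, 0.5), (2.0, 0.4)]:
        m = cm.adapted_methylation(L, a, params)
        N = cm.complex_size(L, params)
        A = cm.activity(cm.free_energy(cm.ComplexState(m=m, L=L, N=N), params))
        assert A == pytest.approx(a, abs=1e-10)


def test_adapted_methylation_monotone_in_ambient_vs_bisection(params):
    Ls = np.linspace(0.0, 2.0, 25)
    ms = [cm.adapted_methylation(L, 1 / 3, params) for L in Ls]
    assert np.all(np.diff(ms) > 0)
    # independent bisection oracle on a few ambients
    for L in (0.05, 0.4, 1.5):
        N = cm.complex_size(L, params)

        def f(m):
            return cm.activity(
                cm.free_energy(cm.ComplexState(m=m, L=L, N=N), params)) - 1 / 3

        m_bis = brentq(f, 0.0, 10.0, xtol=1e-12)
        assert cm.adapted_methylation(L, 1 / 3, params) == pytest.approx(
            m_bis, abs=1e-9)


def test_collapse_function_zeros_and_sign_pattern(params, wt1_spec, a_wt1):
    g = lambda A: cm.collapse_function(A, wt1_spec, params, 0.1)
    assert g(0.0) == 0.0
    assert g(1.0) == 0.0
    assert abs(g(a_wt1)) < 1e-12
    A = np.linspace(1e-3, 1 - 1e-3, 999)
    vals = np.asarray(g(A))
    assert np.all(vals[A < a_wt1 - 1e-3] > 0)
    assert np.all(vals[A > a_wt1 + 1e-3] < 0)


@pytest.mark.parametrize("name, a", [("power-h3", 1 / 3), ("power-h2", 1 / 3),
                                     ("power-h1", 0.5), ("cheb-mutant", 0.5),
                                     ("mm-feedback", 1 / 3),
                                     ("mm-nofeedback", 1 / 3)])
def test_interior_fixed_point_unique_and_attracting(params, name, a):
    spec = cm.get_model(name, a=a)
    g = lambda A: cm.collapse_function(A, spec, params, 0.1)
    A = np.linspace(1e-4, 1 - 1e-4, 5000)
    signs = np.sign(np.asarray(g(A)))
    crossings = np.sum(np.abs(np.diff(signs)) > 0)
    assert crossings == 1  # only the adapted activity
    h = 1e-6
    assert (g(a + h) - g(a - h)) / (2 * h) < 0  # stable


@pytest.mark.parametrize("name, a, expected",
                         [("power-h3", 1 / 3, (0.0, 1 / 3, 1.0)),
                          ("power-h1", 0.5, (0.0, 0.5, 1.0))])
def test_fixed_points_structure(params, name, a, expected):
    spec = cm.get_model(name, a=a)
    roots = cm.fixed_points(spec, params, 0.1)
    assert len(roots) == 3
    for r, e in zip(roots, expected):
        assert r == pytest.approx(e, abs=1e-8)


def test_fixed_points_refuses_imprecise_model(params):
    spec = cm.get_model("power-h3", a=1 / 3, imprecise=True)
    with pytest.raises(ValueError, match="precise"):
        cm.fixed_points(spec, params, 0.1)


def test_demethylation_side_steeper_than_methylation_side(params, wt1_spec,
                                                          a_wt1):
    # the headline asymmetry: fast adaptation of active receptors
    g = lambda A: cm.collapse_function(A, wt1_spec, params, 0.1)
    assert abs(g((1 + a_wt1) / 2)) > abs(g(a_wt1 / 2))


def test_michaelis_without_feedback_is_flat_near_steady_state(params, a_wt1):
    mm = cm.get_model("mm-nofeedback", a=a_wt1)
    h3 = cm.get_model("power-h3", a=a_wt1)
    for dA in (-0.05, -0.02, 0.02, 0.05):
        A = a_wt1 + dA
        assert (abs(cm.collapse_function(A, mm, params, 0.1))
                < abs(cm.collapse_function(A, h3, params, 0.1)))


def test_imprecise_steady_state_shifts_with_ambient(params):
    spec = cm.get_model("power-h3", a=1 / 3, imprecise=True)
    ss_ambient = steady_state(spec, params, 0.1, a_hint=1 / 3)
    ss_high = steady_state(spec, params, 2.1, a_hint=1 / 3)
    # at high concentration the methylation sites run out: adapted
    # activity falls below the ambient-adapted value
    assert ss_high.a < ss_ambient.a
    assert ss_high.m_adapted <= spec.M_max + 1e-9
    # inversion helper is consistent with the steady state found
    m_back = methylation_at_activity(ss_ambient.a, 0.1, params,
                                     cm.complex_size(0.1, params))
    assert m_back == pytest.approx(ss_ambient.m_adapted, abs=1e-6)


def test_cheb_mutant_demethylation_weaker_than_cooperative_model(params):
    # without CheB-P feedback the activity-dependence of demethylation is
    # diminished: |g(A)| above the shared set point sits below the
    # cooperative-feedback curve at matched adapted activity and g_R
    mut = cm.get_model("cheb-mutant", a=0.5)
    wt2 = cm.get_model("power-h3", a=0.5)
    for A in np.linspace(0.55, 0.95, 9):
        assert (abs(cm.collapse_function(A, mut, params, 0.0))
                < abs(cm.collapse_function(A, wt2, params, 0.0)))
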