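"""Collapse extraction, effective methylation rate, fitting, permutation test."""

import numpy as np
import pandas as pd
import pytest

import chemomwc as cm
from chemomwc.collapse import (
    _default_bins,
    extract_collapse,
    effective_dm_dt,
    fit_gR,
    model_curve,
    permutation_test,
    rate_of_change,
    smooth,
)
from chemomwc.synth import campaign_collapse


def test_smooth_block_means():
    t = np.arange(100, dtype=float)
    x = np.full(100, 3.7)
    tb, xb = smooth(t, x, window=20)
    assert len(tb) == 5
    assert np.allclose(xb, 3.7)
    # window 1 is the identity
    tb, xb = smooth(t, x, window=1)
    assert np.array_equal(tb, t) and np.array_equal(xb, x)
    # linear ramp: block means equal the block-midpoint values
    x = 2.0 * t + 1.0
    tb, xb = smooth(t, x, window=20)
    assert np.allclose(xb, 2.0 * tb + 1.0)
    # short tail dropped, not partially averaged
    tb, _ = smooth(t[:55], x[:55], window=20)
    assert len(tb) == 2


def test_rate_of_change_closed_forms():
    t = np.linspace(0, 10, 51)
    A_pair, d = rate_of_change(t, np.full(51, 0.4))
    assert np.allclose(d, 0.0)
    A_pair, d = rate_of_change(t, 0.03 * t)
    assert np.allclose(d, 0.03)
    with pytest.raises(ValueError, match="increasing"):
        rate_of_change(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    # pairing conventions
    x = np.array([0.0, 1.0, 4.0])
    left, _ = rate_of_change(np.arange(3.0), x, pairing="left")
    mid, _ = rate_of_change(np.arange(3.0), x, pairing="mid")
    assert np.allclose(left, [0.0, 1.0])
    assert np.allclose(mid, [0.5, 2.5])


def test_noiseless_perfect_steps_lie_on_the_collapse_curve(
        params, wt1_spec, a_wt1, perfect_step_courses):
    g = model_curve("power-h3", a_wt1, wt1_spec.g_R,
                    cm.complex_size(0.1, params), params)
    scale = np.max(np.abs(g(np.linspace(0, 1, 1001))))
    for delta, tc in perfect_step_courses.items():
        cs = extract_collapse(tc, onset_delay=10.0, window=20)
        A = cs.points["A"].to_numpy()
        dev = np.abs(cs.points["dAdt"].to_numpy() - g(np.clip(A, 0, 1)))
        assert np.max(dev) / scale < 0.02, f"step {delta} mM off the curve"


def test_smoothed_rate_matches_analytic_curve_within_discretization(
        params, wt1_spec, a_wt1, perfect_step_courses):
    # O(dt) bound on the difference-quotient estimate along one course
    tc = perfect_step_courses[0.1]
    cs = extract_collapse(tc, onset_delay=10.0, window=20)
    g = model_curve("power-h3", a_wt1, wt1_spec.g_R,
                    cm.complex_size(0.1, params), params)
    A = np.clip(cs.points["A"].to_numpy(), 0, 1)
    resid = np.abs(cs.points["dAdt"].to_numpy() - g(A))
    block_dt = 20 * 0.2
    assert np.max(resid) < 0.05 * block_dt  # loose O(dt) envelope


def test_imprecise_methylation_branch_falls_below_precise_curve(params,
                                                                a_wt1):
    imp = cm.get_model("power-h3", a=a_wt1, imprecise=True)
    proto = cm.StepProtocol(L_ambient=0.1,
                            events=(cm.Event(20.0, "ADD", 2.0),),
                            k_rise=0.35, k_fall=0.45, t_end=400.0)
    tc = cm.simulate(proto, params, imp, a_wt1)
    cs = extract_collapse(tc, onset_delay=30.0, window=20)
    g = model_curve("power-h3", a_wt1, imp.g_R,
                    cm.complex_size(0.1, params), params)
    pts = cs.points[cs.points["A"] < a_wt1]
    # methylation-branch rates reduced relative to the precise model
    assert np.mean(pts["dAdt"].to_numpy()
                   - g(np.clip(pts["A"].to_numpy(), 0, 1))) < 0


def test_effective_dm_dt_recovers_methylation_kinetics(params, wt1_spec,
                                                       a_wt1,
                                                       perfect_step_courses):
    tc = perfect_step_courses[0.4]
    cs = extract_collapse(tc, onset_delay=10.0, window=20)
    eff = effective_dm_dt(cs, params)
    # the very first block after each event sits on the steepest stretch,
    # where the 4 s difference quotient is coarsest: drop it
    first_of_segment = ~eff.points["direction"].duplicated()
    pts = eff.points.loc[~first_of_segment]
    A = np.clip(pts["A"].to_numpy(), 0, 1)
    expected = np.asarray(cm.dm_dt(A, np.zeros_like(A), wt1_spec))
    got = pts["dmdt"].to_numpy()
    scale = np.max(np.abs(expected))
    assert np.max(np.abs(got - expected)) / scale < 0.02
    # saturated points are dropped by the guard
    assert np.all(A * (1 - A) >= 1e-4)
    # monotone decreasing in A for the precise cooperative model
    order = np.argsort(A)
    fitted = np.polyfit(A[order], got[order], 1)
    assert fitted[0] < 0


def test_fit_gR_zero_residual_on_exact_curve(params, a_wt1):
    g_true = 0.0069
    N = cm.complex_size(0.1, params)
    g = model_curve("power-h3", a_wt1, g_true, N, params)
    A = np.linspace(0.05, 0.6, 40)
    pts = pd.DataFrame(dict(A=A, dAdt=g(A), ambient=0.1, delta=0.1,
                            direction="ADD", N=N))
    g_hat, resid = fit_gR(cm.CollapseSet(points=pts), a_wt1, "power-h3",
                          params)
    assert g_hat == pytest.approx(g_true, abs=1e-10)
    assert resid < 1e-18
    with pytest.raises(ValueError, match="3"):
        fit_gR(cm.CollapseSet(points=pts.iloc[:2]), a_wt1, "power-h3", params)


def test_fit_gR_recovery_and_model_ranking_on_noisy_campaign(params, a_wt1,
                                                             wt1_truths):
    errs, ranks = [], []
    for seed in range(10):
        cs = campaign_collapse("WT1", seed=seed, truths=wt1_truths)
        g_hat, resid_h3 = fit_gR(cs, a_wt1, "power-h3", params)
        _, resid_mm = fit_gR(cs, a_wt1, "mm-nofeedback", params)
        errs.append(abs(g_hat - 0.0069) / 0.0069)
        ranks.append(resid_h3 < resid_mm)
    assert np.median(errs) < 0.10
    assert all(ranks)  # generating model beats the saturated no-feedback model


def test_default_bins_cover_both_sets(params):
    rng = np.random.default_rng(0)
    A1 = rng.uniform(0.05, 0.5, 200)
    A2 = rng.uniform(0.1, 0.6, 50)
    edges = _default_bins(A1, A2, 4)
    assert len(edges) == 5
    for lo, hi in zip(edges[:-1], edges[1:]):
        assert np.any((A1 >= lo) & (A1 <= hi))
        assert np.any((A2 >= lo) & (A2 <= hi))


def _toy_sets(params, a_wt1, seed=0):
    N = cm.complex_size(0.1, params)
    g1 = model_curve("power-h3", a_wt1, 0.0069, N, params)
    g2 = model_curve("power-h3", 0.5, 0.0069, N, params)
    rng = np.random.default_rng(seed)
    A1 = rng.uniform(0.05, 0.55, 120)
    A2 = rng.uniform(0.05, 0.55, 120)
    mk = lambda A, g: cm.CollapseSet(points=pd.DataFrame(dict(
        A=A, dAdt=g(A) + rng.normal(0, 2e-4, len(A)), ambient=0.1,
        delta=0.1, direction="ADD", N=N)))
    return mk(A1, g1), mk(A2, g2), g1, g2


def test_permutation_identical_sets_is_degenerate(params, a_wt1):
    csA, _, g1, _ = _toy_sets(params, a_wt1)
    res = permutation_test(csA, csA, g1, g1, n_pairs=4, n_permutations=64,
                           seed=3)
    assert np.allclose(res.permuted_errors, res.unpermuted_error)


def test_permutation_zero_permutations_still_scores_unpermuted(params, a_wt1):
    csA, csB, g1, g2 = _toy_sets(params, a_wt1)
    res = permutation_test(csA, csB, g1, g2, n_pairs=4, n_permutations=0,
                           seed=3)
    assert len(res.permuted_errors) == 0
    assert res.unpermuted_error > 0


def test_permutation_separated_sets_always_increase_error(params, a_wt1):
    csA, csB, g1, g2 = _toy_sets(params, a_wt1)
    res = permutation_test(csA, csB, g1, g2, n_pairs=4, n_permutations=200,
                           seed=5)
    assert np.all(res.permuted_errors > res.unpermuted_error)


def test_permutation_validation_errors(params, a_wt1):
    csA, csB, g1, g2 = _toy_sets(params, a_wt1)
    with pytest.raises(ValueError, match="exceeds"):
        permutation_test(csA, csB, g1, g2, bin_edges=[0.1, 0.3, 0.5],
                         n_pairs=4, n_permutations=10, seed=0)
    with pytest.raises(ValueError, match="lacks"):
        permutation_test(csA, csB, g1, g2, bin_edges=[0.56, 0.9],
                         n_pairs=1, n_permutations=10, seed=0)
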