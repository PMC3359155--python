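"""Tests of steady-state location and stability at all model levels."""

import numpy as np
import pytest
from scipy.optimize import brentq

import cpebswitch as cs
from cpebswitch.fixed_points import (
    SteadyPolynomial,
    compare_printed_quartic,
    steady_state_polynomial,
)


def dense_scan_roots(params, lo=1e-8, hi=400.0, n=4000):
    """Brute-force oracle: sign changes of the steady-state balance in X_P.

    The balance c a X_P/(a X_P + P7) - lambda f(X_P) is evaluated on a dense
    log grid and refined with brentq, independently of the polynomial route.
    """
    d = cs.derive_constants(params)
    lam = params.lam

    def balance(xp):
        return d.c * d.a * xp / (d.a * xp + d.P7) - lam * cs.xt_of_xp(xp, params)

    grid = np.geomspace(lo, hi, n)
    vals = np.array([balance(g) for g in grid])
    roots = []
    for i in np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        roots.append(brentq(balance, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-14))
    return np.array(roots)


class TestSteadyPolynomial:
    def test_degree_and_zero_constant_term(self, cond1, cond2):
        for p in (cond1, cond2, cond1.replace(lam=3e-4), cond1.replace(k5=1e-4)):
            poly = steady_state_polynomial(p)
            assert poly.degree == 4
            assert poly.coefficients[0] == 0.0
            assert 0.0 in poly.real_nonnegative_roots()

    def test_nonzero_constant_rejected(self):
        with pytest.raises(ValueError):
            SteadyPolynomial(np.array([1.0, 0, 0, 0, 1.0]))

    def test_roots_match_dense_scan_oracle(self, cond1):
        for p in (cond1, cond1.replace(lam=3e-4), cond1.replace(k5=1e-4)):
            roots = steady_state_polynomial(p).real_nonnegative_roots()
            positive = roots[roots > 1e-9]
            oracle = dense_scan_roots(p)
            assert len(positive) == len(oracle)
            np.testing.assert_allclose(np.sort(positive), np.sort(oracle),
                                       rtol=1e-6)

    def test_no_synthesis_means_no_bistability(self, cond1):
        for p in (cond1.replace(k9=0.0), cond1.replace(YT=0.0)):
            roots = steady_state_polynomial(p).real_nonnegative_roots()
            assert len(roots[roots > 1e-9]) <= 1
            assert not cs.solve_fixed_points(p, "quartic").bistable

    def test_printed_z_ladder_documents_the_undefined_symbol(self, cond1):
        """No plausible reading of the published z-coefficients' undefined
        symbol reproduces the eliminated polynomial; the diagnostic reports
        (never averages) the mismatch."""
        report = compare_printed_quartic(cond1)
        assert len(report) == 5
        assert set(report.columns) >= {"candidate", "matches_elimination"}


class TestSolveFixedPoints:
    def test_baseline_three_point_structure(self, quartic_fps1):
        pts = quartic_fps1.points
        assert [p.stability for p in pts] == ["stable", "unstable", "stable"]
        assert quartic_fps1.bistable

    def test_stable_and_unstable_alternate(self, cond1):
        for level in ("quartic", "reduced3", "full"):
            pts = cs.solve_fixed_points(cond1, level).points
            labels = [p.stability for p in pts]
            assert labels in (["stable"], ["stable", "unstable", "stable"])

    def test_quartic_points_vanish_under_reduced3_rhs(self, cond1, quartic_fps1):
        for fp in quartic_fps1.points:
            resid = cs.reduced3_rhs([fp.XT, fp.XP, fp.YP], cond1, cond1.U_basal)
            assert np.max(np.abs(resid)) < 1e-9

    def test_full_level_residuals(self, cond1):
        from cpebswitch.model_core import _full_rhs_raw
        for fp in cs.solve_fixed_points(cond1, "full").points:
            resid = _full_rhs_raw(fp.state, cond1, cond1.U_basal)
            assert np.max(np.abs(resid)) < 1e-9

    def test_heavy_degradation_is_monostable_everywhere(self, cond1, fit1):
        p = cond1.replace(lam=5e-3)
        for level in ("quartic", "one_d", "reduced3", "full"):
            fps = cs.solve_fixed_points(p, level, fit=fit1)
            assert not fps.bistable
            assert min(pt.XT for pt in fps.points) < 0.5

    def test_upper_state_approaches_saturated_balance(self, cond1):
        """Near saturation the upper state sits at c/lambda (within 10%)."""
        d = cs.derive_constants(cond1)
        for lam in (1e-4, 3e-4):
            fps = cs.solve_fixed_points(cond1.replace(lam=lam), "quartic")
            upper = max(p.XT for p in fps.stable())
            assert upper == pytest.approx(d.c / lam, rel=0.10)


class TestClassifyStability:
    def test_basal_point_stable_under_degradation(self, quartic_fps1):
        basal = min(quartic_fps1.points, key=lambda p: p.XT)
        assert basal.stability == "stable"
        assert basal.leading_eigenvalue < 0

    def test_middle_point_unstable(self, quartic_fps1):
        mid = quartic_fps1.points[1]
        assert mid.stability == "unstable"

    @pytest.mark.parametrize("factors", [
        {"k5": 0.5}, {"k5": 2.0}, {"lam": 2.0}, {"k3": 0.01}, {"T": 1.5},
    ])
    def test_eigenvalue_sign_agrees_with_integration_fate(self, cond1, factors):
        """Perturb each fixed point by 2% and integrate: stable points are
        re-approached, the separatrix is fled."""
        from scipy.integrate import solve_ivp
        p = cond1.replace(**{k: getattr(cond1, k) * v if k != "lam"
                             else cond1.lam * v for k, v in factors.items()})
        fps = cs.solve_fixed_points(p, "reduced3")
        if not fps.bistable:
            pytest.skip("perturbed configuration is mono-stable")
        horizon = 5.0 / p.lam
        for fp in fps.points:
            if fp.XT < 0.5:
                continue
            for sign in (+1, -1):
                y0 = np.array([fp.XT * (1 + 0.02 * sign), fp.XP, fp.YP])
                sol = solve_ivp(lambda t, y: cs.reduced3_rhs(y, p, p.U_basal),
                                (0, horizon), y0, method="LSODA",
                                rtol=1e-8, atol=1e-12)
                drift = abs(sol.y[0, -1] - fp.XT)
                start = abs(y0[0] - fp.XT)
                if fp.stability == "stable":
                    assert drift < start
                else:
                    assert drift > 2 * start


class TestCompareLevels:
    def test_condition_I_levels_agree(self, cond1, fit1):
        """With fast autophosphorylation almost no kinase is complex-bound,
        so all four levels share the same three fixed points (within 15%)."""
        cmp = cs.compare_levels(cond1, fit=fit1)
        assert cmp["max_discrepancy"] < 0.15

    def test_condition_II_full_model_exceeds_reductions(self, cond2):
        """Slow autophosphorylation traps kinase in the C1 complex, which
        the reductions degrade but the full model does not: the full
        model's upper state far exceeds the reduced ones."""
        full = cs.solve_fixed_points(cond2, "full")
        reduced = cs.solve_fixed_points(cond2, "reduced3")
        up_full = max(p.XT for p in full.stable())
        up_red = max(p.XT for p in reduced.stable())
        assert up_full > 2.0 * up_red

    def test_comparison_table_shape(self, cond1, fit1):
        cmp = cs.compare_levels(cond1, fit=fit1)
        assert set(cmp["table"]["model_level"]) == {"full", "reduced3",
                                                    "one_d", "quartic"}
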