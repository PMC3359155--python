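"""Tests of the pseudo-steady-state reduction chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cpebswitch as cs
from cpebswitch.model_core import DomainError
from cpebswitch.reduction import xt_of_xp_closed_form, xt_of_xp_printed

pos = st.floats(min_value=1e-6, max_value=150.0, allow_nan=False)


class TestPssaComplexes:
    def test_zero_phospho_kinase_gives_no_kinase_complexes(self, cond1):
        c1, c2, c3 = cs.pssa_complexes(5.0, 0.0, 3.0, 1.0, cond1)
        assert c1 == 0.0 and c2 == 0.0 and c3 > 0.0

    def test_zero_phospho_cpeb_gives_no_translation_complex(self, cond1):
        assert cs.pssa_complexes(5.0, 1.0, 3.0, 0.0, cond1)[2] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(X=pos, XP=pos, Y=pos, YP=pos)
    def test_matches_direct_quotients(self, X, XP, Y, YP, cond1):
        p = cond1
        c1, c2, c3 = cs.pssa_complexes(X, XP, Y, YP, p)
        assert c1 == pytest.approx(p.k1 * X * XP / (p.k2 + p.k3), rel=1e-12)
        assert c2 == pytest.approx(p.k5 * Y * XP / (p.k55 + p.k6), rel=1e-12)
        assert c3 == pytest.approx(p.k8 * YP * p.T / (p.k88 + p.k9), rel=1e-12)


class TestYpNullcline:
    def test_origin_and_saturation(self, cond1):
        assert cs.yp_nullcline(0.0, cond1) == 0.0
        assert cs.yp_nullcline(1e9, cond1) == pytest.approx(cond1.YT, rel=1e-6)

    def test_half_saturation_at_km(self, cond1):
        """Y_P reaches half of Y_T exactly at X_P = P7/a."""
        d = cs.derive_constants(cond1)
        assert cs.yp_nullcline(d.P7 / d.a, cond1) == pytest.approx(
            cond1.YT / 2.0, rel=1e-12)

    def test_monotone_and_bounded(self, cond1):
        xps = np.geomspace(1e-6, 1e4, 200)
        yps = np.array([cs.yp_nullcline(x, cond1) for x in xps])
        assert np.all(np.diff(yps) > 0)
        assert np.all(yps < cond1.YT)

    def test_degenerate_input(self, cond1):
        with pytest.raises(DomainError):
            cs.yp_nullcline(0.0, cond1.replace(k7=0.0))


class TestXFree:
    def test_no_phospho_kinase(self, cond1):
        assert cs.x_free(10.0, 0.0, cond1) == pytest.approx(10.0)

    def test_no_binding_limit(self, cond1):
        p = cond1.replace(k1=0.0, k5=0.0)
        assert cs.x_free(10.0, 3.0, p) == pytest.approx(7.0, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(XT=st.floats(min_value=1.0, max_value=150.0), frac=st.floats(0.0, 0.5))
    def test_composition_reconstructs_total(self, XT, frac, cond1):
        """X + XP + 2 C1 + C2 returns X_T with the complexes at PSSA."""
        p = cond1
        XP = frac * XT
        YP = cs.yp_nullcline(XP, p)
        X = cs.x_free(XT, XP, p, YP=YP)
        c1, c2, _ = cs.pssa_complexes(X, XP, p.YT - YP, YP, p)
        assert X + XP + 2 * c1 + c2 == pytest.approx(XT, rel=1e-10)

    def test_infeasible_composition_raises(self, cond1):
        with pytest.raises(cs.InfeasibleCompositionError):
            cs.x_free(5.0, 5.0, cond1.replace(YT=1e4))


class TestReduced3Rhs:
    def test_origin_is_stationary(self, cond1):
        np.testing.assert_allclose(
            cs.reduced3_rhs(np.zeros(3), cond1, 0.0), np.zeros(3), atol=1e-300)

    def test_xt_equation_is_definitional(self, cond1):
        """dX_T/dt is exactly k9 C3 - lambda X_T with C3 at PSSA."""
        XT, XP, YP = 40.0, 20.0, 5.0
        dxt = cs.reduced3_rhs([XT, XP, YP], cond1, 1e-6)[0]
        c3 = cs.pssa_complexes(1.0, 1.0, 1.0, YP, cond1)[2]
        assert dxt == pytest.approx(cond1.k9 * c3 - cond1.lam * XT, rel=1e-12)

    def test_vanishes_at_fixed_points(self, cond1, quartic_fps1):
        for fp in quartic_fps1.points:
            rhs = cs.reduced3_rhs([fp.XT, fp.XP, fp.YP], cond1, cond1.U_basal)
            assert np.max(np.abs(rhs)) < 1e-9


class TestXtOfXp:
    def test_origin(self, cond1):
        assert cs.xt_of_xp(0.0, cond1) == 0.0

    def test_strictly_increasing(self, cond1):
        xps = np.geomspace(1e-3, 200.0, 150)
        xts = np.array([cs.xt_of_xp(x, cond1) for x in xps])
        assert np.all(np.diff(xts) > 0)

    def test_numeric_elimination_matches_closed_form(self, cond1):
        for xp in np.geomspace(1e-4, 200.0, 40):
            assert cs.xt_of_xp(xp, cond1) == pytest.approx(
                xt_of_xp_closed_form(xp, cond1), rel=1e-10)

    def test_consistent_with_fixed_point_solver(self, cond1, quartic_fps1):
        upper = max(quartic_fps1.points, key=lambda p: p.XT)
        assert cs.xt_of_xp(upper.XP, cond1) == pytest.approx(upper.XT, rel=1e-6)

    def test_printed_variant_deviates_only_slightly(self, cond1):
        """The published I4 term drops a factor k6~0.96; the effect on X_T
        stays below 5% across the physiological range."""
        for xp in np.geomspace(1e-3, 150.0, 30):
            printed = xt_of_xp_printed(xp, cond1)
            exact = xt_of_xp_closed_form(xp, cond1)
            assert printed == pytest.approx(exact, rel=0.05)


class TestInversionFit:
    def test_zero_intercept_exact(self, fit1):
        assert fit1(0.0) == 0.0

    def test_round_trip_on_the_trusted_domain(self, cond1, fit1):
        """f(h(X_T)) returns X_T within 2% on the middle 90% of the fit's
        validity domain (the basal shoulder below domain_lo is excluded,
        where a degree-9 polynomial cannot follow the near-ramp inverse)."""
        lo = fit1.domain_lo + 0.05 * (fit1.domain_hi - fit1.domain_lo)
        hi = fit1.domain_hi - 0.05 * (fit1.domain_hi - fit1.domain_lo)
        for xt in np.linspace(lo, hi, 60):
            back = cs.xt_of_xp(max(float(fit1(xt)), 0.0), cond1)
            assert back == pytest.approx(xt, rel=0.02)

    def test_residual_small_relative_to_domain(self, fit1):
        """The fit overlays the exact map: max residual under 0.5% of the
        domain width (the published overlay check, done numerically)."""
        assert fit1.max_abs_residual < 5e-3 * fit1.domain_hi

    def test_nondecreasing_on_domain(self, cond1, fit1):
        xts = np.linspace(fit1.domain_lo, fit1.domain_hi, 400)
        h = np.asarray(fit1(xts))
        assert np.all(np.diff(h) > -1e-9)

    def test_json_round_trip(self, tmp_path, fit1):
        path = tmp_path / "fit.json"
        fit1.to_json(path)
        loaded = cs.InversionFit.from_json(path)
        assert loaded(50.0) == pytest.approx(fit1(50.0), rel=1e-14)

    def test_small_grid_rejected(self, cond1):
        with pytest.raises(ValueError):
            cs.fit_inversion(cond1, grid_size=10)


class TestOneDRhs:
    def test_origin(self, cond1, fit1):
        assert cs.one_d_rhs(0.0, cond1, fit1) == 0.0

    def test_sign_pattern_matches_three_intersections(self, cond1, fit1,
                                                      quartic_fps1):
        """Negative below the separatrix, positive between separatrix and
        upper state, negative above: the three-crossing geometry of the
        synthesis/degradation curves."""
        _, sep, upper = (p.XT for p in quartic_fps1.points)
        assert cs.one_d_rhs(0.6 * sep, cond1, fit1) < 0
        assert cs.one_d_rhs(0.5 * (sep + upper), cond1, fit1) > 0
        assert cs.one_d_rhs(1.3 * upper, cond1, fit1) < 0

    def test_synthesis_saturates_at_c(self, cond1, fit1):
        d = cs.derive_constants(cond1)
        g = np.asarray(cs.synthesis_rate(
            np.linspace(0, fit1.domain_hi, 300), cond1, fit1))
        assert np.all(g <= d.c * (1 + 1e-12))
        assert g[-1] > 0.99 * d.c

    def test_outside_domain_rejected(self, cond1, fit1):
        with pytest.raises(DomainError):
            cs.one_d_rhs(fit1.domain_hi * 1.01, cond1, fit1)

    def test_curve_table_columns(self, cond1, fit1):
        df = cs.reduction.curve_table(cond1, fit1, n=50)
        assert list(df.columns) == ["XT", "XP", "G_prime", "F"]
        assert len(df) == 50
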