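import math

import numpy as np
import pytest

from adipoint import (
    ModelParameters,
    appetite_intake,
    appetite_line_fat,
    critical_fat,
    diet_line_intake,
    fat_line,
    fat_line_points,
    kcrit,
    leptin_line,
    leptin_qss,
    solve_operating_point,
)
from adipoint.parameters import random_valid_parameters

from conftest import grid_bisect_intersection

# Frozen from the independent bisection oracle (see conftest), default set:
FST_ORACLE = 0.5196898479113813
UST_ORACLE = 0.9621123098892268


class TestDietLine:
    def test_zero_cost_origin(self, default_params):
        p = default_params.with_(gammaE=1e-300)  # gammaE -> 0 limit
        assert diet_line_intake(0.0, p) == pytest.approx(0.0, abs=1e-280)

    def test_value_at_operating_fat(self, default_params):
        assert diet_line_intake(FST_ORACLE, default_params) == pytest.approx(
            UST_ORACLE, rel=1e-12)

    def test_normalized_inverse_form(self):
        # printed normalized fit a=1.56, b=0.49: F = 1.56*u - 0.49 at u=1
        a, b = 1.56, 0.49
        assert a * 1.0 - b == pytest.approx(1.07)

    def test_monotone_and_rejects_negative_fat(self, default_params, rng):
        F = np.sort(rng.uniform(0, 3, 50))
        u = diet_line_intake(F, default_params)
        assert np.all(np.diff(u) > 0)
        with pytest.raises(ValueError):
            diet_line_intake(-0.1, default_params)


class TestAppetiteLine:
    def test_fat_vanishes_at_satiety_boundary(self, default_params):
        # F ~ (umax/u - 1)**(1/n) -> 0 as u -> umax, at the algebraic rate eps**(1/n)
        p = default_params
        eps = np.array([1e-3, 1e-6, 1e-9, 1e-12])
        F = appetite_line_fat(p.umax * (1 - eps), p, n=7.1)
        assert np.all(np.diff(F) < 0) and F[-1] < 0.01

    def test_large_n_approaches_steep_limit(self, default_params):
        F100 = appetite_line_fat(1.0, default_params, n=100)
        F_inf = critical_fat(default_params) * default_params.umax / 1.0
        assert abs(F100 - F_inf) < 1e-3

    def test_linear_in_KL(self, default_params):
        base = appetite_line_fat(1.2, default_params, n=7.1)
        doubled = appetite_line_fat(1.2, default_params.with_(KL=1.0), n=7.1)
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_domain_rejected(self, default_params):
        for bad_u in (0.0, -1.0, 2.0, 2.5):
            with pytest.raises(ValueError):
                appetite_line_fat(bad_u, default_params, n=7.1)
        with pytest.raises(ValueError, match="finite n"):
            appetite_line_fat(1.0, default_params)


class TestAppetiteIntake:
    def test_no_leptin_no_inhibition(self, default_params):
        assert appetite_intake(0.0, default_params) == default_params.umax
        assert appetite_intake(0.0, default_params, n=7.1) == default_params.umax

    def test_steep_limit_value(self, default_params):
        # u = Fc*umax/F = 0.25*2/0.5
        assert appetite_intake(0.5, default_params) == pytest.approx(1.0, rel=1e-12)

    def test_continuity_at_critical_fat(self, default_params):
        Fc = critical_fat(default_params)
        assert appetite_intake(Fc, default_params) == default_params.umax
        assert appetite_intake(Fc * (1 + 1e-9), default_params) == pytest.approx(
            default_params.umax, rel=1e-8)

    def test_finite_n_inverts_appetite_line(self, default_params):
        # fixed-point solution and closed-form line are inverses of each other
        for n in (3.0, 7.1, 40.0):
            for u in (0.5, 1.0, 1.7):
                F = appetite_line_fat(u, default_params, n=n)
                assert appetite_intake(F, default_params, n=n) == pytest.approx(u, rel=1e-9)

    @pytest.mark.parametrize("n", [7, 100, 1000])
    def test_pointwise_convergence_to_steep_limit(self, default_params, n):
        F = np.array([0.05, 0.15, 0.35, 0.6, 1.0, 1.5])
        u_n = appetite_intake(F, default_params, n=n)
        u_inf = appetite_intake(F, default_params)
        # convergence: error shrinks with n, and is small for n=1000
        if n == 1000:
            away = np.abs(F - critical_fat(default_params)) > 0.05
            assert np.max(np.abs(u_n - u_inf)[away]) < 0.01

    def test_non_increasing_in_fat(self, default_params, rng):
        F = np.sort(rng.uniform(0, 2.5, 60))
        for n in (5.0, 100.0, math.inf):
            u = appetite_intake(F, default_params, n=n)
            assert np.all(np.diff(u) <= 1e-12)


class TestCriticalValues:
    def test_critical_fat_default(self, default_params):
        assert critical_fat(default_params) == pytest.approx(0.25)

    def test_critical_fat_proportional_to_KL(self, default_params):
        KLs = np.linspace(0.35, 1.6, 7)
        Fcs = [critical_fat(default_params.with_(KL=k)) for k in KLs]
        ratio = np.array(Fcs) / KLs
        assert np.allclose(ratio, ratio[0])

    def test_kcrit_default_and_zero_cost(self, default_params):
        assert kcrit(default_params) == pytest.approx(2.7, rel=1e-12)
        zero_cost = default_params.with_(gammaE=1e-300)
        # aL*umax^2*aF/(gammaL*gammaF) = 3.2
        assert kcrit(zero_cost) == pytest.approx(3.2, rel=1e-9)

    def test_kcrit_solves_defining_equality(self, default_params, rng):
        # Fc(KL*) equals the diet-line fat at u=umax
        for _ in range(20):
            p = random_valid_parameters(rng)
            KL_star = kcrit(p)
            ps = p.with_(KL=KL_star)
            assert critical_fat(ps) == pytest.approx(
                (p.aF * p.umax - p.gammaE) / p.gammaF, rel=1e-12)

    def test_kcrit_linear_in_aL(self, default_params):
        k1 = kcrit(default_params)
        k3 = kcrit(default_params.with_(aL=3.0))
        assert k3 == pytest.approx(3 * k1, rel=1e-12)

    def test_kcrit_infeasible_raises(self, default_params):
        with pytest.raises(ValueError, match="positive-fat"):
            kcrit(default_params.with_(gammaE=0.05))


class TestOperatingPoint:
    def test_default_above_critical_values(self, default_params):
        op = solve_operating_point(default_params)
        assert op.regime == "above-critical"
        assert op.Fst == pytest.approx(FST_ORACLE, rel=1e-10)
        assert op.ust == pytest.approx(UST_ORACLE, rel=1e-10)
        assert op.Lst == default_params.KL  # exact in this regime

    def test_satiety_capped_values(self, default_params):
        op = solve_operating_point(default_params.with_(KL=5.4))
        assert op.regime == "satiety-capped"
        assert op.ust == default_params.umax  # exact in this regime
        assert op.Fst == pytest.approx(1.35, rel=1e-12)
        assert op.Lst == pytest.approx(2.7, rel=1e-12)
        # leptin quasi-steady consistency: (aL/gammaL)*F*u
        assert leptin_qss(op.Fst, op.ust, default_params) == pytest.approx(op.Lst)

    def test_matches_independent_bisection_oracle(self, rng):
        for _ in range(100):
            p = random_valid_parameters(rng)
            op = solve_operating_point(p)
            F_oracle = grid_bisect_intersection(p)
            assert op.Fst == pytest.approx(F_oracle, rel=1e-8)
            if p.KL < op.Kcrit:
                assert op.Lst == p.KL

    def test_finite_n_matches_oracle(self, rng):
        for _ in range(10):
            p = random_valid_parameters(rng, n=9.0)
            op = solve_operating_point(p)
            assert op.Fst == pytest.approx(grid_bisect_intersection(p, n=9.0), rel=1e-8)

    def test_regime_continuity_at_kcrit(self, default_params):
        Kc = kcrit(default_params)
        below = solve_operating_point(default_params.with_(KL=Kc * (1 - 1e-9)))
        at = solve_operating_point(default_params.with_(KL=Kc))
        above = solve_operating_point(default_params.with_(KL=Kc * (1 + 1e-9)))
        assert below.Fst == pytest.approx(at.Fst, rel=1e-7)
        assert above.Fst == pytest.approx(at.Fst, rel=1e-7)
        assert at.regime == "above-critical"  # closed-interval boundary choice
        assert above.regime == "satiety-capped"

    def test_no_positive_intersection_raises(self, default_params):
        with pytest.raises(ValueError, match="positive-fat"):
            solve_operating_point(default_params.with_(gammaE=0.05))


class TestOperatingPointProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(KL=st.floats(0.05, 4.0), umax=st.floats(0.5, 5.0),
           aF=st.floats(0.005, 0.08), gammaE=st.floats(1e-4, 0.02))
    def test_intersection_consistency(self, KL, umax, aF, gammaE):
        """Wherever a positive steady state exists, both lines pass through
        it and leptin sits at its quasi-steady value."""
        p = ModelParameters(aF=aF, KL=KL, umax=umax, gammaE=gammaE)
        if not p.feasible_positive_fat:
            return
        op = solve_operating_point(p)
        assert diet_line_intake(op.Fst, p) == pytest.approx(op.ust, rel=1e-9)
        assert appetite_intake(op.Fst, p) == pytest.approx(op.ust, rel=1e-9)
        assert leptin_qss(op.Fst, op.ust, p) == pytest.approx(op.Lst, rel=1e-9)
        assert (op.regime == "satiety-capped") == (p.KL > op.Kcrit)


class TestLeptinNullclines:
    def test_qss_bilinear(self, default_params):
        assert leptin_qss(0.0, 1.3, default_params) == 0.0
        assert leptin_qss(1.35, 2.0, default_params) == pytest.approx(2.7)
        assert leptin_qss(0.7, 3 * 0.9, default_params) == pytest.approx(
            3 * leptin_qss(0.7, 0.9, default_params))

    def test_leptin_line_equals_qss_composition(self, default_params, rng):
        F = rng.uniform(0, 3, 40)
        composed = leptin_qss(F, diet_line_intake(F, default_params), default_params)
        assert np.allclose(leptin_line(F, default_params), composed, rtol=1e-13)

    def test_leptin_line_at_operating_point_equals_KL(self, default_params):
        assert leptin_line(FST_ORACLE, default_params) == pytest.approx(0.5, rel=1e-9)

    def test_reduced_quadratic_coefficients(self, default_params, rng):
        # L = a*F^2 + b*F with a = aL*gammaF/(gammaL*aF), b = aL*gammaE/(gammaL*aF)
        p = default_params
        a = p.aL * p.gammaF / (p.gammaL * p.aF)
        b = p.aL * p.gammaE / (p.gammaL * p.aF)
        F = rng.uniform(0, 2, 20)
        assert np.allclose(leptin_line(F, p), a * F ** 2 + b * F, rtol=1e-13)

    def test_pure_quadratic_without_body_cost(self, default_params):
        p = default_params.with_(gammaE=1e-300)
        F = np.array([0.5, 1.0, 2.0])
        L = leptin_line(F, p)
        assert L[1] / L[0] == pytest.approx(4.0, rel=1e-9)


class TestFatLine:
    def test_steep_limit_plateaus(self, default_params):
        assert fat_line(0.3, default_params) == pytest.approx(1.35)
        assert fat_line(0.8, default_params) == pytest.approx(-0.25)

    def test_negative_branch_flagged_as_diminished(self, default_params):
        pts = fat_line_points([0.3, 0.8], default_params)
        assert list(pts["diminished"]) == [False, True]

    def test_zero_leptin_finite_n_equals_plateau(self, default_params):
        assert fat_line(0.0, default_params, n=7.1) == pytest.approx(1.35)
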