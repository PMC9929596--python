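import numpy as np
import pytest

from adipoint import (
    ModelParameters,
    PhasePoint,
    SimulationConfig,
    appetite_intake,
    daily_intake,
    detect_transient,
    refeeding_initial_condition,
    simulate,
    simulate_clamped_intake,
    solve_operating_point,
)

# Frozen refeeding initial conditions (inverse diet line at factor*ust,
# computed from the bisection-oracle steady state):
UNDERFEED_IC = (0.28878289353796693, 0.6734786169224587)
OVERFEED_IC = (0.827565787075934, 1.3469572338449174)
JUMP_UNDER = 1.7314044951705696   # Fc*umax/F0, steep-limit appetite at F0
JUMP_OVER = 0.6041815742125672


class TestRefeedingInitialCondition:
    def test_factor_one_is_operating_point(self, default_params):
        op = solve_operating_point(default_params)
        ic = refeeding_initial_condition(default_params, 1.0)
        assert ic.F == pytest.approx(op.Fst, rel=1e-12)
        assert ic.u == pytest.approx(op.ust, rel=1e-12)

    @pytest.mark.parametrize("factor, expected", [(0.7, UNDERFEED_IC), (1.4, OVERFEED_IC)])
    def test_protocol_values(self, default_params, factor, expected):
        ic = refeeding_initial_condition(default_params, factor)
        assert (ic.F, ic.u) == pytest.approx(expected, rel=1e-10)

    def test_starvation_factor_rejected(self, default_params):
        with pytest.raises(ValueError, match="starvation"):
            refeeding_initial_condition(default_params, 0.1)


class TestSimulate:
    def test_operating_point_is_fixed(self, default_params):
        op = solve_operating_point(default_params, n=100)
        traj = simulate(default_params, PhasePoint(op.Fst, op.ust))
        assert np.allclose(traj.F, op.Fst, rtol=1e-6)
        assert np.allclose(traj.u, op.ust, rtol=1e-6)

    def test_converges_to_operating_point(self, default_params):
        op = solve_operating_point(default_params, n=100)
        cfg = SimulationConfig(t_end=150.0)
        for factor in (0.7, 1.4):
            traj = simulate(default_params, refeeding_initial_condition(default_params, factor), cfg)
            assert traj.F[-1] == pytest.approx(op.Fst, rel=0.01)
            assert traj.u[-1] == pytest.approx(op.ust, rel=0.01)

    def test_underfeeding_recovery_jumps_to_appetite_line(self, default_params):
        # quasi-steady intake starts exactly at the appetite response to F0
        ic = refeeding_initial_condition(default_params, 0.7)
        cfg = SimulationConfig(t_end=200.0, leptin_mode="quasi-steady")
        traj = simulate(default_params, ic, cfg)
        # matches the finite-n appetite response exactly and the steep-limit
        # jump oracle within 5% (F0 sits near the corner that finite n rounds)
        assert traj.u[0] == pytest.approx(
            appetite_intake(ic.F, default_params, n=100), rel=1e-6)
        assert traj.u[0] == pytest.approx(JUMP_UNDER, rel=0.05)
        # then decays monotonically toward the steady intake
        assert np.all(np.diff(traj.u[1:]) < 1e-9)
        assert traj.u[-1] == pytest.approx(0.9621123, rel=1e-3)

    def test_overfeeding_first_ad_lib_intake_below_steady(self, default_params):
        ic = refeeding_initial_condition(default_params, 1.4)
        traj = simulate(default_params, ic, SimulationConfig(t_end=200.0))
        op = solve_operating_point(default_params, n=100)
        assert traj.u[1] == pytest.approx(JUMP_OVER, rel=0.05)
        assert traj.u[1] < op.ust

    def test_quasi_steady_and_dynamic_agree_after_fast_phase(self, default_params):
        ic = refeeding_initial_condition(default_params, 1.4)
        cfg_d = SimulationConfig(t_end=100.0)
        cfg_q = SimulationConfig(t_end=100.0, leptin_mode="quasi-steady")
        td = simulate(default_params, ic, cfg_d)
        tq = simulate(default_params, ic, cfg_q)
        late = td.t >= 5.0
        assert np.allclose(td.F[late], tq.F[late], rtol=0.02)

    def test_timescale_separation_crawl_along_appetite_line(self, default_params):
        # after the leptin transient, |u - appetite(F)| stays below 5%
        ic = refeeding_initial_condition(default_params, 1.4)
        cfg = SimulationConfig(t_end=100.0, dt_out=5.0)
        traj = simulate(default_params, ic, cfg)
        pn = default_params.with_(n=100.0)
        for F, u in zip(traj.F[1:], traj.u[1:]):
            assert abs(u - appetite_intake(F, pn)) / u < 0.05

    def test_energy_bookkeeping(self, default_params):
        # dF/dt from the trajectory matches aF*u - gammaE - gammaF*F
        ic = refeeding_initial_condition(default_params, 0.7)
        cfg = SimulationConfig(t_end=60.0, dt_out=0.25)
        traj = simulate(default_params, ic, cfg)
        p = default_params
        dFdt = np.gradient(traj.F, traj.t)
        rhs = p.aF * traj.u - p.gammaE - p.gammaF * traj.F
        # exclude the first few points where the leptin transient makes u move fast
        settled = traj.t > 5
        assert np.allclose(dFdt[settled], rhs[settled], atol=2e-3)

    def test_daily_intake_integrates_dense_solution(self, default_params):
        op = solve_operating_point(default_params, n=100)
        traj = simulate(default_params, PhasePoint(op.Fst, op.ust))
        table = daily_intake(traj)
        assert list(table.columns) == ["day", "intake", "fat"]
        assert np.allclose(table["intake"], op.ust, rtol=1e-6)

    def test_clamped_intake_matches_linear_solution(self, default_params):
        p = default_params
        traj = simulate_clamped_intake(p, 0.5, 1.2, 40.0, dt_out=2.0)
        Fss = (p.aF * 1.2 - p.gammaE) / p.gammaF
        expected = Fss + (0.5 - Fss) * np.exp(-p.gammaF * traj.t)
        assert np.allclose(traj.F, expected, rtol=1e-12)
        assert np.all(traj.u == 1.2)


class TestDetectTransient:
    def _traj(self, u, u0=None, default=None):
        p = default or ModelParameters()
        t = np.arange(len(u), dtype=float)
        from adipoint.dynamics import Trajectory

        return Trajectory(t=t, F=np.ones_like(t), L=np.ones_like(t),
                          u=np.asarray(u, dtype=float), params=p,
                          init=PhasePoint(1.0, u0 if u0 is not None else u[0]),
                          config=SimulationConfig())

    def test_constant_is_monotone(self):
        assert detect_transient(self._traj([1.0] * 20)) == "monotone"

    def test_monotone_rise_is_not_an_undershoot(self):
        u = 1.0 + 0.5 * (1 - np.exp(-np.linspace(0, 10, 40)))
        assert detect_transient(self._traj(u)) == "monotone"

    def test_jump_then_decay_is_overshoot(self):
        u = 1.0 + 0.8 * np.exp(-np.linspace(0, 12, 60))
        assert detect_transient(self._traj(u, u0=0.9)) == "overshoot"

    def test_dip_then_recovery_is_undershoot(self):
        u = 1.0 - 0.5 * np.exp(-np.linspace(0, 12, 60))
        assert detect_transient(self._traj(u, u0=1.2)) == "undershoot"

    def test_unsettled_is_inconclusive_not_a_guess(self):
        u = np.linspace(1.0, 2.0, 30)  # still rising at the end
        assert detect_transient(self._traj(u)) == "inconclusive"

    def test_underfeeding_recovery_is_overshoot(self, default_params):
        ic = refeeding_initial_condition(default_params, 0.7)
        traj = simulate(default_params, ic, SimulationConfig(t_end=200.0))
        assert detect_transient(traj) == "overshoot"

    def test_exercise_onset_is_monotone(self, default_params):
        # raised body energy cost from the old operating point: intake rises
        # monotonically (the initial state stays on the appetite line)
        op = solve_operating_point(default_params, n=100)
        harder = default_params.with_(gammaE=0.01875)
        traj = simulate(harder, PhasePoint(op.Fst, op.ust), SimulationConfig(t_end=300.0))
        assert detect_transient(traj, u_ref=op.ust) == "monotone"
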