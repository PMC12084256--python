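import json

import numpy as np
import pytest

from qssa.kinetics import PhaseState, RateConstants
from qssa.phase_geometry import curve, funnel
from qssa.simulate import (
    error_metrics,
    find_crossing,
    integrate_full,
    integrate_reduction,
    integrate_rqssa_outer,
    rate_bound_check,
    sqssa_time_of_substrate,
)


@pytest.fixture(scope="module")
def fig3_full(unit_params_module):
    return integrate_full(unit_params_module, PhaseState(6.0, 0.0))


@pytest.fixture(scope="module")
def unit_params_module():
    return RateConstants(1.0, 1.0, 1.0, 6.0)


class TestIntegrateFull:
    @pytest.mark.parametrize("s0", [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    def test_enters_trapping_region(self, s0, unit_params_module):
        # trajectories from the s-axis cross the c-nullcline in finite time
        p = unit_params_module
        traj = integrate_full(p, PhaseState(s0, 0.0))
        t_cross = find_crossing(traj, curve("gamma_c", p))
        assert t_cross is not None
        assert 0 < t_cross < traj.t_end

    def test_no_flux_when_e0_zero(self):
        p = RateConstants(1.0, 1.0, 1.0, 0.0)
        traj = integrate_full(p, PhaseState(5.0, 0.0), horizon=10.0)
        np.testing.assert_allclose(traj.s, 5.0, rtol=1e-9)

    def test_mass_conservation(self, fig3_full, unit_params_module):
        assert np.all(fig3_full.c <= unit_params_module.e0 * (1 + 1e-9))
        assert np.all(fig3_full.c >= -1e-12)

    def test_substrate_range(self, fig3_full):
        assert np.all(fig3_full.s <= 6.0 * (1 + 1e-9))
        assert np.all(fig3_full.s >= -1e-12)

    def test_stops_near_s_stop(self, fig3_full):
        assert fig3_full.s[-1] == pytest.approx(6e-3, rel=1e-6)

    def test_rejects_bad_horizon(self, unit_params_module):
        with pytest.raises(ValueError):
            integrate_full(unit_params_module, PhaseState(1.0, 0.0),
                           horizon=-1.0)

    def test_stays_in_funnel_after_entering(self, fig3_full,
                                            unit_params_module):
        # once past t_cross the trajectory never exits Gamma_0
        p = unit_params_module
        t_cross = find_crossing(fig3_full, curve("gamma_c", p))
        f = funnel("Gamma_0", p)
        ts = np.linspace(t_cross, fig3_full.t_end, 400)
        s, c = fig3_full.sample(ts)
        lo = f.lower.value(s)
        hi = f.upper.value(s)
        slack = 1e-6 * np.maximum(np.abs(hi), 1e-12)
        assert np.all(c >= lo - slack)
        assert np.all(c <= hi + slack)


class TestIntegrateReduction:
    def test_sqssa_against_closed_form_time(self, unit_params_module):
        # oracle: t(s) = (K_M ln(s0/s) + s0 - s)/(k2 e0)
        p = unit_params_module
        traj = integrate_reduction("sqssa", p, 6.0)
        for s_target in (3.0, 1.0, 0.1):
            t_oracle = sqssa_time_of_substrate(s_target, 6.0, p)
            s_num, _ = traj.sample(t_oracle)
            assert float(s_num[0]) == pytest.approx(s_target, rel=1e-6)

    def test_complex_reconstruction_on_qss_curve(self, unit_params_module):
        p = unit_params_module
        traj = integrate_reduction("sqssa", p, 6.0)
        expect = p.e0 * traj.s / (p.K_M + traj.s)
        np.testing.assert_allclose(traj.c, expect, rtol=1e-12)

    def test_slow_product_constant_when_k2_zero(self):
        p = RateConstants(1.0, 1.0, 0.0, 6.0)
        traj = integrate_reduction("slow_product", p, 4.0, horizon=25.0)
        np.testing.assert_allclose(traj.s, 4.0, rtol=1e-10)

    def test_rejects_negative_ic(self, unit_params_module):
        with pytest.raises(ValueError):
            integrate_reduction("sqssa", unit_params_module, -1.0)


class TestRqssaOuter:
    def test_linear_depletion(self):
        p = RateConstants(1.0, 1.0, 1.0, 6.0)
        traj = integrate_rqssa_outer(p, 10.0)
        # s(t) = s0 - e0 - k2 e0 t from the shifted start (4, 6)
        assert traj.s[0] == pytest.approx(4.0)
        assert np.all(traj.c == p.e0)
        ts = np.linspace(0.0, traj.t_end, 50)
        s, _ = traj.sample(ts)
        np.testing.assert_allclose(s, np.clip(4.0 - 6.0 * ts, 0.0, None),
                                   atol=1e-12)

    def test_clipped_at_zero(self):
        p = RateConstants(1.0, 1.0, 1.0, 6.0)
        traj = integrate_rqssa_outer(p, 10.0)
        assert traj.s[-1] == pytest.approx(0.0, abs=1e-12)


class TestFindCrossing:
    def test_start_on_curve_returns_zero(self, unit_params_module):
        p = unit_params_module
        gc = curve("gamma_c", p)
        ic = PhaseState(3.0, float(gc.value(3.0)))
        traj = integrate_full(p, ic)
        assert find_crossing(traj, gc) == pytest.approx(0.0, abs=1e-12)

    def test_gamma_sp_crossing_exists_large_s0(self, unit_params_module):
        # e0 = 6 < 8 K_S = 8: both crossings exist; from s0 = 12 > s* = 5
        # the trajectory ascends where gamma_SP < gamma_c, so the
        # slow-product curve is met first
        p = unit_params_module
        traj = integrate_full(p, PhaseState(12.0, 0.0))
        t_c = find_crossing(traj, curve("gamma_c", p))
        t_sp = find_crossing(traj, curve("gamma_SP", p))
        assert t_c is not None and t_sp is not None
        assert 0 < t_sp < t_c

    def test_gamma_sp_crossed_after_gamma_c_small_s0(self, unit_params_module):
        # from s0 = 2 < s* = 5 the c-nullcline lies below gamma_SP, so it
        # is crossed first
        p = unit_params_module
        traj = integrate_full(p, PhaseState(2.0, 0.0))
        t_c = find_crossing(traj, curve("gamma_c", p))
        t_sp = find_crossing(traj, curve("gamma_SP", p))
        assert t_c is not None and t_sp is not None
        assert 0 < t_c < t_sp

    def test_stays_in_gamma_sp_after_crossing(self, unit_params_module):
        # positive invariance of the slow-product anti-funnel (e0 < 8 K_S)
        p = unit_params_module
        traj = integrate_full(p, PhaseState(12.0, 0.0))
        t_sp = find_crossing(traj, curve("gamma_SP", p))
        f = funnel("Gamma_SP", p)
        ts = np.linspace(t_sp, traj.t_end, 300)
        s, c = traj.sample(ts)
        lo = f.lower.value(s)
        hi = f.upper.value(s)
        slack = 1e-6 * np.maximum(np.abs(hi), 1e-12)
        assert np.all(c >= lo - slack)
        assert np.all(c <= hi + slack)

    def test_absent_crossing_is_none(self, unit_params_module):
        # a trajectory started inside Gamma_0 never returns to gamma_s
        p = unit_params_module
        gs = curve("gamma_s", p)
        gc = curve("gamma_c", p)
        ic = PhaseState(3.0, float(0.5 * (gc.value(3.0) + gs.value(3.0))))
        traj = integrate_full(p, ic)
        assert find_crossing(traj, gs) is None


class TestErrorMetrics:
    def test_identical_trajectories_zero(self, fig3_full):
        m = error_metrics(fig3_full, fig3_full)
        assert m == {"max_abs": 0.0, "max_rel": 0.0, "L2": 0.0}

    def test_empty_window_rejected(self, fig3_full):
        with pytest.raises(ValueError):
            error_metrics(fig3_full, fig3_full, window=(5.0, 5.0))

    def test_error_halves_with_e0(self):
        # first-order convergence: halving e0 halves the slow-regime error
        errs = {}
        for e0 in (0.2, 0.1):
            p = RateConstants(1.0, 1.0, 1.0, e0)
            full = integrate_full(p, PhaseState(10.0, 0.0))
            t_cross = find_crossing(full, curve("gamma_c", p))
            red = integrate_reduction("sqssa", p, 10.0,
                                      horizon=full.t_end * 1.05, s_stop=0.0)
            errs[e0] = error_metrics(full, red,
                                     window=(t_cross, full.t_end))["max_abs"]
        assert errs[0.2] / errs[0.1] == pytest.approx(2.0, rel=0.2)

    def test_tolerance_robustness(self, unit_params_module):
        # 10x tighter solver tolerances move the metric by < 1%
        p = unit_params_module
        vals = []
        for factor in (1.0, 0.1):
            full = integrate_full(p, PhaseState(6.0, 0.0),
                                  rtol=1e-8 * factor, atol=1e-10 * factor)
            t_cross = find_crossing(full, curve("gamma_c", p))
            red = integrate_reduction("sqssa", p, 6.0, rtol=1e-8 * factor,
                                      atol=1e-10 * factor,
                                      horizon=full.t_end * 1.05, s_stop=0.0)
            vals.append(error_metrics(full, red,
                                      window=(t_cross, full.t_end))["max_rel"])
        assert vals[0] == pytest.approx(vals[1], rel=1e-2)


class TestRateBoundCheck:
    def test_prop2_zero_violations(self, fig3_full, unit_params_module):
        res = rate_bound_check(fig3_full, unit_params_module, "prop2")
        assert res["n_violations"] == 0
        assert res["n_checked"] > 0

    def test_prop1_zero_violations(self, fig3_full, unit_params_module):
        res = rate_bound_check(fig3_full, unit_params_module, "prop1")
        assert res["n_violations"] == 0

    def test_eq67_zero_violations(self, fig3_full, unit_params_module):
        # K = 1 < e0 = 6 < 8 K_S = 8, s* = 5
        res = rate_bound_check(fig3_full, unit_params_module, "eq67")
        assert res["n_violations"] == 0
        assert res["chain_ok"]

    def test_eq67_requires_regime(self, fig3_full):
        p = RateConstants(0.1, 1.0, 1.0, 6.0)  # e0 < K
        traj = integrate_full(p, PhaseState(6.0, 0.0))
        with pytest.raises(ValueError, match="K < e0"):
            rate_bound_check(traj, p, "eq67")

    def test_degenerate_e0_zero(self):
        p = RateConstants(1.0, 1.0, 1.0, 0.0)
        traj = integrate_full(p, PhaseState(5.0, 0.0), horizon=1.0)
        res = rate_bound_check(traj, p, "prop2")
        assert res["n_violations"] == 0

    def test_unknown_kind(self, fig3_full, unit_params_module):
        with pytest.raises(ValueError):
            rate_bound_check(fig3_full, unit_params_module, "prop3")


class TestSerialization:
    def test_csv_columns(self, fig3_full, tmp_path):
        path = tmp_path / "traj.csv"
        fig3_full.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t,s,c,model"

    def test_json_round_trip(self, fig3_full, tmp_path):
        path = tmp_path / "traj.json"
        fig3_full.events["t_cross"] = 0.25
        fig3_full.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["model"] == "full"
        assert payload["params"]["e0"] == 6.0
        assert payload["events"]["t_cross"] == 0.25
        np.testing.assert_allclose(payload["s"], fig3_full.s)
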