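"""Forward simulation of the four transcription models."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from grmfit.models import (
    ParamSet,
    TAU_TF_S,
    auc,
    delayed_value,
    hill,
    mfi,
    sim_fold_change,
    simulate,
    steady_state,
)
from grmfit.models.params import MODEL_SPECS
from grmfit.timecourse import InputGrid, T_END_S, T_START_S


def constant_grid(value: float, cond="ctrl") -> InputGrid:
    n = T_END_S - T_START_S + 1
    return InputGrid(T_START_S, T_END_S, np.full(n, value), condition=cond)


def step_grid(v1: float) -> InputGrid:
    """Grid constant at v1 (the pre-window hold rule makes any within-grid
    step coincide with its t=0 value, so step responses are realized through
    the initial condition instead)."""
    return constant_grid(v1)


@pytest.fixture(scope="module")
def cycle_params():
    return ParamSet.create(
        "cycle3", k_1=2e-3, k_2=0.5, k_deg=1e-3, K_D1=0.05, K_D2=0.05, tau=600
    )


class TestHill:
    def test_symmetry_point(self):
        for h in (1.0, 2.0, 3.7):
            assert hill(2.0, 0.5, h) == pytest.approx(0.5)

    def test_zero_input(self):
        assert hill(0.0, 10.0, 2.0) == 0.0

    def test_direct_evaluation(self):
        assert hill(3.0, 1.0, 2.0) == pytest.approx(9.0 / 10.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill(-1.0, 1.0, 1.0)


class TestDelayedValue:
    def test_zero_delay_is_identity(self, rep1):
        g = rep1["ctrl"]
        assert delayed_value(g, 1800.0, 0.0) == g.value_at(1800)

    def test_prewindow_hold(self, rep1):
        g = rep1["ctrl"]
        assert delayed_value(g, 100.0, 7200.0) == g.value_at(0)

    def test_step_shift(self):
        vals = np.full(T_END_S - T_START_S + 1, 2.0)
        vals[-T_START_S + 60 :] = 50.0  # rises at t=60s
        g = InputGrid(T_START_S, T_END_S, vals)
        assert delayed_value(g, 100.0, 60.0) == 2.0
        assert delayed_value(g, 121.0, 60.0) == 50.0

    def test_lookup_before_grid_rejected(self, rep1):
        with pytest.raises(ValueError):
            delayed_value(rep1["ctrl"], rep1["ctrl"].t_start_s, 1.0)


class TestSteadyState:
    def test_simple_closed_form(self):
        ps = ParamSet.create("simple", k_deg=1e-3, K_D=0.5, tau=0)
        ss = steady_state(ps, 2.0)
        assert ss["mrna"] == pytest.approx(0.5 / 1e-3)

    def test_simple_saturation_limit(self):
        ps = ParamSet.create("simple", k_deg=1e-3, K_D=999.0, tau=0)
        ss = steady_state(ps, 1e6)  # K_D * n0 >> 1
        assert ss["mrna"] == pytest.approx(1.0 / 1e-3, rel=1e-6)

    def test_cycle_low_drive_closed_promoter(self):
        ps = ParamSet.create(
            "cycle3", k_1=6.1e-5, k_2=0.01, k_deg=1e-3, K_D1=0.0011, K_D2=0.0011, tau=0
        )
        ss = steady_state(ps, 2.0)
        assert ss["C"] == pytest.approx(1.0, abs=1e-2)
        assert ss["A"] < 1e-3

    def test_cycle_equilibrium_against_long_integration(self, cycle_params):
        p = cycle_params.resolved()
        n0 = 2.0
        u1 = p["K_D1"] * n0 / (p["K_D1"] * n0 + 1)
        u2 = p["K_D2"] * n0 / (p["K_D2"] * n0 + 1)

        def rhs(_, y):
            o, a = y
            c = 1 - o - a
            return [
                p["k_1"] * u1 * c - (p["k_2"] * u2 + p["k_m1"]) * o + p["k_m2"] * a,
                p["k_2"] * u2 * o - p["k_m2"] * a
                - p["k_m3"] * p["K_D3"] * a / (p["K_D3"] * a + 1),
            ]

        sol = solve_ivp(rhs, (0, 5e6), [0.0, 0.0], rtol=1e-11, atol=1e-14, method="LSODA")
        ss = steady_state(cycle_params, n0)
        assert ss["O"] == pytest.approx(sol.y[0, -1], rel=1e-5, abs=1e-9)
        assert ss["A"] == pytest.approx(sol.y[1, -1], rel=1e-5, abs=1e-9)

    def test_derivatives_vanish_at_steady_state(self, cycle_params):
        ss = steady_state(cycle_params, 2.0)
        p = cycle_params.resolved()
        n0 = 2.0
        u1 = p["K_D1"] * n0 / (p["K_D1"] * n0 + 1)
        u2 = p["K_D2"] * n0 / (p["K_D2"] * n0 + 1)
        dO = p["k_1"] * u1 * ss["C"] - (p["k_2"] * u2 + p["k_m1"]) * ss["O"] + p["k_m2"] * ss["A"]
        dA = (p["k_2"] * u2 * ss["O"] - p["k_m2"] * ss["A"]
              - p["k_m3"] * p["K_D3"] * ss["A"] / (p["K_D3"] * ss["A"] + 1))
        assert abs(dO) <= 1e-9
        assert abs(dA) <= 1e-9

    def test_nonpositive_input_rejected(self, cycle_params):
        with pytest.raises(ValueError):
            steady_state(cycle_params, 0.0)


class TestSimulate:
    @pytest.mark.parametrize("model,free", [
        ("simple", dict(k_deg=1e-3, K_D=0.05, tau=600)),
        ("iffl", dict(k_deg=1e-3, K_D1=0.5, K_D2=0.005, tau=600)),
        ("cycle3", dict(k_1=2e-3, k_2=0.5, k_deg=1e-3, K_D1=0.05, K_D2=0.05, tau=600)),
        ("v4", dict(k_1=2e-3, k_2=0.5, k_deg=1e-3, K_D1=0.05, K_D2=0.05,
                    K_DTF2=0.005, tau=600)),
    ])
    def test_equilibrium_preserved_under_constant_input(self, model, free):
        ps = ParamSet.create(model, **free)
        res = simulate(ps, constant_grid(2.0))
        np.testing.assert_allclose(res.fold_change, 1.0, atol=1e-6)
        if res.states is not None:
            ss = steady_state(ps, 2.0)
            np.testing.assert_allclose(res.states[:, 2], ss["A"], rtol=1e-6, atol=1e-12)

    def test_simple_step_response_matches_closed_form(self):
        # step n0 -> n1 realized by steady-state initialisation at n0 under a
        # grid held at n1
        k_deg, K_D = 1e-3, 0.05
        n0, n1 = 2.0, 100.0
        ps = ParamSet.create("simple", k_deg=k_deg, K_D=K_D, tau=0.0)
        ss0 = steady_state(ps, n0)["mrna"]
        ss1 = steady_state(ps, n1)["mrna"]
        times = np.arange(0.0, 181.0, 5.0)
        res = simulate(ps, step_grid(n1), times, y0={"mrna": ss0})
        # the step acts from the simulation start (-60 min)
        expected = ss1 + (ss0 - ss1) * np.exp(-k_deg * (times * 60.0 + 3600.0))
        np.testing.assert_allclose(res.mrna, expected, rtol=1e-4)

    def test_iffl_without_competitor_equals_simple_h2(self, rep1):
        # K_D2 -> 0 removes the competitor term; h is overridden to match
        iffl = ParamSet(
            model_name="iffl",
            free=dict(k_deg=1e-3, K_D1=0.05, K_D2=0.0, tau=600.0),
            fixed=MODEL_SPECS["iffl"]["fixed"],
            bounds={**{k: v for k, v in MODEL_SPECS["iffl"]["bounds"].items()},
                    "K_D2": (0.0, 1000.0)},
        )
        simple = ParamSet(
            model_name="simple",
            free=dict(k_deg=1e-3, K_D=0.05, tau=600.0),
            fixed={"h": 2.0, "k_syn": 1.0},
            bounds=MODEL_SPECS["simple"]["bounds"],
        )
        for cond in ("ctrl", "siIkBa"):
            a = simulate(iffl, rep1[cond])
            b = simulate(simple, rep1[cond])
            np.testing.assert_allclose(a.fold_change, b.fold_change, atol=1e-6)

    def test_cycle3_states_shifted_input_equal_v4_states(self, rep1):
        # v4 state equations are the cycle3 equations driven by the delayed
        # input; with the mRNA coupling ignored the state trajectories agree
        tau = 600.0
        grid = rep1["ctrl"]
        shifted_values = np.concatenate([
            np.full(int(tau), grid.values[0]), grid.values[: -int(tau)]
        ])
        shifted = InputGrid(grid.t_start_s, grid.t_end_s, shifted_values)
        c3 = ParamSet.create("cycle3", k_1=2e-3, k_2=0.5, k_deg=1e-3,
                             K_D1=0.05, K_D2=0.05, tau=tau)
        v4 = ParamSet.create("v4", k_1=2e-3, k_2=0.5, k_deg=1e-3,
                             K_D1=0.05, K_D2=0.05, K_DTF2=0.005, tau=tau)
        res_c3 = simulate(c3, shifted, full_output=True)
        res_v4 = simulate(v4, grid, full_output=True)
        np.testing.assert_allclose(res_c3.states, res_v4.states, atol=1e-6)

    @pytest.mark.parametrize("model", ["cycle3", "v4"])
    def test_conservation_and_positivity_random_draws(self, model, rep1):
        rng = np.random.default_rng(42)
        spec = MODEL_SPECS[model]
        for _ in range(5):
            free = {}
            for nm in spec["free"]:
                lo, hi = spec["bounds"][nm]
                if nm == "tau":
                    free[nm] = rng.uniform(lo, hi)
                else:
                    free[nm] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            ps = ParamSet.create(model, **free)
            res = simulate(ps, rep1["ctrl"], full_output=True)
            np.testing.assert_allclose(res.states.sum(axis=1), 1.0, atol=1e-6)
            assert res.states.min() >= -1e-9
            assert res.mrna.min() >= -1e-9

    def test_states_match_reference_integrator(self, rep1, cycle_params):
        """Dual-route check: the package integrator vs scipy at tight tolerance."""
        grid = rep1["ctrl"]
        p = cycle_params.resolved()
        res = simulate(cycle_params, grid, full_output=True)
        n_post = grid.post_stim()
        ss = steady_state(cycle_params, grid.v0)

        def rhs(t, y):
            o, a = y
            x = min(max(t, 0.0), 10800.0)
            lo = int(np.floor(x))
            hi = min(lo + 1, 10800)
            nv = n_post[lo] * (1 - (x - lo)) + n_post[hi] * (x - lo)
            u1 = p["K_D1"] * nv / (p["K_D1"] * nv + 1)
            u2 = p["K_D2"] * nv / (p["K_D2"] * nv + 1)
            c = 1 - o - a
            return [
                p["k_1"] * u1 * c - (p["k_2"] * u2 + p["k_m1"]) * o + p["k_m2"] * a,
                p["k_2"] * u2 * o - p["k_m2"] * a
                - p["k_m3"] * p["K_D3"] * a / (p["K_D3"] * a + 1),
            ]

        eval_s = np.array([1800, 3600, 7200, 10800])
        sol = solve_ivp(rhs, (0, 10800), [ss["O"], ss["A"]], t_eval=eval_s,
                        rtol=1e-10, atol=1e-13, method="LSODA")
        ours = res.states[3600 + eval_s, 2]
        np.testing.assert_allclose(ours, sol.y[1], rtol=1e-3, atol=1e-10)

    def test_eval_grid_covers_simulation_window(self, rep1, cycle_params):
        res = simulate(cycle_params, rep1["ctrl"])
        assert res.eval_times[0] == 0.0
        assert res.eval_times[-1] == 180.0
        assert res.fold_change[0] == pytest.approx(1.0)


class TestSummaries:
    def test_mfi_is_max(self):
        assert mfi(np.array([1, 2.5, 4, 3])) == 4.0
        assert mfi(np.array([1.0])) == 1.0
        with pytest.raises(ValueError):
            mfi(np.array([]))

    def test_auc_trapezoid(self):
        assert auc(np.ones(13), np.arange(0, 181, 15)) == pytest.approx(180.0)
        assert auc(np.array([1.0, 3.0]), np.array([0.0, 15.0])) == pytest.approx(30.0)

    def test_auc_linearity(self):
        t = np.arange(0, 181, 15.0)
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 5, 13), rng.uniform(0, 5, 13)
        assert auc(a + b, t) == pytest.approx(auc(a, t) + auc(b, t))

    def test_auc_length_mismatch(self):
        with pytest.raises(ValueError):
            auc(np.ones(3), np.arange(4))

    def test_fold_change_scale_invariance(self, rep1, cycle_params):
        res = simulate(cycle_params, rep1["ctrl"])
        scaled = sim_fold_change(
            type(res)(
                model_name=res.model_name, condition=res.condition,
                eval_times=res.eval_times, mrna=res.mrna * 7.3,
                fold_change=res.fold_change, mfi=res.mfi, auc=res.auc,
                m_pre=res.m_pre,
            )
        )
        np.testing.assert_allclose(scaled.fold_change, res.fold_change)

    def test_fixed_competitor_delay_constant(self):
        assert TAU_TF_S == 7200.0
        assert MODEL_SPECS["iffl"]["fixed"]["tau_TF"] == 7200.0
        assert MODEL_SPECS["v4"]["fixed"]["tau_TF"] == 7200.0
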