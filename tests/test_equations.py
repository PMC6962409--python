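"""Model DSL parsing, rate curves and the exponential-Euler kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikesim as ss
from spikesim.models import COBAHH_EQUATIONS, COBAHH_PARAMETERS

from reference import rk4_cobahh


class TestParsing:
    def test_pure_decay_coefficients(self):
        eqs = ss.parse_model("dg/dt = -g/tau", {"tau": 5.0})
        a, b = eqs.linear_coefficients["g"]
        assert float(a) == 0.0
        assert float(b.subs({"tau": 5.0})) == pytest.approx(-0.2)

    def test_gating_equation_coefficients(self):
        eqs = ss.parse_model(
            "dx/dt = alpha*(1-x) - beta*x", {"alpha": 2.0, "beta": 3.0}
        )
        a, b = eqs.linear_coefficients["x"]
        subs = {"alpha": 2.0, "beta": 3.0}
        assert float(a.subs(subs)) == pytest.approx(2.0)
        assert float(b.subs(subs)) == pytest.approx(-5.0)

    def test_quadratic_rhs_rejected(self):
        with pytest.raises(ss.LinearityError):
            ss.parse_model("dx/dt = x*x", {})

    def test_unresolved_symbol_rejected(self):
        with pytest.raises(ss.UnresolvedSymbolError):
            ss.parse_model("dx/dt = -x/tau + drive", {"tau": 1.0})

    def test_malformed_line_rejected(self):
        with pytest.raises(ss.ModelSyntaxError):
            ss.parse_model("x = -x/tau", {"tau": 1.0})
        with pytest.raises(ss.ModelSyntaxError):
            ss.parse_model("dx/dt = (x", {})

    def test_input_terms_accepted(self):
        eqs = ss.parse_model("dv/dt = (-v + I)/tau", {"tau": 10.0}, input_terms=["I"])
        assert eqs.input_terms == ("I",)

    def test_cross_variable_dependence_allowed(self):
        # conditionally linear: each RHS is linear in its own variable only
        eqs = ss.parse_model(
            "dV/dt = -gNa*m*V\ndm/dt = alpha_m(V)*(1-m)", {"gNa": 1.0}
        )
        assert set(eqs.state_variables) == {"V", "m"}


class TestRateCurves:
    @pytest.mark.parametrize(
        "kind,v,expected",
        [
            ("alpha_h", -46.0, 0.128),  # exponent exactly 0
            ("beta_h", -23.0, 2.0),  # 4/(1+e^0)
            ("alpha_m", -50.0, 1.28),  # removable singularity: 0.32*4
            ("beta_m", -23.0, 1.4),  # removable singularity: 0.28*5
            ("alpha_n", -48.0, 0.16),  # removable singularity: 0.032*5
        ],
    )
    def test_special_values(self, kind, v, expected):
        assert ss.rate_curve(kind, v) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("kind,v0", [("alpha_m", -50.0), ("beta_m", -23.0), ("alpha_n", -48.0)])
    def test_singularities_are_removable(self, kind, v0):
        # limit value agrees with the formula evaluated just off the
        # singular point
        at = ss.rate_curve(kind, v0)
        for eps in (1e-6, -1e-6):
            assert ss.rate_curve(kind, v0 + eps) == pytest.approx(at, rel=1e-5)

    def test_finite_nonnegative_over_physiological_range(self):
        v = np.linspace(-100.0, 50.0, 3001)
        for kind in ("alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_n", "beta_n"):
            r = ss.rate_curve(kind, v)
            assert np.all(np.isfinite(r))
            assert np.all(r >= 0)

    def test_steady_state_gate(self):
        v = -65.0
        expected = ss.rate_curve("alpha_n", v) / (
            ss.rate_curve("alpha_n", v) + ss.rate_curve("beta_n", v)
        )
        assert ss.steady_state_gate("n", v) == pytest.approx(expected, rel=1e-14)
        for kind in ("m", "h", "n"):
            x = ss.steady_state_gate(kind, np.linspace(-100, 50, 301))
            assert np.all((0 <= x) & (x <= 1))


class TestKernel:
    def test_single_decay_step_is_exact(self):
        eqs = ss.parse_model("dg/dt = -g/tau", {"tau": 5.0})
        k = ss.build_exponential_euler_kernel(eqs, dt=0.1)
        out = k.advance({"g": 1.0}, 1)
        assert out["g"][0] == pytest.approx(math.exp(-0.02), rel=1e-15)

    def test_decay_exact_over_many_steps(self):
        # the scheme is exact for linear decay up to per-step roundoff:
        # after 1e4 steps the relative error stays below n*eps (~2e-12;
        # observed ~5e-14), ten orders of magnitude tighter than a
        # first-order non-exact scheme such as forward Euler (~0.2
        # relative at this dt/tau)
        eqs = ss.parse_model("dg/dt = -g/tau", {"tau": 5.0})
        k = ss.build_exponential_euler_kernel(eqs, dt=0.1)
        state = {"g": np.array([1.0])}
        n_steps = 10_000
        for _ in range(n_steps):
            k.step(state)
        exact = math.exp(-n_steps * 0.1 / 5.0)
        assert abs(state["g"][0] - exact) <= n_steps * np.finfo(float).eps * exact

    def test_gate_fixed_point_preserved(self):
        alpha, beta = 2.0, 3.0
        eqs = ss.parse_model("dx/dt = alpha*(1-x) - beta*x", {"alpha": alpha, "beta": beta})
        k = ss.build_exponential_euler_kernel(eqs, dt=0.1)
        xinf = alpha / (alpha + beta)
        out = k.advance({"x": xinf}, 50)
        assert out["x"][0] == pytest.approx(xinf, rel=1e-14)

    def test_leak_free_membrane_is_fixed_point(self):
        # with every conductance parameter zero the membrane equation has
        # zero net current: V stays exactly at its initial value
        params = dict(COBAHH_PARAMETERS, gL=0.0, gNa=0.0, gK=0.0)
        eqs = ss.parse_model(COBAHH_EQUATIONS, params)
        k = ss.build_exponential_euler_kernel(eqs, dt=0.1)
        state = {"V": -60.0, "m": 0.0, "h": 0.5, "n": 0.0, "gE": 0.0, "gI": 0.0}
        out = k.advance(state, 10)
        assert out["V"][0] == -60.0

    def test_b_zero_limit(self):
        # constant-rate accumulation: dx/dt = c has b = 0 exactly
        eqs = ss.parse_model("dx/dt = c", {"c": 2.5})
        k = ss.build_exponential_euler_kernel(eqs, dt=0.1)
        out = k.advance({"x": 0.0}, 10)
        assert out["x"][0] == pytest.approx(2.5, rel=1e-14)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        v=st.floats(-100.0, 50.0),
        x0=st.floats(0.0, 1.0),
        dt=st.floats(1e-3, 10.0),
    )
    def test_gates_stay_in_unit_interval(self, v, x0, dt):
        # the update is a convex combination of x and x_inf for any dt > 0
        alpha = ss.rate_curve("alpha_m", v)
        beta = ss.rate_curve("beta_m", v)
        eqs = ss.parse_model("dx/dt = alpha*(1-x) - beta*x", {"alpha": alpha, "beta": beta})
        k = ss.build_exponential_euler_kernel(eqs, dt=dt)
        out = k.advance({"x": x0}, 1)
        assert 0.0 <= out["x"][0] <= 1.0

    def test_converges_to_rk4_reference(self):
        # strongly driven single COBAHH neuron through one action
        # potential; the global error of the first-order scheme shrinks
        # about linearly in dt once the spike-phase error is below the
        # upstroke width
        v0 = -60.0
        s0 = [
            v0,
            ss.steady_state_gate("m", v0),
            ss.steady_state_gate("h", v0),
            ss.steady_state_gate("n", v0),
            100.0,
            0.0,
        ]
        duration = 8.0
        ref = rk4_cobahh(s0, 0.0002, duration)
        ref_v = np.array([s[0] for s in ref])
        eqs = ss.parse_model(COBAHH_EQUATIONS, COBAHH_PARAMETERS)
        names = ["V", "m", "h", "n", "gE", "gI"]
        errs = []
        for dt in (0.008, 0.004, 0.002):
            k = ss.build_exponential_euler_kernel(eqs, dt)
            state = {nm: np.array([s0[i]]) for i, nm in enumerate(names)}
            traj = [state["V"][0]]
            for _ in range(int(round(duration / dt))):
                k.step(state)
                traj.append(state["V"][0])
            stride = int(round(dt / 0.0002))
            errs.append(np.abs(np.array(traj) - ref_v[::stride]).max())
        assert errs[1] < 0.65 * errs[0]
        assert errs[2] < 0.65 * errs[1]

    def test_single_and_double_precision_agree_on_one_step(self):
        eqs = ss.parse_model(COBAHH_EQUATIONS, COBAHH_PARAMETERS)
        state = {"V": -55.0, "m": 0.1, "h": 0.6, "n": 0.3, "gE": 20.0, "gI": 100.0}
        out64 = ss.build_exponential_euler_kernel(eqs, 0.1, "double").advance(state, 1)
        out32 = ss.build_exponential_euler_kernel(eqs, 0.1, "single").advance(state, 1)
        for name in state:
            ref = out64[name][0]
            tol = 64 * np.finfo(np.float32).eps * max(1.0, abs(ref))
            assert abs(float(out32[name][0]) - ref) < tol
        assert out32["V"].dtype == np.float32
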