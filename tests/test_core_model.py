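"""Core-model equations: conservation, QSSA identities, Jacobians, steady
states, linearization, and parameter plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxclock.core_model import (
    ParameterSet,
    jacobian,
    linearized_rhs,
    qssa_active_fraction,
    rhs_full,
    rhs_reduced,
    steady_state,
    validate_physiology,
)

rates = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)
conc = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)
pos_conc = st.floats(min_value=1e-6, max_value=10.0, allow_nan=False)


def random_params(draw):
    return ParameterSet(
        p=draw(rates), a=draw(rates), b=draw(rates), d=draw(rates),
        e=draw(rates), q=draw(rates), T=draw(st.floats(0.1, 5.0)),
    )


params_st = st.builds(
    ParameterSet,
    p=rates, a=rates, b=rates, d=rates, e=rates, q=rates,
    T=st.floats(min_value=0.1, max_value=5.0),
)


class TestParameterSet:
    def test_defaults_match_reference_values(self):
        p = ParameterSet()
        assert (p.p, p.a, p.b, p.d, p.e, p.q, p.T) == (1.0, 1000.0, 2.0, 0.2, 0.1, 0.1, 1.0)

    @pytest.mark.parametrize("bad", [{"p": 0.0}, {"a": -1.0}, {"T": 0.0}, {"q": float("nan")}])
    def test_nonpositive_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            ParameterSet(**bad)

    @pytest.mark.parametrize("suffix", [".toml", ".yaml"])
    def test_config_roundtrip(self, tmp_path, suffix):
        p = ParameterSet(d=0.3, q=0.16)
        path = tmp_path / f"params{suffix}"
        p.to_file(path)
        assert ParameterSet.from_file(path) == p

    def test_unknown_config_keys_rejected(self, tmp_path):
        path = tmp_path / "params.toml"
        path.write_text("p = 1.0\nk_extra = 2.0\n")
        with pytest.raises(ValueError, match="unknown"):
            ParameterSet.from_file(path)


class TestRhs:
    def test_fresh_pool_without_oxidant(self):
        # fully active pool, no H2O2 anywhere: only production acts
        p = ParameterSet()
        dy = rhs_full([p.T, 0.0, 0.0, 0.0, 0.0], p)
        assert dy[2] == pytest.approx(p.p)
        assert dy[0] == 0.0 and dy[1] == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(params=params_st, A=conc, I=conc, D1=conc, D2=conc, R=conc)
    def test_pool_conservation_in_rhs(self, params, A, I, D1, D2, R):
        dy = rhs_full([A, I, D1, D2, R], params)
        assert dy[0] + dy[1] == pytest.approx(0.0, abs=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            rhs_full([1.0, -0.1, 0.0, 0.0, 0.0], ParameterSet())
        with pytest.raises(ValueError, match="negative"):
            rhs_reduced([-1e-3, 0.0, 0.0], ParameterSet())

    def test_reduced_no_oxidant_limit(self):
        p = ParameterSet()
        dy = rhs_reduced([0.0, 0.5, 0.5], p)
        assert dy[0] == pytest.approx(p.p)


class TestQssa:
    def test_limits(self):
        p = ParameterSet()
        assert qssa_active_fraction(0.0, 1.0, p) == pytest.approx(p.T)
        assert qssa_active_fraction(1.0, 0.0, p) == pytest.approx(0.0)

    def test_binding_balance_symmetry(self):
        # a*D1 == b*R -> half the pool is active
        p = ParameterSet()
        D1 = 0.01
        R = p.a * D1 / p.b
        assert qssa_active_fraction(D1, R, p) == pytest.approx(p.T / 2)

    def test_singular_point_returns_active_pool_with_warning(self):
        with pytest.warns(UserWarning, match="fully"):
            assert qssa_active_fraction(0.0, 0.0, ParameterSet()) == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(params=params_st, D1=pos_conc, R=pos_conc)
    def test_qssa_manifold_is_exact_nullcline_of_A(self, params, D1, R):
        # on the QSSA manifold the full model's dA/dt vanishes identically
        A = qssa_active_fraction(D1, R, params)
        dy = rhs_full([A, params.T - A, D1, 0.0, R], params)
        assert dy[0] == pytest.approx(0.0, abs=1e-9 * params.a * params.T)

    @settings(max_examples=50, derandomize=True)
    @given(params=params_st, D1=pos_conc, R=pos_conc)
    def test_reduced_removal_flux_matches_closed_form(self, params, D1, R):
        dy = rhs_reduced([D1, 0.0, R], params)
        flux = params.a * params.b * D1 * R * params.T / (params.b * R + params.a * D1)
        assert dy[0] == pytest.approx(params.p - flux - params.d * D1, rel=1e-12)


def _fd_jacobian(fun, y, h=1e-6):
    y = np.asarray(y, dtype=float)
    J = np.zeros((len(fun(y)), len(y)))
    for j in range(len(y)):
        step = h * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += step
        ym[j] -= step
        J[:, j] = (fun(yp) - fun(ym)) / (2 * step)
    return J


class TestJacobian:
    @pytest.mark.parametrize("model", ["reduced", "full"])
    def test_matches_finite_differences_at_random_states(self, model, rng):
        p = ParameterSet()
        n = 3 if model == "reduced" else 5
        fun = (lambda y: rhs_reduced(y, p)) if model == "reduced" else (lambda y: rhs_full(y, p))
        for _ in range(10):
            y = rng.uniform(0.05, 2.0, size=n)
            J = jacobian(y, p, model=model)
            Jfd = _fd_jacobian(fun, y)
            scale = np.abs(J).max()
            assert np.abs(J - Jfd).max() / scale < 1e-6

    def test_singular_point_rejected(self):
        with pytest.raises(ValueError):
            jacobian([0.0, 0.0, 0.0], ParameterSet(), model="reduced")

    def test_default_steady_state_is_unstable_focus(self):
        ss = steady_state(ParameterSet(), model="reduced")
        eig = ss.jacobian_eigenvalues
        lead = eig[np.argmax(eig.real)]
        assert not ss.stable
        assert lead.real > 0 and abs(lead.imag) > 0  # complex pair: Hopf-born cycle

    def test_stable_steady_state_below_onset(self):
        ss = steady_state(ParameterSet(d=0.01), model="reduced")
        assert ss.stable
        assert np.all(ss.jacobian_eigenvalues.real < 0)


class TestSteadyState:
    @settings(max_examples=40, derandomize=True)
    @given(params=params_st)
    def test_flux_chain_identity(self, params):
        # p = removal + d*D1*, and d*D1* = e*D2* = q*R* along the export chain
        ss = steady_state(params, model="reduced")
        D1, D2, R = ss.state
        assert params.d * D1 == pytest.approx(params.e * D2, rel=1e-9)
        assert params.d * D1 == pytest.approx(params.q * R, rel=1e-9)
        assert np.max(np.abs(rhs_reduced(ss.state, params))) < 1e-9

    def test_full_and_reduced_fixed_points_agree(self):
        p = ParameterSet()
        red = steady_state(p, model="reduced")
        full = steady_state(p, model="full")
        assert full["D1"] == pytest.approx(red["D1"], rel=1e-12)
        assert full["A"] + full["I"] == pytest.approx(p.T, rel=1e-12)


class TestLinearized:
    def test_tangency_at_fixed_point(self):
        p = ParameterSet()
        lin = linearized_rhs(p)
        ss = steady_state(p, model="reduced")
        np.testing.assert_allclose(
            lin.rhs(0.0, ss.state, p), rhs_reduced(ss.state, p), atol=1e-12
        )

    def test_linearized_jacobian_equals_nonlinear_jacobian_at_fixed_point(self):
        # first-order expansion preserves the spectrum at the expansion point
        p = ParameterSet()
        lin = linearized_rhs(p)
        ss = steady_state(p, model="reduced")
        np.testing.assert_allclose(
            lin.jac(0.0, ss.state, p), jacobian(ss.state, p, "reduced"), rtol=1e-12
        )

    def test_perturbation_decay_rate_matches_leading_eigenvalue(self):
        # in a stable regime the linear model relaxes at the leading eigenvalue rate
        from redoxclock.simulate import integrate

        p = ParameterSet(d=0.7)  # above the oscillatory window
        lin = linearized_rhs(p)
        ss = steady_state(p, model="reduced")
        lam = ss.leading_real_part
        assert lam < 0
        traj = integrate(lin, p, initial=ss.state * 1.05, t_end=400.0, dt_out=0.5)
        dev = np.linalg.norm(traj.states - ss.state[None, :], axis=1)
        window = (traj.times > 100) & (traj.times < 350) & (dev > 1e-12)
        slope = np.polyfit(traj.times[window], np.log(dev[window]), 1)[0]
        assert slope == pytest.approx(lam, rel=0.05)


class TestPhysiology:
    def test_default_parameters_pass_all_checks(self):
        assert all(c.ok for c in validate_physiology(ParameterSet()))

    def test_measured_srx_half_life(self):
        # q = 0.16/h corresponds to the measured 4-5 h Srx half-life
        checks = {c.name: c for c in validate_physiology(ParameterSet(q=0.16))}
        c = checks["Srx half-life 4-5 h"]
        assert c.ok and c.value == pytest.approx(np.log(2) / 0.16, rel=1e-12)

    def test_equal_oxidation_and_reduction_rates_fail(self):
        checks = {c.name: c for c in validate_physiology(ParameterSet(a=2.0, b=2.0, d=0.0002))}
        assert not checks["a/b ~ 1e3..1e4"].ok
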