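"""Right-hand sides, nondimensionalization, and exact Taylor coefficients."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumordyn import (
    ModelParams,
    OriginalParams,
    State,
    integrate_ode,
    nondimensionalize,
    rhs_dde,
    rhs_ode,
    taylor_coefficients,
    tumor_free,
)
from tumordyn.model import first_partials
from tumordyn.params import load_params, save_params

from conftest import random_params


class TestNondimensionalize:
    def test_identity_scaling(self):
        orig = OriginalParams(s=2.0, p=3.0, g=1.0, m=0.5, d=0.7, a=1.1, b=0.2, n=1.0)
        params, scale = nondimensionalize(orig)
        assert params == ModelParams(sigma=2.0, alpha=3.0, mu=0.5, delta=0.7, f=1.1, beta=0.2)
        assert scale == 1.0

    def test_direct_substitution(self):
        orig = OriginalParams(s=2.0, p=1.0, g=1.0, m=1.0, d=1.0, a=1.0, b=1.0, n=2.0)
        params, scale = nondimensionalize(orig)
        assert params.sigma == pytest.approx(1.0)
        assert params.mu == pytest.approx(0.5)
        assert scale == pytest.approx(2.0)

    def test_roundtrip_identities(self, rng):
        for _ in range(50):
            s, p, g, m, d, a, b, n = 10.0 ** rng.uniform(-2, 2, 8)
            orig = OriginalParams(s=s, p=p, g=g, m=m, d=d, a=a, b=b, n=n)
            mp, scale = nondimensionalize(orig)
            assert mp.mu * n == pytest.approx(m, rel=1e-14)
            assert mp.sigma * n * g * g == pytest.approx(s, rel=1e-14)
            assert mp.beta / g == pytest.approx(b, rel=1e-14)
            assert scale == pytest.approx(n * g, rel=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="sigma"):
            ModelParams(sigma=0.0, alpha=1, mu=1, delta=1, f=1, beta=1)
        with pytest.raises(ValueError, match="[.]n"):
            OriginalParams(s=1, p=1, g=1, m=1, d=1, a=1, b=1, n=-2)

    def test_dimensional_vs_nondimensional_simulation(self):
        """Integrating the dimensional model and rescaling matches the nondimensional run."""
        orig = OriginalParams(s=0.2, p=0.9, g=2.0, m=0.05, d=0.4, a=1.2, b=0.01, n=0.5)
        mp, scale = nondimensionalize(orig)

        from scipy.integrate import solve_ivp

        def dim_rhs(t, u):
            E, T = u
            return [
                orig.s + orig.p * E * T / (orig.g + T) - orig.m * E * T - orig.d * E,
                orig.a * T * (1 - orig.b * T) - orig.n * E * T,
            ]

        E0, T0 = 1.0, 3.0
        t_end_nd = 5.0
        sol = solve_ivp(dim_rhs, (0, t_end_nd / scale), [E0, T0], rtol=1e-10, atol=1e-12)
        traj = integrate_ode(mp, (E0 / orig.g, T0 / orig.g), t_end_nd, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            traj.final_state, np.array(sol.y[:, -1]) / orig.g, rtol=1e-6, atol=1e-9
        )


class TestRhs:
    def test_tumor_free_annihilates(self, kuz_params):
        eq = tumor_free(kuz_params)
        assert rhs_ode(kuz_params, eq.point) == (pytest.approx(0.0, abs=1e-15), 0.0)

    def test_reference_equilibrium_near_zero(self, kuz_params):
        r = rhs_ode(kuz_params, (1.6348, 0.366269))
        assert max(abs(v) for v in r) < 5e-4

    def test_origin_gives_influx_only(self, kuz_params):
        assert rhs_ode(kuz_params, (0.0, 0.0)) == (kuz_params.sigma, 0.0)

    def test_zero_delay_equivalence(self, rng):
        """rhs_dde with now == lagged equals rhs_ode exactly, over 1000 random draws."""
        for params in random_params(rng, 100):
            for _ in range(10):
                state = tuple(10.0 ** rng.uniform(-2, 2, 2))
                assert rhs_dde(params, state, state) == rhs_ode(params, state)

    @settings(max_examples=200, derandomize=True)
    @given(
        vals=st.lists(st.floats(1e-3, 10.0), min_size=6, max_size=6),
        state=st.tuples(st.floats(0.0, 100.0), st.floats(0.0, 100.0)),
    )
    def test_zero_delay_equivalence_property(self, vals, state):
        """Property form of the zero-delay reduction over the parameter box."""
        params = ModelParams(*vals)
        assert rhs_dde(params, state, state) == rhs_ode(params, state)

    def test_mu_zero_removes_delay_dependence(self, rng):
        params = ModelParams(sigma=1, alpha=1, mu=1e-300, delta=1, f=1, beta=1)
        out1 = rhs_dde(params, (1.0, 2.0), (5.0, 7.0))
        out2 = rhs_dde(params, (1.0, 2.0), (0.1, 0.3))
        assert out1 == pytest.approx(out2)

    def test_nonfinite_state_rejected(self, kuz_params):
        with pytest.raises(ValueError):
            rhs_ode(kuz_params, (np.nan, 1.0))
        with pytest.raises(ValueError):
            rhs_dde(kuz_params, (1.0, 1.0), (np.inf, 0.0))


class TestState:
    def test_tiny_negative_flagged_not_rejected(self):
        with pytest.warns(UserWarning):
            State(x=-1e-13, y=0.5)
        with pytest.raises(ValueError):
            State(x=-1e-6, y=0.5)


class TestTaylorCoefficients:
    def test_known_partials(self, kuz_params, kuz_equilibria):
        eq = kuz_equilibria[0]
        tc = taylor_coefficients(kuz_params, eq)
        p, y = kuz_params, eq.y_star
        # d2 f2 / dy2 = -2*f*beta from the logistic term
        assert tc.partial(1, (0, 2, 0, 0)) == pytest.approx(-2 * p.f * p.beta, rel=1e-12)
        # d2 f1 / dx dy (instantaneous) = alpha/(1+y*)^2
        assert tc.partial(0, (1, 1, 0, 0)) == pytest.approx(p.alpha / (1 + y) ** 2, rel=1e-12)
        # component 2 is quadratic: all third partials vanish
        assert np.all(tc.third[1] == 0.0)

    def test_delayed_argument_structure(self, kuz_params, kuz_equilibria):
        """Only the mixed (x_lag, y_lag) second partial of component 1 is nonzero: -mu."""
        tc = taylor_coefficients(kuz_params, kuz_equilibria[2])
        assert tc.partial(0, (0, 0, 1, 1)) == pytest.approx(-kuz_params.mu, rel=1e-14)
        lagged = tc.second[:, 2:, 2:].copy()
        lagged[0, 0, 1] = lagged[0, 1, 0] = 0.0
        assert np.all(lagged == 0.0)
        assert np.all(tc.second[1, 2:, :] == 0.0)
        assert np.all(tc.second[1, :, 2:] == 0.0)
        assert np.all(tc.third[:, 2:, 2:, 2:] == 0.0)
        # no mixed instantaneous/lagged second partials either
        assert np.all(tc.second[:, :2, 2:][1] == 0.0)

    def test_finite_difference_agreement(self, kuz_params, kuz_equilibria):
        """Every stored second/third partial matches a central finite difference.

        Checked at the smallest equilibrium, where both rhs components are
        O(1) and the difference quotients are not cancellation-limited.
        """
        eq = kuz_equilibria[0]
        tc = taylor_coefficients(kuz_params, eq)
        u0 = np.array([eq.x_star, eq.y_star, eq.x_star, eq.y_star])

        def f(u, c):
            return rhs_dde(kuz_params, u[:2], u[2:])[c]

        h = 1e-4
        for c in range(2):
            for i in range(4):
                for j in range(4):
                    e = np.eye(4)
                    fd = (
                        f(u0 + h * e[i] + h * e[j], c)
                        - f(u0 + h * e[i] - h * e[j], c)
                        - f(u0 - h * e[i] + h * e[j], c)
                        + f(u0 - h * e[i] - h * e[j], c)
                    ) / (4 * h * h)
                    assert tc.second[c, i, j] == pytest.approx(fd, rel=1e-5, abs=1e-7)

        # spot-check a third partial of component 1 by differencing the second tensor
        def second_at(u, c, i, j):
            e = np.eye(4)
            return (
                f(u + h * e[i] + h * e[j], c)
                - f(u + h * e[i] - h * e[j], c)
                - f(u - h * e[i] + h * e[j], c)
                + f(u - h * e[i] - h * e[j], c)
            ) / (4 * h * h)

        e = np.eye(4)
        fd3 = (second_at(u0 + h * e[1], 0, 0, 1) - second_at(u0 - h * e[1], 0, 0, 1)) / (2 * h)
        assert tc.third[0, 0, 1, 1] == pytest.approx(fd3, rel=1e-3, abs=1e-6)

    def test_rejects_non_equilibrium(self, kuz_params):
        with pytest.raises(ValueError, match="not an equilibrium"):
            taylor_coefficients(kuz_params, (1.0, 1.0))


def test_first_partials_match_finite_differences(kuz_params, rng):
    x, y = 0.7, 1.3
    J = first_partials(kuz_params, x, y)
    u0 = np.array([x, y, x, y])
    h = 1e-6
    e = np.eye(4)
    for c in range(2):
        for i in range(4):
            fd = (
                rhs_dde(kuz_params, (u0 + h * e[i])[:2], (u0 + h * e[i])[2:])[c]
                - rhs_dde(kuz_params, (u0 - h * e[i])[:2], (u0 - h * e[i])[2:])[c]
            ) / (2 * h)
            assert J[c, i] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def test_config_roundtrip(tmp_path, kuz_params):
    path = tmp_path / "params.yaml"
    save_params(kuz_params, path)
    loaded, scale = load_params(path)
    assert loaded == kuz_params
    assert scale == 1.0


def test_dimensional_config(tmp_path):
    path = tmp_path / "dim.yaml"
    path.write_text("s: 2\np: 3\ng: 1\nm: 0.5\nd: 0.7\na: 1.1\nb: 0.2\nn: 1\n")
    params, scale = load_params(path)
    assert params.sigma == pytest.approx(2.0)
    assert scale == pytest.approx(1.0)


def test_config_rejects_mixed_keys(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("sigma: 1\nalpha: 1\n")
    with pytest.raises(ValueError, match="config must contain"):
        load_params(path)
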