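"""Delay-dependent linear analysis: coefficients, crossings, transversality, oracle."""
import cmath
import math

import numpy as np
import pytest

from tumordyn import (
    ModelParams,
    char_coeffs,
    classify,
    critical_delays,
    critical_frequencies,
    delay_verdict,
    first_crossing_by_continuation,
    jacobian,
    linearization_split,
    positive_equilibria,
    rightmost_roots,
    transversality,
)
from tumordyn.delay import CharCoeffs, _theta
from tumordyn.scenarios import _stable_hopf_candidates, sample_regime

from conftest import random_params


def _splits(rng, n):
    out = []
    for params in random_params(rng, 10 * n):
        for eq in positive_equilibria(params):
            out.append((params, eq))
            if len(out) >= n:
                return out
    return out


class TestLinearizationSplit:
    def test_sum_equals_jacobian(self, rng):
        for params, eq in _splits(rng, 30):
            s = linearization_split(params, eq)
            np.testing.assert_allclose(s.J0 + s.J1, jacobian(params, eq), atol=1e-9)

    def test_delayed_block_structure(self, kuz_params, kuz_equilibria):
        eq = kuz_equilibria[2]
        s = linearization_split(kuz_params, eq)
        np.testing.assert_allclose(
            s.J1,
            [[-0.00311 * eq.y_star, -0.00311 * eq.x_star], [0.0, 0.0]],
            rtol=1e-12,
        )

    def test_mu_zero_limit(self):
        params = ModelParams(sigma=0.4, alpha=0.8, mu=1e-12, delta=0.3, f=1.5, beta=0.4)
        eqs = positive_equilibria(params)
        assert eqs
        s = linearization_split(params, eqs[0])
        assert np.max(np.abs(s.J1)) < 1e-9


class TestCharCoeffs:
    def test_published_closed_forms_for_B_and_D(self, rng):
        for params, eq in _splits(rng, 30):
            c = char_coeffs(linearization_split(params, eq))
            p, y = params, eq.y_star
            B_ref = p.f * p.beta * y - p.alpha * y / (1 + y) + p.delta
            assert c.B == pytest.approx(B_ref, rel=1e-10, abs=1e-12)
            assert c.D == pytest.approx(p.mu * y, rel=1e-12)
            E_ref = p.mu * y * (p.f * p.beta * y - eq.x_star)
            assert c.E == pytest.approx(E_ref, rel=1e-9, abs=1e-12)

    def test_tau_zero_reduction(self, rng):
        for params, eq in _splits(rng, 50):
            s = linearization_split(params, eq)
            c = char_coeffs(s)
            J = s.J0 + s.J1
            assert c.B + c.D == pytest.approx(-np.trace(J), abs=1e-9 * max(1, abs(np.trace(J))))
            assert c.C + c.E == pytest.approx(
                np.linalg.det(J), abs=1e-9 * max(1, abs(np.linalg.det(J)))
            )

    def test_determinant_expansion_oracle(self, rng):
        """The scalar characteristic form equals det(lambda*I - J0 - J1 e^(-lambda*tau))."""
        for params, eq in _splits(rng, 30):
            s = linearization_split(params, eq)
            c = char_coeffs(s)
            for _ in range(4):
                lam = complex(rng.normal(), rng.normal())
                tau = rng.uniform(0, 5)
                M = lam * np.eye(2) - s.J0 - s.J1 * cmath.exp(-lam * tau)
                det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
                scale = max(1.0, abs(det))
                assert abs(det - c.char(lam, tau)) < 1e-10 * scale


class TestCriticalFrequencies:
    def test_single_crossing_when_C2_below_E2(self, kuz_params, kuz_equilibria):
        c = char_coeffs(linearization_split(kuz_params, kuz_equilibria[2]))
        assert c.C**2 - c.E**2 < 0
        omegas, degenerate = critical_frequencies(c)
        assert len(omegas) == 1 and not degenerate

    def test_e1_empty(self, kuz_params, kuz_equilibria):
        c = char_coeffs(linearization_split(kuz_params, kuz_equilibria[0]))
        omegas, _ = critical_frequencies(c)
        assert omegas == ()

    def test_quartic_residual(self, rng):
        for params, eq in _splits(rng, 40):
            c = char_coeffs(linearization_split(params, eq))
            omegas, _ = critical_frequencies(c)
            for w in omegas:
                res = w**4 + (c.B**2 - 2 * c.C - c.D**2) * w**2 + (c.C**2 - c.E**2)
                assert abs(res) < 1e-10 * max(1.0, w**4)


SYNTH_TWO_OMEGA = CharCoeffs(B=0.1, C=1.0, D=1.5, E=0.8)  # both omega+ and omega- exist
SYNTH_DEGENERATE = CharCoeffs(B=1.0, C=1.0, D=1.0, E=0.0)  # double root of the quartic at w=1


class TestCriticalDelays:
    def test_crossing_residuals_and_trig_identity(self, kuz_params, kuz_equilibria):
        c = char_coeffs(linearization_split(kuz_params, kuz_equilibria[2]))
        cds = critical_delays(c, j_max=3)
        w = cds.omega_plus
        for tau in cds.tau_plus:
            assert abs(c.char(1j * w, tau)) < 1e-8
        th = _theta(c, w)
        den = c.E**2 + c.D**2 * w**2
        cth = (c.E * (w**2 - c.C) - c.D * c.B * w**2) / den
        sth = w * (c.D * (w**2 - c.C) + c.B * c.E) / den
        assert cth**2 + sth**2 == pytest.approx(1.0, abs=1e-8)
        assert list(cds.tau_plus) == sorted(cds.tau_plus)
        assert all(t >= 0 for t in cds.tau_plus)
        # consecutive thresholds are spaced by the period 2*pi/omega
        gaps = np.diff(cds.tau_plus)
        np.testing.assert_allclose(gaps, 2 * math.pi / w, rtol=1e-12)

    def test_two_branch_signs_alternate(self):
        cds = critical_delays(SYNTH_TWO_OMEGA, j_max=8)
        assert cds.omega_plus is not None and cds.omega_minus is not None
        assert cds.omega_plus > cds.omega_minus
        assert set(cds.transversality_plus) == {1}
        assert set(cds.transversality_minus) == {-1}
        # omega+ crossings recur faster than omega- ones, so instability wins eventually
        assert 2 * math.pi / cds.omega_plus < 2 * math.pi / cds.omega_minus
        # within a window ending at a minus-branch crossing, destabilizing events dominate
        T = cds.tau_minus[2]
        events = sorted(
            [(t, +1) for t in cds.tau_plus if t <= T]
            + [(t, -1) for t in cds.tau_minus if t <= T]
        )
        n = 0
        for _, s in events:
            n += 2 * s
            assert n >= 0  # roots cannot leave the right half plane before entering
        assert n > 0

    def test_degenerate_quartic_flagged(self):
        omegas, degenerate = critical_frequencies(SYNTH_DEGENERATE)
        assert degenerate and omegas == (1.0,)


class TestTransversality:
    def test_simple_crossing_destabilizes(self, kuz_params, kuz_equilibria):
        c = char_coeffs(linearization_split(kuz_params, kuz_equilibria[2]))
        cds = critical_delays(c, j_max=0)
        res = transversality(c, cds.omega_plus, cds.tau_plus[0])
        assert res.sign == 1 and not res.degenerate

    def test_finite_difference_bracket(self, kuz_params, kuz_equilibria):
        """The rightmost root's real part changes sign across tau0 as predicted."""
        eq = kuz_equilibria[2]
        c = char_coeffs(linearization_split(kuz_params, eq))
        cds = critical_delays(c, j_max=0)
        tau0 = cds.tau_plus[0]
        lo = max(r.real for r in rightmost_roots(kuz_params, eq, tau0 - 1e-3))
        hi = max(r.real for r in rightmost_roots(kuz_params, eq, tau0 + 1e-3))
        assert lo < 0 < hi

    def test_degenerate_double_root_branch(self):
        c = SYNTH_DEGENERATE
        omega = 1.0
        tau0 = _theta(c, omega) / omega
        assert abs(c.char(1j * omega, tau0)) < 1e-12
        res = transversality(c, omega, tau0)
        assert res.degenerate
        assert res.second_derivative is not None

    def test_rejects_non_crossing(self, kuz_params, kuz_equilibria):
        c = char_coeffs(linearization_split(kuz_params, kuz_equilibria[2]))
        with pytest.raises(ValueError, match="not a crossing"):
            transversality(c, 0.5, 0.5)


class TestRightmostRoots:
    def test_tau_zero_reduces_to_ode(self, kuz_params, kuz_equilibria):
        for eq in kuz_equilibria:
            roots = rightmost_roots(kuz_params, eq, 0.0, count=2)
            ref = sorted(classify(kuz_params, eq).eigenvalues, key=lambda z: -z.real)
            for a, b in zip(roots, ref):
                assert a == pytest.approx(b, rel=1e-8, abs=1e-10)

    def test_finds_imaginary_root_at_crossing(self, kuz_params, kuz_equilibria):
        eq = kuz_equilibria[2]
        c = char_coeffs(linearization_split(kuz_params, eq))
        cds = critical_delays(c, j_max=0)
        roots = rightmost_roots(kuz_params, eq, cds.tau_plus[0], count=4)
        assert min(abs(r - 1j * cds.omega_plus) for r in roots) < 1e-6

    def test_residuals(self, kuz_params, kuz_equilibria):
        eq = kuz_equilibria[0]
        c = char_coeffs(linearization_split(kuz_params, eq))
        for tau in (0.5, 2.0, 7.0):
            for r in rightmost_roots(kuz_params, eq, tau, count=5):
                assert abs(c.char(r, tau)) < 1e-10

    def test_e1_stable_for_all_sampled_tau(self, kuz_params, kuz_equilibria):
        for tau in (0.5, 1.0, 5.0, 10.0):
            roots = rightmost_roots(kuz_params, kuz_equilibria[0], tau, count=5)
            assert max(r.real for r in roots) < 0


class TestDelayVerdict:
    def test_kuznetsov_verdicts(self, kuz_params, kuz_equilibria):
        v1 = delay_verdict(kuz_params, kuz_equilibria[0])
        assert v1.verdict == "stable_all_tau"
        v2 = delay_verdict(kuz_params, kuz_equilibria[1])
        assert v2.verdict == "unstable_all_tau"
        v3 = delay_verdict(kuz_params, kuz_equilibria[2])
        assert v3.verdict == "hopf_at_tau0"
        assert v3.omega_minus is None
        assert v3.tau0 == pytest.approx(0.990969, rel=1e-4)
        assert v3.schedule[0][2] == 0  # stable below tau0
        assert v3.schedule[1][2] == 2  # one unstable pair above

    def test_tau_zero_consistency_with_ode(self, rng):
        for params, eq in _splits(rng, 20):
            v = delay_verdict(params, eq, j_max=0)
            ode_stable = classify(params, eq).is_stable
            first_interval = v.schedule[0] if v.schedule else (0, math.inf, 0)
            assert (first_interval[2] == 0) == ode_stable

    def test_oracle_equivalence_on_random_hopf_sets(self):
        """Closed-form tau0 matches the root-continuation oracle to 1e-6."""
        for seed in range(8):
            scen = sample_regime("hopf", seed=seed)
            eq = _stable_hopf_candidates(scen.params)[0]
            v = delay_verdict(scen.params, eq, j_max=0)
            tau0 = v.tau0
            assert tau0 is not None
            t_oracle = first_crossing_by_continuation(scen.params, eq, tau_max=1.5 * tau0, n_grid=30)
            assert t_oracle == pytest.approx(tau0, abs=1e-6)
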