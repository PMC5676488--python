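"""Center-manifold normal form at a Hopf point of the delayed system.

Following the standard Hassard-Kazarinoff-Wan reduction, time is rescaled by
the critical delay (t -> t/tau0) so the delay interval becomes [-1, 0] and
the critical eigenvalue is i*omega0*tau0.  The right/left eigenfunctions

    q(theta)  = (1, rho)^T  * exp(i*omega0*tau0*theta),    theta in [-1, 0]
    q*(s)     = Dn*(1, rho*) * exp(i*omega0*tau0*s),       s in [0, 1]

are normalized by the bilinear pairing <q*, q> = 1.  Expanding the
nonlinearity on the center manifold yields the coefficients g20, g11, g02,
g21 (the cubic one requiring the second-order manifold terms W20, W11 with
their constant vectors E1, E2), and finally::

    c1(0)  = i/(2*omega0*tau0) * (g20*g11 - 2|g11|^2 - |g02|^2/3) + g21/2
    mu2    = -Re c1(0) / Re lambda'(tau0)       (bifurcation direction)
    beta2  = 2 Re c1(0)                         (orbital stability)
    T2     = -(Im c1(0) + mu2 * Im lambda'(tau0)) / (omega0*tau0)

With Re lambda'(tau0) > 0: mu2 > 0 means periodic orbits exist for
tau > tau0, and beta2 < 0 means they are orbitally stable (the supercritical
case).  The period correction uses eps^2 = (tau - tau0)/mu2:
period ~ (2*pi/omega0) * (1 + T2*eps^2) in original (pre-rescaling) time.
"""
from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .delay import CharCoeffs, CROSSING_TOL, char_coeffs, critical_delays, linearization_split
from .equilibria import Equilibrium
from .model import TaylorCoeffs, taylor_coefficients
from .params import ModelParams

__all__ = [
    "HopfPoint",
    "EigenPair",
    "GCoeffs",
    "NormalFormResult",
    "hopf_point",
    "lambda_prime",
    "eigen_pair",
    "g_coeffs",
    "hopf_quantities",
    "normal_form_at",
]

RESIDUAL_TOL = 1e-10


class DegenerateHopfError(RuntimeError):
    pass


@dataclass(frozen=True)
class HopfPoint:
    """A Hopf bifurcation point: parameters, equilibrium, omega0, tau0, lambda'."""

    params: ModelParams
    equilibrium: Equilibrium
    omega0: float
    tau0: float
    lambda_prime: complex
    coeffs: CharCoeffs

    def __post_init__(self):
        resid = self.coeffs.residual(1j * self.omega0, self.tau0)
        if resid > CROSSING_TOL:
            raise ValueError(f"characteristic residual {resid:.2e} at the Hopf point")


def lambda_prime(coeffs: CharCoeffs, omega0: float, tau0: float) -> complex:
    """d(lambda)/d(tau) at the crossing lambda = i*omega0, by implicit differentiation."""
    lam = 1j * omega0
    e = cmath.exp(-lam * tau0)
    denom = 2 * lam + coeffs.B + (coeffs.D - tau0 * (coeffs.D * lam + coeffs.E)) * e
    if abs(denom) < 1e-12:
        raise DegenerateHopfError("vanishing denominator in lambda'(tau0)")
    return lam * (coeffs.D * lam + coeffs.E) * e / denom


def hopf_point(params: ModelParams, eq: Equilibrium, j: int = 0) -> HopfPoint:
    """Construct the Hopf point at the j-th critical delay of the omega+ branch."""
    coeffs = char_coeffs(linearization_split(params, eq))
    cds = critical_delays(coeffs, j_max=j)
    if cds.omega_plus is None:
        raise DegenerateHopfError("no crossing frequency: the equilibrium has no Hopf point")
    omega0 = cds.omega_plus
    tau0 = cds.tau_plus[j]
    lp = lambda_prime(coeffs, omega0, tau0)
    if abs(lp.real) < 1e-12:
        raise DegenerateHopfError("Re lambda'(tau0) = 0: degenerate (tangential) crossing")
    return HopfPoint(params=params, equilibrium=eq, omega0=omega0, tau0=tau0, lambda_prime=lp, coeffs=coeffs)


@dataclass(frozen=True)
class EigenPair:
    """Right/left critical eigenvectors and the pairing normalizer."""

    rho: complex
    rho_star: complex
    d_norm: complex
    q0: np.ndarray  # (1, rho)
    psi0: np.ndarray  # (1, rho_star)


def _pairing(psi0, a, phi0, b, tau0, J1) -> complex:
    """Bilinear pairing of exponential eigenfunctions psi(s)=psi0*e^(a*s), phi(theta)=phi0*e^(b*theta).

    <psi, phi> = conj(psi0).phi0 + tau0*e^(conj(a)) * conj(psi0).J1.phi0 * I
    where I = (1 - e^(-(conj(a)+b)))/(conj(a)+b)  (I = 1 in the resonant limit).
    """
    ac = np.conj(a)
    s = ac + b
    I = 1.0 if abs(s) < 1e-12 else (1.0 - cmath.exp(-s)) / s
    psic = np.conj(np.asarray(psi0))
    phi0 = np.asarray(phi0)
    return complex(psic @ phi0 + tau0 * cmath.exp(ac) * (psic @ J1 @ phi0) * I)


def eigen_pair(hp: HopfPoint) -> EigenPair:
    """Critical eigenvectors of the rescaled-time linearization, normalized.

    q0 = (1, rho) spans the null space of M(i*omega0) with
    M(lambda) = lambda*I - J0 - J1*exp(-lambda*tau0); psi0 = (1, rho*) is the
    corresponding left null vector of the conjugate problem.  The normalizer
    Dn enforces <q*, q> = 1 under the bilinear pairing; <q*, conj(q)> = 0
    then holds automatically and is asserted.
    """
    split = linearization_split(hp.params, hp.equilibrium)
    J0, J1 = split.J0, split.J1
    lam = 1j * hp.omega0
    M = lam * np.eye(2) - J0 - J1 * cmath.exp(-lam * hp.tau0)
    rho = -M[1, 0] / M[1, 1]
    q0 = np.array([1.0, rho])
    if np.linalg.norm(M @ q0) > 1e-8 * max(1.0, np.linalg.norm(M)):
        raise DegenerateHopfError("defective eigenstructure: right null-vector residual too large")
    # left null vector of conj(M): psi0^T (i*omega0*I + J0 + J1*e^{+i*omega0*tau0}) = 0
    N = lam * np.eye(2) + J0 + J1 * cmath.exp(lam * hp.tau0)
    rho_star = -N[0, 0] / N[1, 0]
    psi0 = np.array([1.0, rho_star])
    if np.linalg.norm(psi0 @ N) > 1e-8 * max(1.0, np.linalg.norm(N)):
        raise DegenerateHopfError("defective eigenstructure: left null-vector residual too large")

    w = hp.omega0 * hp.tau0
    raw = _pairing(psi0, 1j * w, q0, 1j * w, hp.tau0, J1)
    d_norm = 1.0 / np.conj(raw)  # q* carries Dn; <q*, q> = conj(Dn) * raw = 1
    psi0_n = d_norm * psi0
    assert abs(_pairing(psi0_n, 1j * w, q0, 1j * w, hp.tau0, J1) - 1.0) < RESIDUAL_TOL
    ortho = _pairing(psi0_n, 1j * w, np.conj(q0), -1j * w, hp.tau0, J1)
    assert abs(ortho) < RESIDUAL_TOL, f"biorthogonality violated: {ortho}"
    return EigenPair(rho=rho, rho_star=rho_star, d_norm=complex(d_norm), q0=q0, psi0=psi0)


@dataclass(frozen=True)
class GCoeffs:
    """Center-manifold expansion coefficients and the W-terms that feed g21.

    W20(theta) = a_q*q0*e^(i*w*theta) + a_qb*conj(q0)*e^(-i*w*theta) + E1*e^(2i*w*theta)
    W11(theta) = b_q*q0*e^(i*w*theta) + b_qb*conj(q0)*e^(-i*w*theta) + E2,
    with w = omega0*tau0.
    """

    g20: complex
    g11: complex
    g02: complex
    g21: complex
    E1: np.ndarray
    E2: np.ndarray
    W20_coeffs: dict = field(default_factory=dict)
    W11_coeffs: dict = field(default_factory=dict)


def g_coeffs(hp: HopfPoint, tc: TaylorCoeffs, pair: EigenPair) -> GCoeffs:
    """Quadratic and cubic normal-form coefficients from the exact Taylor tensors.

    The nonlinearity enters through the 4-argument direction vectors
    U = (q(0), q(-1)) = (1, rho, e^(-i*w), rho*e^(-i*w)); the constant
    vectors E1, E2 solve M(2i*omega0) E1 = B(U, U) and M(0) E2 = B(U, conj U)
    where M is the (unscaled-time) characteristic matrix.  All linear solves
    carry residual checks.
    """
    split = linearization_split(hp.params, hp.equilibrium)
    J0, J1 = split.J0, split.J1
    w = hp.omega0 * hp.tau0
    tau0 = hp.tau0
    ew = cmath.exp(-1j * w)
    U = np.array([1.0, pair.rho, ew, pair.rho * ew])
    Ub = np.conj(U)
    wbar = np.conj(pair.d_norm) * np.conj(pair.psi0)  # conj(q*(0)) row vector

    BUU = tc.bilinear(U, U)
    BUUb = tc.bilinear(U, Ub)
    BUbUb = tc.bilinear(Ub, Ub)
    g20 = complex(tau0 * (wbar @ BUU))
    g11 = complex(tau0 * (wbar @ BUUb))
    g02 = complex(tau0 * (wbar @ BUbUb))

    def char_matrix(lam: complex) -> np.ndarray:
        return lam * np.eye(2) - J0 - J1 * cmath.exp(-lam * tau0)

    M2 = char_matrix(2j * hp.omega0)
    E1 = np.linalg.solve(M2, BUU)
    if np.linalg.norm(M2 @ E1 - BUU) > RESIDUAL_TOL * max(1.0, np.linalg.norm(BUU)):
        raise DegenerateHopfError("E1 linear solve residual too large")
    M0 = char_matrix(0.0)
    if abs(np.linalg.det(M0)) < 1e-14:
        raise DegenerateHopfError("characteristic matrix singular at 0: degenerate Hopf")
    E2 = np.linalg.solve(M0, BUUb)
    if np.linalg.norm(M0 @ E2 - BUUb) > RESIDUAL_TOL * max(1.0, np.linalg.norm(BUUb)):
        raise DegenerateHopfError("E2 linear solve residual too large")

    q0, q0b = pair.q0, np.conj(pair.q0)
    a_q = 1j * g20 / w
    a_qb = 1j * np.conj(g02) / (3.0 * w)
    b_q = -1j * g11 / w
    b_qb = 1j * np.conj(g11) / w

    def w20_at(theta: float) -> np.ndarray:
        return (
            a_q * q0 * cmath.exp(1j * w * theta)
            + a_qb * q0b * cmath.exp(-1j * w * theta)
            + E1 * cmath.exp(2j * w * theta)
        )

    def w11_at(theta: float) -> np.ndarray:
        return b_q * q0 * cmath.exp(1j * w * theta) + b_qb * q0b * cmath.exp(-1j * w * theta) + E2

    W20v = np.concatenate([w20_at(0.0), w20_at(-1.0)])
    W11v = np.concatenate([w11_at(0.0), w11_at(-1.0)])
    g21 = complex(
        tau0 * (wbar @ (2.0 * tc.bilinear(U, W11v) + tc.bilinear(Ub, W20v) + tc.trilinear(U, U, Ub)))
    )
    return GCoeffs(
        g20=g20,
        g11=g11,
        g02=g02,
        g21=g21,
        E1=E1,
        E2=E2,
        W20_coeffs={"a_q": a_q, "a_qbar": a_qb, "E1": E1},
        W11_coeffs={"b_q": b_q, "b_qbar": b_qb, "E2": E2},
    )


@dataclass(frozen=True)
class NormalFormResult:
    rho: complex
    rho_star: complex
    d_norm: complex
    g20: complex
    g11: complex
    g02: complex
    g21: complex
    W20_coeffs: dict
    W11_coeffs: dict
    c1_0: complex
    mu2: float
    beta2: float
    T2: float
    direction: str  # side of tau0 bearing the periodic orbits
    orbit_stability: str
    period_estimate: float  # leading-order period 2*pi/omega0 in original time
    epsilon_convention: str = "eps^2 = (tau - tau0)/mu2; period ~ (2*pi/omega0)*(1 + T2*eps^2)"

    @property
    def classification(self) -> str:
        return "supercritical" if self.orbit_stability == "stable" else "subcritical"


def hopf_quantities(g: GCoeffs, hp: HopfPoint, pair: EigenPair) -> NormalFormResult:
    """Assemble c1(0), mu2, beta2, T2 and the Hopf classification."""
    if abs(hp.lambda_prime.real) < 1e-12:
        raise DegenerateHopfError("Re lambda'(tau0) = 0")
    w = hp.omega0 * hp.tau0
    c1 = (1j / (2.0 * w)) * (g.g20 * g.g11 - 2.0 * abs(g.g11) ** 2 - abs(g.g02) ** 2 / 3.0) + g.g21 / 2.0
    mu2 = -c1.real / hp.lambda_prime.real
    beta2 = 2.0 * c1.real
    T2 = -(c1.imag + mu2 * hp.lambda_prime.imag) / w
    direction = "tau > tau0" if mu2 > 0 else "tau < tau0"
    stability = "stable" if beta2 < 0 else "unstable"
    return NormalFormResult(
        rho=pair.rho,
        rho_star=pair.rho_star,
        d_norm=pair.d_norm,
        g20=g.g20,
        g11=g.g11,
        g02=g.g02,
        g21=g.g21,
        W20_coeffs=g.W20_coeffs,
        W11_coeffs=g.W11_coeffs,
        c1_0=c1,
        mu2=mu2,
        beta2=beta2,
        T2=T2,
        direction=direction,
        orbit_stability=stability,
        period_estimate=2.0 * math.pi / hp.omega0,
    )


def normal_form_at(params: ModelParams, eq: Equilibrium, j: int = 0) -> NormalFormResult:
    """One-call normal form at the j-th Hopf point of a positive equilibrium."""
    hp = hopf_point(params, eq, j=j)
    pair = eigen_pair(hp)
    tc = taylor_coefficients(params, eq)
    g = g_coeffs(hp, tc, pair)
    return hopf_quantities(g, hp, pair)
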