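"""Delay-dependent linear analysis at a positive equilibrium.

Splitting the linearization into an instantaneous part J0 and a delayed part
J1 (nonzero only in its first row, from the -mu*x(t-tau)*y(t-tau) term), the
characteristic equation of the delayed linearization is transcendental::

    lambda^2 + B*lambda + C + (D*lambda + E) * exp(-lambda*tau) = 0

with B = -tr(J0), C = det(J0), D = mu*y*, E = mu*y*(f*beta*y* - x*).
Purely imaginary roots lambda = i*omega require omega^2 to solve the quartic

    w^2 + (B^2 - 2C - D^2) w + (C^2 - E^2) = 0,   w = omega^2,

and each admissible omega yields an arithmetic progression of critical delays
tau_j = (theta + 2*pi*j)/omega where theta is recovered branch-safely via
atan2 from the exact (sin, cos) pair.  Transversality is evaluated from the
full implicit derivative d(lambda)/d(tau), with a root-tracking second
derivative in the degenerate case.

An independent pseudospectral (Chebyshev collocation) discretization of the
delay linearization, Newton-refined on the analytic characteristic function,
serves as the rightmost-root oracle that cross-validates every closed-form
crossing.
"""
from __future__ import annotations

import cmath
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .equilibria import Equilibrium
from .model import EQ_RESIDUAL_TOL
from .params import ModelParams
from .stability import eigenvalues_2x2

__all__ = [
    "LinearizationSplit",
    "CharCoeffs",
    "CriticalDelaySet",
    "TransversalityResult",
    "linearization_split",
    "char_coeffs",
    "critical_frequencies",
    "critical_delays",
    "transversality",
    "rightmost_roots",
    "first_crossing_by_continuation",
    "delay_verdict",
]

log = logging.getLogger(__name__)

CROSSING_TOL = 1e-8  # characteristic residual accepted for a reported crossing
DEGENERATE_TOL = 1e-10  # |Re dlambda/dtau| below this triggers the 2nd-derivative path


class DelayAnalysisError(RuntimeError):
    """Raised when the spectral oracle fails to converge; carries diagnostics."""

    def __init__(self, msg, spectrum=None):
        super().__init__(msg)
        self.spectrum = spectrum


@dataclass(frozen=True)
class LinearizationSplit:
    """Instantaneous (J0) and delayed (J1) parts of the linearization."""

    J0: np.ndarray
    J1: np.ndarray


@dataclass(frozen=True)
class CharCoeffs:
    """Coefficients of lambda^2 + B*lambda + C + (D*lambda + E)e^(-lambda*tau)."""

    B: float
    C: float
    D: float
    E: float

    def char(self, lam: complex, tau: float) -> complex:
        return lam * lam + self.B * lam + self.C + (self.D * lam + self.E) * cmath.exp(-lam * tau)

    def scale(self, lam: complex) -> float:
        """Natural magnitude of the characteristic terms (for relative residuals)."""
        a = abs(lam)
        return a * a + abs(self.B) * a + abs(self.C) + abs(self.D) * a + abs(self.E)

    def residual(self, lam: complex, tau: float) -> float:
        """|char| normalized by the term magnitudes (equals |char| at scale <= 1)."""
        return abs(self.char(lam, tau)) / max(1.0, self.scale(lam))

    def char_dlambda(self, lam: complex, tau: float) -> complex:
        e = cmath.exp(-lam * tau)
        return 2 * lam + self.B + (self.D - tau * (self.D * lam + self.E)) * e


@dataclass(frozen=True)
class TransversalityResult:
    sign: int
    dlambda_dtau: complex
    degenerate: bool
    second_derivative: Optional[float] = None


@dataclass(frozen=True)
class CriticalDelaySet:
    """Crossing frequencies, delay thresholds, transversality, and the verdict."""

    omega_plus: Optional[float]
    omega_minus: Optional[float]
    tau_plus: tuple = ()
    tau_minus: tuple = ()
    transversality_plus: tuple = ()
    transversality_minus: tuple = ()
    verdict: str = "stable_all_tau"
    schedule: tuple = ()  # (tau_lo, tau_hi, n_unstable_roots) intervals
    degenerate_frequency: bool = False

    @property
    def tau0(self) -> Optional[float]:
        taus = [t for t in (*self.tau_plus, *self.tau_minus)]
        return min(taus) if taus else None


def linearization_split(params: ModelParams, eq: Equilibrium) -> LinearizationSplit:
    """J0 from the instantaneous terms, J1 = [[-mu*y*, -mu*x*], [0, 0]]."""
    if eq.kind != "positive":
        raise ValueError("delay analysis applies to positive equilibria")
    if eq.residual > EQ_RESIDUAL_TOL:
        raise ValueError(f"equilibrium residual {eq.residual:.2e} exceeds {EQ_RESIDUAL_TOL:.1e}")
    p = params
    x, y = eq.x_star, eq.y_star
    J0 = np.array(
        [
            [p.alpha * y / (1.0 + y) - p.delta, p.alpha * x / (1.0 + y) ** 2],
            [-y, -p.f * p.beta * y],
        ]
    )
    J1 = np.array([[-p.mu * y, -p.mu * x], [0.0, 0.0]])
    return LinearizationSplit(J0=J0, J1=J1)


def char_coeffs(split: LinearizationSplit) -> CharCoeffs:
    """B = -tr(J0), C = det(J0), D = -tr(J1), E from the 2x2 cross expansion.

    E is fixed by requiring det(lambda*I - J0 - J1*e^(-lambda*tau)) to equal
    the scalar form identically; for this J1 (first row only) that gives
    E = J1[0,0]*J0[1,1] - J1[0,1]*J0[1,0] = mu*y*(f*beta*y* - x*).
    """
    J0, J1 = split.J0, split.J1
    return CharCoeffs(
        B=-np.trace(J0),
        C=float(np.linalg.det(J0)),
        D=-np.trace(J1),
        E=float(J1[0, 0] * J0[1, 1] - J1[0, 1] * J0[1, 0]),
    )


def critical_frequencies(coeffs: CharCoeffs) -> tuple[tuple[float, ...], bool]:
    """Positive crossing frequencies (omega_plus first), plus a degeneracy flag.

    Solves w^2 + (B^2 - 2C - D^2) w + (C^2 - E^2) = 0 for w = omega^2 and
    keeps the real positive roots; the flag marks a double root of the
    quartic (tangential crossing).
    """
    c = coeffs
    p = c.D * c.D - c.B * c.B + 2.0 * c.C  # = -(B^2 - 2C - D^2)
    q = c.C * c.C - c.E * c.E
    disc = p * p - 4.0 * q
    if disc < 0:
        return (), False
    if disc == 0.0:
        w = p / 2.0
        return ((math.sqrt(w),), True) if w > 0 else ((), False)
    root = math.sqrt(disc)
    omegas = []
    for w in ((p + root) / 2.0, (p - root) / 2.0):
        if w > 0:
            omegas.append(math.sqrt(w))
    return tuple(omegas), False


def _theta(coeffs: CharCoeffs, omega: float) -> float:
    """Crossing phase in [0, 2*pi) recovered from the exact (sin, cos) pair."""
    c = coeffs
    w2 = omega * omega
    den = c.E * c.E + c.D * c.D * w2
    cth = (c.E * (w2 - c.C) - c.D * c.B * w2) / den
    sth = omega * (c.D * (w2 - c.C) + c.B * c.E) / den
    return math.atan2(sth, cth) % (2.0 * math.pi)


def transversality(coeffs: CharCoeffs, omega: float, tau: float) -> TransversalityResult:
    """Sign of d(Re lambda)/d(tau) at a crossing via implicit differentiation.

    d(lambda)/d(tau) = lambda*(D*lambda + E)*e^(-lambda*tau) /
                       (2*lambda + B + (D - tau*(D*lambda + E))*e^(-lambda*tau)).

    When the first derivative's real part is below 1e-10 the crossing is
    tangential and the sign of the second derivative of Re(lambda), obtained
    by Newton root-tracking across tau, is reported instead.
    """
    lam = 1j * omega
    resid = coeffs.residual(lam, tau)
    if resid > CROSSING_TOL:
        raise ValueError(f"({omega}, {tau}) is not a crossing: residual {resid:.2e}")
    e = cmath.exp(-lam * tau)
    denom = coeffs.char_dlambda(lam, tau)
    if abs(denom) < 1e-14:
        raise DelayAnalysisError("characteristic derivative vanishes at the crossing")
    dl = lam * (coeffs.D * lam + coeffs.E) * e / denom

    # consistency check against the quartic-discriminant sign shortcut
    p = coeffs.D**2 - coeffs.B**2 + 2 * coeffs.C
    disc = p * p - 4 * (coeffs.C**2 - coeffs.E**2)
    if disc > 0:
        w2 = omega * omega
        shortcut = 1 if abs(w2 - (p + math.sqrt(disc)) / 2) < abs(w2 - (p - math.sqrt(disc)) / 2) else -1
        if dl.real != 0 and shortcut != int(math.copysign(1, dl.real)):
            log.info(
                "transversality shortcut sign %+d disagrees with implicit derivative %+.3e",
                shortcut,
                dl.real,
            )

    if abs(dl.real) >= DEGENERATE_TOL:
        return TransversalityResult(sign=int(math.copysign(1, dl.real)), dlambda_dtau=dl, degenerate=False)

    # tangential crossing: track the root through tau and difference Re(lambda)
    h = 1e-4 * max(1.0, tau)
    re = []
    for t in (tau - h, tau, tau + h):
        re.append(_track_root(coeffs, lam, t).real)
    second = (re[0] - 2 * re[1] + re[2]) / (h * h)
    sgn = 0 if abs(second) < 1e-8 else int(math.copysign(1, second))
    return TransversalityResult(sign=sgn, dlambda_dtau=dl, degenerate=True, second_derivative=second)


def _track_root(coeffs: CharCoeffs, lam0: complex, tau: float, tol: float = 1e-13) -> complex:
    """Newton-continue a characteristic root to the given tau."""
    lam = lam0
    for _ in range(60):
        f = coeffs.char(lam, tau)
        if abs(f) < tol * max(1.0, coeffs.scale(lam)):
            return lam
        df = coeffs.char_dlambda(lam, tau)
        if abs(df) < 1e-14 * max(1.0, coeffs.scale(lam)):
            break
        lam -= f / df
    if coeffs.residual(lam, tau) > 1e-9:
        raise DelayAnalysisError(f"root tracking failed at tau={tau}")
    return lam


def critical_delays(coeffs: CharCoeffs, j_max: int = 3) -> CriticalDelaySet:
    """Enumerate the critical delays tau_j = (theta + 2*pi*j)/omega, j <= j_max."""
    if j_max < 0:
        raise ValueError("j_max must be >= 0")
    omegas, degenerate = critical_frequencies(coeffs)
    if not omegas:
        return CriticalDelaySet(omega_plus=None, omega_minus=None, verdict="stable_all_tau")

    def taus_for(omega):
        th = _theta(coeffs, omega)
        taus = tuple((th + 2.0 * math.pi * j) / omega for j in range(j_max + 1))
        trans = tuple(transversality(coeffs, omega, t) for t in taus)
        for t in taus:
            r = coeffs.residual(1j * omega, t)
            if r > CROSSING_TOL:
                raise DelayAnalysisError(f"crossing residual {r:.2e} at omega={omega}, tau={t}")
        return taus, tuple(tr.sign for tr in trans)

    om_p = omegas[0]
    tau_p, sg_p = taus_for(om_p)
    om_m = omegas[1] if len(omegas) > 1 else None
    tau_m, sg_m = taus_for(om_m) if om_m is not None else ((), ())
    return CriticalDelaySet(
        omega_plus=om_p,
        omega_minus=om_m,
        tau_plus=tau_p,
        tau_minus=tau_m,
        transversality_plus=sg_p,
        transversality_minus=sg_m,
        verdict="pending",
        degenerate_frequency=degenerate,
    )


# --- pseudospectral rightmost-root oracle -----------------------------------


def _cheb(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev points on [-1, 1] and the differentiation matrix (Trefethen)."""
    if n == 0:
        return np.zeros((1, 1)), np.array([1.0])
    x = np.cos(np.pi * np.arange(n + 1) / n)
    c = np.hstack([2.0, np.ones(n - 1), 2.0]) * (-1.0) ** np.arange(n + 1)
    X = np.tile(x, (n + 1, 1)).T
    dX = X - X.T
    D = np.outer(c, 1.0 / c) / (dX + np.eye(n + 1))
    D -= np.diag(D.sum(axis=1))
    return D, x


def rightmost_roots(
    params: ModelParams,
    eq: Equilibrium,
    tau: float,
    count: int = 6,
    n_cheb: Optional[int] = None,
) -> list[complex]:
    """Rightmost characteristic roots of the delay linearization.

    Chebyshev collocation of the linear DDE on [-tau, 0] yields a matrix
    whose spectrum approximates the characteristic roots; the leading
    approximations are Newton-refined on the analytic characteristic function
    and deduplicated.  Each returned root has residual < 1e-10.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    split = linearization_split(params, eq)
    if tau == 0:
        return sorted(
            eigenvalues_2x2(split.J0 + split.J1), key=lambda z: -z.real
        )[:count]
    coeffs = char_coeffs(split)
    n = n_cheb or min(128, max(24, int(6 * tau) + 16))
    Dm, _ = _cheb(n)
    Dm = Dm * (2.0 / tau)  # rescale from [-1, 1] to [-tau, 0]
    A = np.kron(Dm, np.eye(2))
    A[0:2, :] = 0.0
    A[0:2, 0:2] = split.J0  # collocation node x[0] = +1 maps to theta = 0
    A[0:2, 2 * n : 2 * n + 2] = split.J1  # node x[n] = -1 maps to theta = -tau
    spec = np.linalg.eigvals(A)
    spec = spec[np.argsort(-spec.real)]

    refined: list[complex] = []
    for lam in spec:
        if len(refined) >= count + 4:
            break
        try:
            root = _track_root(coeffs, complex(lam), tau, tol=1e-12)
        except DelayAnalysisError:
            continue
        if coeffs.residual(root, tau) > 1e-10:
            continue
        if any(abs(root - r) < 1e-7 * max(1.0, abs(root)) for r in refined):
            continue
        if any(abs(root - r.conjugate()) < 1e-7 * max(1.0, abs(root)) for r in refined):
            refined.append(root)  # keep both members of a conjugate pair
            continue
        refined.append(root)
    if not refined:
        raise DelayAnalysisError("no characteristic roots could be refined", spectrum=spec)
    refined.sort(key=lambda z: -z.real)
    return refined[:count]


def first_crossing_by_continuation(
    params: ModelParams,
    eq: Equilibrium,
    tau_max: float,
    n_grid: int = 60,
) -> Optional[float]:
    """Independent oracle: first tau where the rightmost root crosses Re = 0.

    Scans a tau grid with the pseudospectral spectrum and refines the first
    sign change of the rightmost real part by bisection (brentq).  Returns
    None if no crossing occurs below tau_max.
    """

    def rightmost_re(tau: float) -> float:
        return max(r.real for r in rightmost_roots(params, eq, tau, count=4))

    grid = np.linspace(0.0, tau_max, n_grid + 1)
    prev_t, prev_v = grid[0], rightmost_re(grid[0])
    for t in grid[1:]:
        v = rightmost_re(float(t))
        if prev_v < 0.0 <= v or prev_v <= 0.0 < v:
            return float(brentq(rightmost_re, prev_t, float(t), xtol=1e-10, rtol=1e-12))
        prev_t, prev_v = float(t), v
    return None


def delay_verdict(params: ModelParams, eq: Equilibrium, j_max: int = 3) -> CriticalDelaySet:
    """Full delay-stability schedule at a positive equilibrium.

    Starts from the tau = 0 root count, enumerates crossings, and accumulates
    the number of right-half-plane roots across the sorted critical delays
    (each crossing moves a conjugate pair in the direction of its
    transversality sign).  A negative determinant of the full Jacobian
    (C + E < 0) pins a real positive root for every tau, so the equilibrium
    is then unstable for all delays.
    """
    split = linearization_split(params, eq)
    coeffs = char_coeffs(split)
    lam0 = eigenvalues_2x2(split.J0 + split.J1)
    n0 = sum(1 for z in lam0 if z.real > 0)

    base = critical_delays(coeffs, j_max)
    if coeffs.C + coeffs.E < 0:
        # det(J) < 0: one real root stays in the right half plane for all tau
        return CriticalDelaySet(
            omega_plus=base.omega_plus,
            omega_minus=base.omega_minus,
            tau_plus=base.tau_plus,
            tau_minus=base.tau_minus,
            transversality_plus=base.transversality_plus,
            transversality_minus=base.transversality_minus,
            verdict="unstable_all_tau",
            schedule=((0.0, math.inf, max(n0, 1)),),
        )
    if base.omega_plus is None:
        verdict = "stable_all_tau" if n0 == 0 else "unstable_all_tau"
        return CriticalDelaySet(
            omega_plus=None,
            omega_minus=None,
            verdict=verdict,
            schedule=((0.0, math.inf, n0),),
        )

    events = [(t, s) for t, s in zip(base.tau_plus, base.transversality_plus)]
    events += [(t, s) for t, s in zip(base.tau_minus, base.transversality_minus)]
    events.sort()
    schedule = []
    n = n0
    lo = 0.0
    for t, s in events:
        schedule.append((lo, t, n))
        n += 2 * s
        lo = t
    schedule.append((lo, math.inf, n))

    if base.omega_minus is None:
        verdict = "hopf_at_tau0" if n0 == 0 else "unstable_all_tau"
    else:
        verdict = "finite_switches"
    return CriticalDelaySet(
        omega_plus=base.omega_plus,
        omega_minus=base.omega_minus,
        tau_plus=base.tau_plus,
        tau_minus=base.tau_minus,
        transversality_plus=base.transversality_plus,
        transversality_minus=base.transversality_minus,
        verdict=verdict,
        schedule=tuple(schedule),
        degenerate_frequency=base.degenerate_frequency,
    )
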