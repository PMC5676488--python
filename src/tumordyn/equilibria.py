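"""Equilibria of the non-delayed system.

The tumor-free steady state is (sigma/delta, 0).  Positive equilibria satisfy
x* = f(1 - beta*y*) together with the effector balance; eliminating x reduces
the problem to a cubic in y::

    a1*y^3 + a2*y^2 + a3*y + a4 = 0

with a1 = f*beta*mu, a2 = f*(-alpha*beta + beta*delta - mu + beta*mu),
a3 = f*alpha - f*delta + f*beta*delta - f*mu + sigma, a4 = sigma - f*delta.

Roots are found via the companion matrix (robust near double roots) and then
Newton-polished on the original two-dimensional equilibrium system.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import EQ_RESIDUAL_TOL, first_partials, rhs_ode
from .params import ModelParams

__all__ = [
    "CubicCoeffs",
    "Equilibrium",
    "RegimeReport",
    "tumor_free",
    "cubic_coefficients",
    "positive_equilibria",
    "regime_report",
]

log = logging.getLogger(__name__)

#: roots with a coordinate below this are treated as coincident with the axes
POSITIVITY_TOL = 1e-10


@dataclass(frozen=True)
class CubicCoeffs:
    """Coefficients of the y-cubic whose positive roots are the tumor levels."""

    a1: float
    a2: float
    a3: float
    a4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4])

    def __call__(self, y: float) -> float:
        return ((self.a1 * y + self.a2) * y + self.a3) * y + self.a4

    def discriminant(self) -> float:
        """Standard cubic discriminant (> 0 iff three distinct real roots)."""
        a, b, c, d = self.a1, self.a2, self.a3, self.a4
        return (
            18 * a * b * c * d - 4 * b**3 * d + b**2 * c**2 - 4 * a * c**3 - 27 * a**2 * d**2
        )


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the model; ``kind`` is 'tumor_free' or 'positive'."""

    x_star: float
    y_star: float
    kind: str
    residual: float
    multiplicity: int = 1

    @property
    def point(self) -> tuple[float, float]:
        return (self.x_star, self.y_star)


def tumor_free(params: ModelParams) -> Equilibrium:
    """The tumor-free steady state (sigma/delta, 0)."""
    x = params.sigma / params.delta
    resid = max(abs(r) for r in rhs_ode(params, (x, 0.0)))
    return Equilibrium(x_star=x, y_star=0.0, kind="tumor_free", residual=resid)


def cubic_coefficients(params: ModelParams) -> CubicCoeffs:
    """Coefficients of the cubic obtained by substituting x = f(1 - beta*y)."""
    p = params
    return CubicCoeffs(
        a1=p.f * p.beta * p.mu,
        a2=p.f * (-p.alpha * p.beta + p.beta * p.delta - p.mu + p.beta * p.mu),
        a3=p.f * p.alpha - p.f * p.delta + p.f * p.beta * p.delta - p.f * p.mu + p.sigma,
        a4=p.sigma - p.f * p.delta,
    )


def _newton_polish(params: ModelParams, x: float, y: float, iters: int = 30) -> tuple[float, float]:
    """Newton iteration on the 2-D equilibrium system with the analytic Jacobian."""
    for _ in range(iters):
        r = np.array(rhs_ode(params, (x, y)))
        if np.max(np.abs(r)) < 1e-14:
            break
        J = first_partials(params, x, y)
        J2 = J[:, :2] + J[:, 2:]  # collapse lagged args: equilibria are delay-independent
        try:
            dx, dy = np.linalg.solve(J2, -r)
        except np.linalg.LinAlgError:
            break
        x, y = x + dx, y + dy
    return x, y


def positive_equilibria(params: ModelParams) -> list[Equilibrium]:
    """All positive equilibria, sorted by increasing tumor level y*.

    Real cubic roots are extracted from the companion-matrix spectrum,
    Newton-polished on the full 2-D system, and filtered for positivity of
    both coordinates.  Near-coincident polished roots are merged and reported
    once with their multiplicity.
    """
    cc = cubic_coefficients(params)
    roots = np.roots(cc.as_array())
    candidates = []
    for r in roots:
        if abs(r.imag) > 1e-7 * max(1.0, abs(r)):
            continue
        y = float(r.real)
        x = params.f * (1.0 - params.beta * y)
        if y <= POSITIVITY_TOL or x <= POSITIVITY_TOL:
            if 0 < y <= POSITIVITY_TOL or (y > 0 and 0 < x <= POSITIVITY_TOL):
                log.warning("dropping near-degenerate root y=%.3e (coincides with an axis)", y)
            continue
        x, y = _newton_polish(params, x, y)
        if y <= POSITIVITY_TOL or x <= POSITIVITY_TOL:
            continue
        resid = max(abs(v) for v in rhs_ode(params, (x, y)))
        if resid > EQ_RESIDUAL_TOL:
            log.warning("discarding candidate (%.6g, %.6g): residual %.2e", x, y, resid)
            continue
        candidates.append((x, y, resid))

    candidates.sort(key=lambda t: t[1])
    merged: list[list] = []
    for x, y, resid in candidates:
        if merged and abs(y - merged[-1][1]) <= 1e-6 * max(1.0, abs(y)):
            merged[-1][2] = min(merged[-1][2], resid)
            merged[-1][3] += 1
        else:
            merged.append([x, y, resid, 1])
    return [
        Equilibrium(x_star=x, y_star=y, kind="positive", residual=r, multiplicity=m)
        for x, y, r, m in merged
    ]


# --- advisory case table ----------------------------------------------------
# The published classification of root counts by parameter inequalities is
# internally inconsistent (overlapping hypotheses with different conclusions,
# and some symbols never defined), so direct root counting is authoritative
# and the table below is advisory only.


def _case_table(p: ModelParams, disc: float):
    chain = p.alpha > p.delta > p.mu / p.beta > p.mu
    lo = p.sigma < p.f * p.delta
    hi = p.sigma > p.f * p.delta
    return [
        ("three-roots", chain and lo and disc < 0, 3),
        ("two-roots-a", chain and hi and disc < 0, 2),
        ("two-roots-b", chain and hi and disc == 0, 2),
        ("one-root-i", chain and lo and disc < 0, 1),
        ("one-root-iii", p.delta > p.alpha and p.beta > 1 and p.alpha + p.beta * p.delta < p.mu and lo and disc > 0, 1),
        ("one-root-iv", chain and lo and disc == 0, 1),
    ]


@dataclass(frozen=True)
class RegimeReport:
    """Root count, discriminant, and which advisory case (if any) matched."""

    computed_count: int
    cubic_discriminant: float
    printed_case_matched: str
    consistency_flag: bool
    matched_cases: tuple = field(default_factory=tuple)


def regime_report(params: ModelParams) -> RegimeReport:
    """Count positive equilibria directly and compare with the advisory case table."""
    eqs = positive_equilibria(params)
    count = sum(e.multiplicity for e in eqs)
    disc = cubic_coefficients(params).discriminant()
    matches = [(label, pred) for label, hold, pred in _case_table(params, disc) if hold]
    if not matches:
        return RegimeReport(count, disc, "none", True, ())
    agreeing = [label for label, pred in matches if pred == count]
    if agreeing:
        return RegimeReport(count, disc, agreeing[0], True, tuple(m[0] for m in matches))
    return RegimeReport(count, disc, matches[0][0], False, tuple(m[0] for m in matches))
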