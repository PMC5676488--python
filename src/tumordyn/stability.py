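"""Linear stability of the non-delayed system and the analytic certificates.

At a positive equilibrium the equilibrium identities simplify the Jacobian to::

    J = [[-sigma/x*,  alpha*x*/(1+y*)^2 - mu*x*],
        [   -y*,     -f*beta*y*                ]]

Eigenvalues come from the 2x2 closed form (trace/discriminant); the general
solver serves as a test oracle only.  The module also evaluates the analytic
stability certificates: the tumor-free threshold (f vs sigma/delta), the
global-elimination certificate (Dulac function 1/y on the invariant box), and
the tumor-burden threshold for positive equilibria based on the sign of
h(y*) = a*y*^2 + 2a*y* + a + alpha with a = (sigma*f*beta - mu*x*^2)/x*^2.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .equilibria import Equilibrium, positive_equilibria, tumor_free
from .model import EQ_RESIDUAL_TOL, first_partials
from .params import ModelParams

__all__ = [
    "StabilityVerdict",
    "Certificate",
    "jacobian",
    "eigenvalues_2x2",
    "classify",
    "tumor_free_stability",
    "global_stability_certificate",
    "invariant_region",
    "positive_stability_conditions",
]

#: |Re(lambda)| below this is treated as a zero real part (center candidate)
CENTER_TOL = 1e-10


@dataclass(frozen=True)
class Certificate:
    """An analytic stability certificate with its evaluated inequalities."""

    label: str
    holds: bool
    values: dict
    prediction: str = ""
    note: str = ""


@dataclass(frozen=True)
class StabilityVerdict:
    eigenvalues: tuple
    classification: str
    certificates: tuple = field(default_factory=tuple)

    @property
    def is_stable(self) -> bool:
        return self.classification in ("stable_node", "stable_focus")


def jacobian(params: ModelParams, eq: Equilibrium) -> np.ndarray:
    """Jacobian of the instantaneous vector field at an equilibrium.

    For accepted positive equilibria (residual < 1e-9) the simplified entries
    that use the equilibrium identities are returned; otherwise the raw
    partial derivatives are used.
    """
    if eq.residual > EQ_RESIDUAL_TOL:
        raise ValueError(f"equilibrium residual {eq.residual:.2e} exceeds {EQ_RESIDUAL_TOL:.1e}")
    p = params
    x, y = eq.x_star, eq.y_star
    if eq.kind == "positive":
        return np.array(
            [
                [-p.sigma / x, p.alpha * x / (1.0 + y) ** 2 - p.mu * x],
                [-y, -p.f * p.beta * y],
            ]
        )
    J4 = first_partials(params, x, y)
    return J4[:, :2] + J4[:, 2:]


def eigenvalues_2x2(J: np.ndarray) -> tuple[complex, complex]:
    """Closed-form eigenvalues of a real 2x2 matrix (conjugate order: +Im first)."""
    tr = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = tr * tr / 4.0 - det
    if disc >= 0:
        root = math.sqrt(disc)
        return (complex(tr / 2.0 + root), complex(tr / 2.0 - root))
    root = math.sqrt(-disc)
    return (complex(tr / 2.0, root), complex(tr / 2.0, -root))


def _classify_pair(lam1: complex, lam2: complex) -> str:
    re1, re2 = lam1.real, lam2.real
    if abs(re1) < CENTER_TOL or abs(re2) < CENTER_TOL:
        return "center_candidate"
    complex_pair = abs(lam1.imag) > 0
    if complex_pair:
        return "stable_focus" if re1 < 0 else "unstable_focus"
    if re1 < 0 and re2 < 0:
        return "stable_node"
    if re1 > 0 and re2 > 0:
        return "unstable_node"
    return "saddle"


def classify(params: ModelParams, eq: Equilibrium) -> StabilityVerdict:
    """Eigenvalue-based stability classification of an equilibrium."""
    lam1, lam2 = eigenvalues_2x2(jacobian(params, eq))
    return StabilityVerdict(eigenvalues=(lam1, lam2), classification=_classify_pair(lam1, lam2))


def tumor_free_stability(params: ModelParams) -> StabilityVerdict:
    """Stability of (sigma/delta, 0) from the threshold f vs sigma/delta.

    The eigenvalues there are -delta and f - sigma/delta.
    """
    p = params
    ratio = p.sigma / p.delta
    lam = (complex(-p.delta), complex(p.f - ratio))
    gap = p.f - ratio
    if abs(gap) < 1e-12:
        cls, pred = "center_candidate", "stable (boundary - linearization inconclusive)"
    elif gap > 0:
        cls, pred = "saddle", "unstable"
    else:
        cls, pred = "stable_node", "asymptotically stable"
    cert = Certificate(
        label="tumor_free_threshold",
        holds=True,
        values={"f": p.f, "sigma/delta": ratio},
        prediction=pred,
    )
    return StabilityVerdict(eigenvalues=lam, classification=cls, certificates=(cert,))


def global_stability_certificate(params: ModelParams) -> Certificate:
    """Global elimination certificate: sigma > f*delta and delta*beta > mu > alpha.

    Under these inequalities the tumor-free state is the only equilibrium and
    the Dulac function 1/y excludes closed orbits in the invariant box, so
    local stability upgrades to global stability.  If the inequalities hold
    but positive equilibria are nevertheless found, something is internally
    inconsistent and an error is raised.
    """
    p = params
    values = {
        "sigma": p.sigma,
        "f*delta": p.f * p.delta,
        "delta*beta": p.delta * p.beta,
        "mu": p.mu,
        "alpha": p.alpha,
        "dulac_bound": p.alpha - p.mu - p.f * p.beta,
    }
    holds = (p.sigma > p.f * p.delta) and (p.delta * p.beta > p.mu > p.alpha)
    if holds and values["dulac_bound"] >= 0:
        # mu > alpha forces alpha - mu - f*beta < 0; reaching here means a bug
        raise RuntimeError("Dulac bound non-negative although mu > alpha; internal inconsistency")
    if holds and positive_equilibria(params):
        raise RuntimeError(
            "global-stability inequalities hold but positive equilibria were found; "
            "this contradicts the certificate's derivation"
        )
    return Certificate(
        label="global_elimination",
        holds=holds,
        values=values,
        prediction="tumor-free state globally asymptotically stable" if holds else "",
    )


@dataclass(frozen=True)
class InvariantRegion:
    """The forward-invariant box [0, 2 sigma/delta] x [0, 2/beta]."""

    x_max: float
    y_max: float
    certified: bool

    def contains(self, states, tol: float = 1e-8) -> bool:
        arr = np.asarray(states, dtype=float).reshape(-1, 2)
        return bool(
            np.all(arr[:, 0] >= -tol)
            and np.all(arr[:, 1] >= -tol)
            and np.all(arr[:, 0] <= self.x_max + tol)
            and np.all(arr[:, 1] <= self.y_max + tol)
        )


def invariant_region(params: ModelParams) -> InvariantRegion:
    """The invariant box; certified only under the hypothesis mu > alpha."""
    certified = params.mu > params.alpha
    if not certified:
        warnings.warn(
            "invariant-region hypothesis mu > alpha not met; box returned uncertified"
        )
    return InvariantRegion(
        x_max=2.0 * params.sigma / params.delta, y_max=2.0 / params.beta, certified=certified
    )


def positive_stability_conditions(params: ModelParams, eq: Equilibrium) -> tuple[Certificate, ...]:
    """Analytic stability certificates at a positive equilibrium.

    First the sufficient condition sigma*beta > mu*f (trace negative and
    determinant positive outright).  Otherwise the determinant's sign equals
    the sign of h(y*) = a*(y*+1)^2 + alpha with a = (sigma*f*beta - mu*x*^2)/x*^2:
    when f*sigma*beta >= mu*x*^2, h > 0 and the equilibrium is stable; when
    f*sigma*beta < mu*x*^2 the tumor-burden threshold
    y_th = sqrt(alpha*x*^2/(mu*x*^2 - f*sigma*beta)) - 1 separates stability
    (y* < y_th) from a saddle (y* > y_th).
    """
    if eq.kind != "positive":
        raise ValueError("certificates apply to positive equilibria only")
    p = params
    x, y = eq.x_star, eq.y_star
    certs = []

    simple = p.sigma * p.beta > p.mu * p.f
    certs.append(
        Certificate(
            label="trace_det_sufficient",
            holds=simple,
            values={"sigma*beta": p.sigma * p.beta, "mu*f": p.mu * p.f},
            prediction="stable" if simple else "",
        )
    )

    a = (p.sigma * p.f * p.beta - p.mu * x * x) / (x * x)
    h = a * (y + 1.0) ** 2 + p.alpha
    values = {"a": a, "h(y*)": h, "f*sigma*beta": p.f * p.sigma * p.beta, "mu*x*^2": p.mu * x * x}
    if p.f * p.sigma * p.beta >= p.mu * x * x:
        pred, note = "stable", "h(y*) > 0 for all y* in this branch"
    else:
        y_th = math.sqrt(p.alpha * x * x / (p.mu * x * x - p.f * p.sigma * p.beta)) - 1.0
        values["y_threshold"] = y_th
        if abs(h) < 1e-12:
            pred, note = "boundary", "h(y*) = 0 - linearization inconclusive"
        elif y < y_th:
            pred, note = "stable", "tumor level below the threshold"
        else:
            pred, note = "unstable", "tumor level above the threshold (saddle)"
    certs.append(
        Certificate(label="tumor_burden_threshold", holds=True, values=values, prediction=pred, note=note)
    )

    verdict = classify(params, eq)
    predicted_stable = any(c.prediction == "stable" for c in certs)
    if predicted_stable and not verdict.is_stable and verdict.classification != "center_candidate":
        certs.append(
            Certificate(
                label="certificate_eigenvalue_mismatch",
                holds=False,
                values={"classification": verdict.classification},
                note="inconsistent: certificate predicts stability but eigenvalues disagree",
            )
        )
    return tuple(certs)
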