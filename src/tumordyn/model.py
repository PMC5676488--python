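"""Model right-hand sides and exact Taylor coefficients at an equilibrium.

The delayed system reads::

    dx/dt = sigma + alpha*x*y/(1+y) - mu*x(t-tau)*y(t-tau) - delta*x
    dy/dt = f*y*(1 - beta*y) - x*y

Only the effector-inactivation term carries the delay; setting the lagged
state equal to the current one recovers the ODE exactly.

All second- and third-order partial derivatives with respect to the four
arguments ``(x, y, x_lag, y_lag)`` are obtained by symbolic differentiation
of the right-hand side (sympy), evaluated at an equilibrium, and stored as
dense tensors.  This gives the normal-form module a single source of truth
that is cross-checked against finite differences in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
import sympy as sp

from .params import ModelParams, State

__all__ = ["rhs_ode", "rhs_dde", "TaylorCoeffs", "taylor_coefficients", "EQ_RESIDUAL_TOL"]

#: residual bound below which a point is accepted as an equilibrium
EQ_RESIDUAL_TOL = 1e-9


def rhs_ode(params: ModelParams, state) -> tuple[float, float]:
    """Instantaneous vector field at ``state = (x, y)``."""
    x, y = state
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError(f"non-finite state {(x, y)}")
    p = params
    return (
        p.sigma + p.alpha * x * y / (1.0 + y) - p.mu * x * y - p.delta * x,
        p.f * y * (1.0 - p.beta * y) - x * y,
    )


def rhs_dde(params: ModelParams, now, lagged) -> tuple[float, float]:
    """Delayed vector field; the inactivation term uses the lagged state.

    With ``now == lagged`` this equals :func:`rhs_ode` exactly.
    """
    x, y = now
    xl, yl = lagged
    if not all(np.isfinite(v) for v in (x, y, xl, yl)):
        raise ValueError(f"non-finite state {(x, y, xl, yl)}")
    p = params
    return (
        p.sigma + p.alpha * x * y / (1.0 + y) - p.mu * xl * yl - p.delta * x,
        p.f * y * (1.0 - p.beta * y) - x * y,
    )


# --- symbolic machinery -----------------------------------------------------

_XS = sp.symbols("x y x_lag y_lag", real=True)
_PS = sp.symbols("sigma alpha mu delta f beta", positive=True)


def _symbolic_rhs():
    x, y, xl, yl = _XS
    sigma, alpha, mu, delta, f, beta = _PS
    f1 = sigma + alpha * x * y / (1 + y) - mu * xl * yl - delta * x
    f2 = f * y * (1 - beta * y) - x * y
    return (f1, f2)


@lru_cache(maxsize=1)
def _derivative_funcs():
    """Lambdified first/second/third partial-derivative tensors of the rhs."""
    fs = _symbolic_rhs()
    first = [[sp.diff(fc, _XS[i]) for i in range(4)] for fc in fs]
    second = [[[sp.diff(fc, _XS[i], _XS[j]) for j in range(4)] for i in range(4)] for fc in fs]
    third = [
        [[[sp.diff(fc, _XS[i], _XS[j], _XS[k]) for k in range(4)] for j in range(4)] for i in range(4)]
        for fc in fs
    ]
    args = (*_XS, *_PS)
    return (
        sp.lambdify(args, first, "numpy"),
        sp.lambdify(args, second, "numpy"),
        sp.lambdify(args, third, "numpy"),
    )


def _eval_args(params: ModelParams, x: float, y: float):
    return (x, y, x, y, params.sigma, params.alpha, params.mu, params.delta, params.f, params.beta)


def first_partials(params: ModelParams, x: float, y: float) -> np.ndarray:
    """(2, 4) array of first partials of the delayed rhs wrt (x, y, x_lag, y_lag)."""
    f1, _, _ = _derivative_funcs()
    return np.array(f1(*_eval_args(params, x, y)), dtype=float)


@dataclass(frozen=True)
class TaylorCoeffs:
    """Second- and third-order partials of the rhs at an equilibrium.

    ``second[c, i, j]`` is the raw partial d^2 f_c / du_i du_j and
    ``third[c, i, j, k]`` the raw third partial, with the argument order
    u = (x, y, x_lag, y_lag).  The tensors are fully symmetric in the
    derivative indices.
    """

    second: np.ndarray  # (2, 4, 4)
    third: np.ndarray  # (2, 4, 4, 4)

    def partial(self, component: int, multi_index: tuple[int, int, int, int]) -> float:
        """Raw partial for a multi-index over (x, y, x_lag, y_lag)."""
        order = sum(multi_index)
        idx = [i for i, m in enumerate(multi_index) for _ in range(m)]
        if order == 2:
            return float(self.second[component, idx[0], idx[1]])
        if order == 3:
            return float(self.third[component, idx[0], idx[1], idx[2]])
        raise ValueError(f"only orders 2 and 3 are stored, got {order}")

    def bilinear(self, u, v) -> np.ndarray:
        """B(u, v)_c = sum_ij d2f_c/du_i du_j * u_i v_j (full Hessian contraction)."""
        u = np.asarray(u)
        v = np.asarray(v)
        return np.einsum("cij,i,j->c", self.second, u, v)

    def trilinear(self, u, v, w) -> np.ndarray:
        """C(u, v, w)_c = sum_ijk d3f_c * u_i v_j w_k."""
        return np.einsum("cijk,i,j,k->c", self.third, np.asarray(u), np.asarray(v), np.asarray(w))


def taylor_coefficients(params: ModelParams, eq, tol: float = EQ_RESIDUAL_TOL) -> TaylorCoeffs:
    """Exact second/third partial tensors of the delayed rhs at an equilibrium.

    ``eq`` may be an :class:`~tumordyn.equilibria.Equilibrium` or a plain
    ``(x, y)`` pair; it must satisfy the equilibrium equations to within
    ``tol``.
    """
    x, y = (eq.x_star, eq.y_star) if hasattr(eq, "x_star") else tuple(eq)
    resid = max(abs(r) for r in rhs_ode(params, (x, y)))
    if resid > tol:
        raise ValueError(f"point ({x}, {y}) is not an equilibrium: residual {resid:.3e} > {tol:.1e}")
    _, f2, f3 = _derivative_funcs()
    a = _eval_args(params, x, y)
    return TaylorCoeffs(second=np.array(f2(*a), dtype=float), third=np.array(f3(*a), dtype=float))
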