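"""Direct numerical integration of the ODE/DDE systems and orbit diagnostics.

The DDE is integrated by the method of steps: on each window
[k*tau, (k+1)*tau] the lagged state is read from the dense interpolant of the
previous window, so the interpolation error is controlled by the integrator
tolerance.  tau = 0 falls back to the plain ODE integrator.  Diagnostics
discard a transient fraction, test convergence to a supplied equilibrium,
and otherwise peak-detect the tumor component for period and amplitude.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .equilibria import Equilibrium
from .model import rhs_dde, rhs_ode
from .params import ModelParams, State

__all__ = [
    "History",
    "Trajectory",
    "OrbitDiagnostics",
    "IntegrationError",
    "integrate_ode",
    "integrate_dde",
    "diagnostics",
    "bifurcation_scan",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12


class IntegrationError(RuntimeError):
    def __init__(self, msg, partial=None):
        super().__init__(msg)
        self.partial = partial


@dataclass(frozen=True)
class History:
    """Initial history on [-tau, 0]: constant, or an arbitrary callable of t."""

    kind: str  # "constant" | "function"
    value: Union[State, tuple, Callable]

    def __call__(self, t: float) -> np.ndarray:
        if self.kind == "constant":
            return np.array(tuple(self.value), dtype=float)
        return np.asarray(self.value(t), dtype=float)

    @staticmethod
    def constant(state) -> "History":
        return History(kind="constant", value=tuple(state))


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n, 2)
    meta: dict = field(default_factory=dict)
    _segments: list = field(default_factory=list, repr=False)  # (t0, t1, dense) pieces

    def sample(self, ts) -> np.ndarray:
        """Evaluate the dense solution at arbitrary times within the span."""
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        out = np.empty((ts.size, 2))
        for i, t in enumerate(ts):
            seg = None
            for t0, t1, dense in self._segments:
                if t0 - 1e-9 <= t <= t1 + 1e-9:
                    seg = (t0, t1, dense)
            if seg is None:
                raise ValueError(f"time {t} outside trajectory span")
            t0, t1, dense = seg
            out[i] = dense(min(max(t, t0), t1))
        return out

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def _solve_window(fun, t0, t1, y0, rtol, atol, method):
    sol = solve_ivp(fun, (t0, t1), y0, method=method, rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise IntegrationError(f"integration failed on [{t0}, {t1}]: {sol.message}")
    return sol


def integrate_ode(
    params: ModelParams,
    init,
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
) -> Trajectory:
    """Adaptive integration of the non-delayed system with dense output."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = np.array(tuple(init), dtype=float)

    def fun(t, y):
        return rhs_ode(params, y)

    sol = _solve_window(fun, 0.0, float(t_end), y0, rtol, atol, method)
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        meta={"params": params.as_dict(), "tau": 0.0, "rtol": rtol, "atol": atol, "method": method},
        _segments=[(0.0, float(t_end), sol.sol)],
    )


def integrate_dde(
    params: ModelParams,
    tau: float,
    history: History,
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
) -> Trajectory:
    """Method-of-steps integration of the delayed system.

    The lagged state is evaluated from the stored dense interpolant of the
    previous window (or the history for t - tau <= 0).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if tau == 0:
        return integrate_ode(params, history(0.0), t_end, rtol=rtol, atol=atol, method=method)

    segments: list = []

    def lagged(t: float) -> np.ndarray:
        tl = t - tau
        if tl <= 0:
            return history(tl)
        for t0, t1, dense in reversed(segments):
            if t0 - 1e-9 <= tl <= t1 + 1e-9:
                return dense(min(max(tl, t0), t1))
        raise IntegrationError(f"lagged time {tl} not covered")  # pragma: no cover

    def fun(t, y):
        return rhs_dde(params, y, lagged(t))

    times = [np.array([0.0])]
    states = [np.array([history(0.0)])]
    t = 0.0
    y = history(0.0)
    try:
        while t < t_end - 1e-12:
            t1 = min(t + tau, float(t_end))
            sol = _solve_window(fun, t, t1, y, rtol, atol, method)
            segments.append((t, t1, sol.sol))
            times.append(sol.t[1:])
            states.append(sol.y.T[1:])
            t, y = t1, sol.y[:, -1]
    except IntegrationError as err:
        err.partial = Trajectory(
            times=np.concatenate(times), states=np.concatenate(states), _segments=segments
        )
        raise
    return Trajectory(
        times=np.concatenate(times),
        states=np.concatenate(states),
        meta={
            "params": params.as_dict(),
            "tau": tau,
            "rtol": rtol,
            "atol": atol,
            "method": method,
            "history": history.kind,
        },
        _segments=segments,
    )


@dataclass(frozen=True)
class OrbitDiagnostics:
    outcome: str  # converged_to_point | periodic | growing | undecided
    limit_point: Optional[tuple] = None
    period: Optional[float] = None
    amplitude: Optional[tuple] = None  # per-component peak-to-trough
    tail_fraction_used: float = 0.5


def diagnostics(
    traj: Trajectory,
    equilibria: Sequence[Equilibrium] = (),
    transient_fraction: float = 0.5,
    conv_tol: float = 1e-6,
    peak_rel_tol: float = 0.02,
    n_samples: int = 4000,
) -> OrbitDiagnostics:
    """Classify the long-run behavior of a trajectory.

    The first ``transient_fraction`` of the time span is discarded.  A
    trajectory converges if its last-tenth samples all lie within ``conv_tol``
    of one supplied equilibrium; it is periodic if at least five successive
    peak intervals of the tumor component agree within ``peak_rel_tol``
    relative; monotonically expanding peak envelopes are flagged growing.
    """
    t_end = traj.times[-1]
    t_start = traj.times[0] + transient_fraction * (t_end - traj.times[0])
    if t_end - t_start <= 0:
        warnings.warn("trajectory too short for diagnostics")
        return OrbitDiagnostics(outcome="undecided", tail_fraction_used=transient_fraction)
    ts = np.linspace(t_start, t_end, n_samples)
    tail = traj.sample(ts)

    last = tail[int(0.9 * n_samples) :]
    for eq in equilibria:
        pt = np.array(eq.point)
        if np.all(np.linalg.norm(last - pt, axis=1) < conv_tol):
            return OrbitDiagnostics(
                outcome="converged_to_point",
                limit_point=tuple(traj.final_state),
                tail_fraction_used=transient_fraction,
            )

    y = tail[:, 1]
    spread = y.max() - y.min()
    if spread < max(conv_tol, 1e-12):
        # flat but not at a known equilibrium
        return OrbitDiagnostics(
            outcome="converged_to_point" if not equilibria else "undecided",
            limit_point=tuple(traj.final_state),
            tail_fraction_used=transient_fraction,
        )
    peaks, _ = find_peaks(y, prominence=0.05 * spread)
    if len(peaks) >= 6:
        tp = ts[peaks]
        intervals = np.diff(tp)
        period = float(np.mean(intervals[-5:]))
        heights = y[peaks]
        if np.all(np.diff(heights[-5:]) > 0.02 * spread):
            return OrbitDiagnostics(outcome="growing", tail_fraction_used=transient_fraction)
        if np.all(np.abs(intervals[-5:] - period) <= peak_rel_tol * period):
            amp = tuple(tail[:, c].max() - tail[:, c].min() for c in range(2))
            return OrbitDiagnostics(
                outcome="periodic",
                period=period,
                amplitude=amp,
                tail_fraction_used=transient_fraction,
            )
    return OrbitDiagnostics(outcome="undecided", tail_fraction_used=transient_fraction)


def bifurcation_scan(
    params: ModelParams,
    eq: Equilibrium,
    tau_grid: Sequence[float],
    history_rule: Optional[Callable[[Equilibrium, float], History]] = None,
    t_end: float = 400.0,
    equilibria: Sequence[Equilibrium] = (),
    conv_tol: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate across a tau grid and tabulate outcome, amplitude, period.

    The default history is the equilibrium perturbed by +1% in each component.
    """
    taus = list(tau_grid)
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise ValueError("tau_grid must be ascending")
    if history_rule is None:
        history_rule = lambda e, tau: History.constant((e.x_star * 1.01, e.y_star * 1.01))
    eq_list = list(equilibria) if equilibria else [eq]
    rows = []
    for tau in taus:
        traj = integrate_dde(params, float(tau), history_rule(eq, tau), t_end, rtol=rtol, atol=atol)
        diag = diagnostics(traj, eq_list, conv_tol=conv_tol)
        rows.append(
            {
                "tau": float(tau),
                "outcome": diag.outcome,
                "amplitude": diag.amplitude[1] if diag.amplitude else np.nan,
                "period": diag.period if diag.period else np.nan,
            }
        )
    return pd.DataFrame(rows)
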