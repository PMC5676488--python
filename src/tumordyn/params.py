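"""Parameter containers, state type, and the dimensional -> nondimensional map.

The model describes effector (immune) cells ``E`` attacking an immunogenic
tumor ``T``.  In dimensional form::

    dE/dt = s + p*E*T/(g + T) - m*E*T - d*E
    dT/dt = a*T*(1 - b*T) - n*E*T

Rescaling both populations by the Michaelis constant ``g`` (x = E/g, y = T/g)
and time by ``n*g`` yields the six-parameter nondimensional system::

    dx/dt = sigma + alpha*x*y/(1+y) - mu*x*y - delta*x
    dy/dt = f*y*(1 - beta*y) - x*y

with sigma = s/(n g^2), alpha = p/(n g), mu = m/n, delta = d/(n g),
f = a/(n g), beta = b g.  All parameters are strictly positive.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "OriginalParams",
    "ModelParams",
    "State",
    "nondimensionalize",
    "load_params",
    "save_params",
]

#: components smaller than this are treated as integrator round-off, not errors
NEG_TOL = 1e-12


def _check_positive(obj) -> None:
    for fld in fields(obj):
        v = getattr(obj, fld.name)
        if not (isinstance(v, (int, float)) and math.isfinite(v)):
            raise ValueError(f"{type(obj).__name__}.{fld.name} must be finite, got {v!r}")
        if v <= 0:
            raise ValueError(f"{type(obj).__name__}.{fld.name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class OriginalParams:
    """Dimensional rate constants of the effector/tumor model.

    s: effector influx rate; p: immune-response amplitude; g: Michaelis
    constant; m: effector inactivation rate; d: effector death rate;
    a: tumor growth rate; b: inverse tumor carrying capacity; n: kill rate.
    """

    s: float
    p: float
    g: float
    m: float
    d: float
    a: float
    b: float
    n: float

    def __post_init__(self):
        _check_positive(self)


@dataclass(frozen=True)
class ModelParams:
    """The six nondimensional rate constants (all strictly positive)."""

    sigma: float
    alpha: float
    mu: float
    delta: float
    f: float
    beta: float

    def __post_init__(self):
        _check_positive(self)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class State:
    """Nondimensional (effector, tumor) densities.

    Tiny negative components (above -1e-12) are accepted with a warning —
    they arise from integrator round-off near the axes — while anything more
    negative is rejected.
    """

    x: float
    y: float

    def __post_init__(self):
        for name, v in (("x", self.x), ("y", self.y)):
            if not math.isfinite(v):
                raise ValueError(f"State.{name} must be finite, got {v!r}")
            if v < -NEG_TOL:
                raise ValueError(f"State.{name} = {v} is negative beyond round-off tolerance")
            if v < 0:
                warnings.warn(f"State.{name} = {v} slightly negative; accepted as round-off")

    def __iter__(self):
        yield self.x
        yield self.y


def nondimensionalize(original: OriginalParams) -> tuple[ModelParams, float]:
    """Map dimensional parameters to the six nondimensional constants.

    Returns ``(params, time_scale)`` where ``time_scale = n*g``: nondimensional
    time equals dimensional time multiplied by ``n*g`` (so a dimensional delay
    ``tau_dim`` becomes ``tau_dim * n * g``), and states scale as
    ``x = E/g``, ``y = T/g``.
    """
    o = original
    return (
        ModelParams(
            sigma=o.s / (o.n * o.g**2),
            alpha=o.p / (o.n * o.g),
            mu=o.m / o.n,
            delta=o.d / (o.n * o.g),
            f=o.a / (o.n * o.g),
            beta=o.b * o.g,
        ),
        o.n * o.g,
    )


_NONDIM_KEYS = ("sigma", "alpha", "mu", "delta", "f", "beta")
_DIM_KEYS = ("s", "p", "g", "m", "d", "a", "b", "n")


def load_params(source: Union[str, Path, dict]) -> tuple[ModelParams, float]:
    """Read model parameters from a flat key/value config (YAML or JSON).

    Keys must be exactly the six nondimensional names (sigma, alpha, mu,
    delta, f, beta) or the eight dimensional ones (s, p, g, m, d, a, b, n).
    Returns ``(params, time_scale)``; the time scale is 1.0 for an already
    nondimensional config.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("parameter config must be a flat key/value mapping")
    keys = set(data)
    if keys >= set(_NONDIM_KEYS):
        extra = keys - set(_NONDIM_KEYS)
        if extra:
            raise ValueError(f"unexpected keys in nondimensional config: {sorted(extra)}")
        return ModelParams(**{k: float(data[k]) for k in _NONDIM_KEYS}), 1.0
    if keys >= set(_DIM_KEYS):
        extra = keys - set(_DIM_KEYS)
        if extra:
            raise ValueError(f"unexpected keys in dimensional config: {sorted(extra)}")
        return nondimensionalize(OriginalParams(**{k: float(data[k]) for k in _DIM_KEYS}))
    raise ValueError(
        "config must contain either the six nondimensional keys "
        f"{_NONDIM_KEYS} or the eight dimensional keys {_DIM_KEYS}; got {sorted(keys)}"
    )


def save_params(params: ModelParams, path: Union[str, Path]) -> None:
    """Write parameters as a flat YAML mapping (round-trips with load_params)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)
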