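"""One-shot analysis report: equilibria, stability, delay, normal form, simulation.

``run_report`` composes the whole pipeline for a scenario and returns a
JSON-serializable dict.  Sections record their own failures instead of
aborting the report, and every numeric block carries its residual/tolerance
metadata so the output is auditable.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
import traceback
from dataclasses import asdict
from importlib.metadata import PackageNotFoundError, version

import numpy as np

from . import delay as _delay
from . import normal_form as _nf
from . import simulate as _sim
from . import stability as _stab
from .equilibria import positive_equilibria, regime_report, tumor_free
from .scenarios import Scenario, perturbed_history

__all__ = ["run_report", "jsonify"]

log = logging.getLogger(__name__)


def jsonify(obj):
    """Recursively convert analysis objects to JSON-safe structures.

    Complex numbers become {"re": ..., "im": ...}; numpy scalars/arrays become
    Python numbers/lists; dataclasses become dicts; infinities become the
    string "inf".
    """
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: jsonify(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def _section(report: dict, name: str, fn):
    try:
        report[name] = jsonify(fn())
    except Exception as err:  # noqa: BLE001 - partial failures are recorded, not raised
        log.warning("report section %s failed: %s", name, err)
        report[name] = {"error": str(err), "traceback": traceback.format_exc()}


def run_report(scenario: Scenario, simulate_checks: bool = False, j_max: int = 2) -> dict:
    """Run the full analysis pipeline for a scenario.

    With ``simulate_checks=True`` a short DDE integration cross-checks the
    delay verdict at each positive equilibrium (slower; off by default).
    """
    params = scenario.params
    report: dict = {"scenario": json.loads(scenario.to_json())}
    try:
        pkg_version = version("tumordyn")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"

    p0 = tumor_free(params)
    eqs = positive_equilibria(params)
    _section(report, "equilibria", lambda: {"tumor_free": p0, "positive": eqs})
    _section(report, "regime", lambda: regime_report(params))
    _section(
        report,
        "stability",
        lambda: {
            "tumor_free": _stab.tumor_free_stability(params),
            "positive": [
                {
                    "equilibrium": eq,
                    "verdict": _stab.classify(params, eq),
                    "certificates": _stab.positive_stability_conditions(params, eq),
                }
                for eq in eqs
            ],
        },
    )
    _section(report, "global_stability", lambda: _stab.global_stability_certificate(params))

    delay_sections = []
    hopf_sections = []
    for i, eq in enumerate(eqs):
        entry = {"equilibrium_index": i}
        try:
            verdict = _delay.delay_verdict(params, eq, j_max=j_max)
            entry["critical_delays"] = jsonify(verdict)
            if verdict.verdict == "hopf_at_tau0" or (
                verdict.verdict == "finite_switches" and verdict.tau0 is not None
            ):
                try:
                    nf = _nf.normal_form_at(params, eq)
                    hp = _nf.hopf_point(params, eq)
                    hopf_sections.append(
                        {
                            "equilibrium_index": i,
                            "omega0": hp.omega0,
                            "tau0": hp.tau0,
                            "lambda_prime": jsonify(hp.lambda_prime),
                            "normal_form": jsonify(nf),
                            "residual_tol": _delay.CROSSING_TOL,
                        }
                    )
                except Exception as err:  # noqa: BLE001
                    hopf_sections.append({"equilibrium_index": i, "error": str(err)})
        except Exception as err:  # noqa: BLE001
            entry["error"] = str(err)
        delay_sections.append(entry)
    report["delay"] = delay_sections
    report["normal_form"] = hopf_sections if hopf_sections else "not-applicable"

    if simulate_checks and eqs:
        def sim_check():
            out = []
            for i, eq in enumerate(eqs):
                hist = perturbed_history(eq, 0.01, seed=scenario.seed or 0)
                tau = scenario.tau if scenario.tau is not None else 1.0
                traj = _sim.integrate_dde(params, tau, hist, t_end=200.0, rtol=1e-8, atol=1e-10)
                diag = _sim.diagnostics(traj, [eq])
                out.append({"equilibrium_index": i, "tau": tau, "diagnostics": diag})
            return out

        _section(report, "simulation", sim_check)
    else:
        report["simulation"] = "skipped"

    payload = json.dumps(jsonify(report), sort_keys=True, default=str)
    report["meta"] = {
        "tool": "tumordyn",
        "version": pkg_version,
        "settings_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "j_max": j_max,
    }
    return report
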