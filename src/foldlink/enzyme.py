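"""Competitive-inhibition Michaelis-Menten analysis.

Initial velocities follow V0 = Vmax S / (Km_app + S), with the apparent
Michaelis constant under classical competitive inhibition
Km_app = Km (1 + I / Ki). The model assumes inhibitor in large excess
over enzyme (non-tight-binding); see docs/methods.md for the validity
note when inhibitor and enzyme concentrations are comparable.
"""

from __future__ import annotations

import numpy as np
import lmfit

from .curves import CurveTable
from .results import FitResult

__all__ = ["km_apparent", "initial_velocity", "fit_mm", "infer_ki"]


def km_apparent(Km: float, I: float, Ki: float) -> float:
    """Apparent Michaelis constant Km (1 + I/Ki); equals Km when I = 0."""
    if not Km > 0:
        raise ValueError("Km must be > 0")
    if not Ki > 0:
        raise ValueError("Ki must be > 0")
    if I < 0:
        raise ValueError("I must be >= 0")
    return Km * (1.0 + I / Ki)


def initial_velocity(Vmax: float, Km_app: float, S):
    """Hyperbolic initial velocity Vmax S / (Km_app + S)."""
    S = np.asarray(S, float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    return Vmax * S / (Km_app + S)


def fit_mm(curve: CurveTable) -> FitResult:
    """Nonlinear least-squares fit of (Vmax, Km_app) to a V0-vs-S curve."""
    S, V = curve.x, curve.y
    if len(np.unique(S)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")

    vmax0 = float(np.max(V)) * 1.2 or 1.0
    half = 0.5 * np.max(V)
    km0 = float(S[np.argmin(np.abs(V - half))]) or float(np.median(S))

    p = lmfit.Parameters()
    p.add("Vmax", value=vmax0, min=0.0)
    p.add("Km_app", value=max(km0, 1e-12), min=1e-15)

    def resid(p):
        return initial_velocity(p["Vmax"].value, p["Km_app"].value, S) - V

    out = lmfit.minimize(resid, p, method="leastsq")
    params = {k: float(out.params[k].value) for k in ("Vmax", "Km_app")}
    stderr = {k: (float(out.params[k].stderr) if out.params[k].stderr else None)
              for k in ("Vmax", "Km_app")}
    return FitResult(
        params=params,
        stderr=stderr,
        rss=float(np.sum(np.asarray(out.residual) ** 2)),
        converged=bool(out.success),
        n_restarts_used=1,
        provenance=dict(curve.provenance),
    )


def infer_ki(Km: float, Km_app: float, I: float) -> float:
    """Inhibitor dissociation constant Ki = I / (Km_app/Km - 1).

    Raises ValueError when Km_app <= Km (no measurable inhibition, Ki
    undefined) or I <= 0.
    """
    if not Km > 0:
        raise ValueError("Km must be > 0")
    if not I > 0:
        raise ValueError("I must be > 0")
    if Km_app <= Km:
        raise ValueError("Km_app <= Km: no inhibition detected, Ki undefined")
    return I / (Km_app / Km - 1.0)
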