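"""Five-species allosteric linkage model of fold-switch coupled assembly.

The monomer interconverts between a native fold N, a fold-switched
conformation S and the unfolded state U. Only S assembles: six copies form
a hexameric ring H, and two rings stack into a dodecamer H2. A short
C-terminal peptide P binds the native fold (N + P <-> NP), acting as a
negative allosteric effector of assembly. All steps are treated under
mass-action thermodynamic control on the 1 M standard state:

    N <-> S        K_S   (dimensionless)
    N <-> U        K_U   (dimensionless)
    6S <-> H       K_H   (M^-5)
    2H <-> H2      K_H2  (M^-1)
    N + P <-> NP   K_P   (M^-1)

Given total monomer concentration C_tot, temperature T and total peptide
P_tot, the free native-monomer concentration x = [N] is the unique root of
the (strictly increasing) monomer mass balance; all species follow in
closed form. High-order terms (x^6, x^12) are evaluated in log space and
the root is found by bisection on ln x, which monotonicity makes
unconditionally safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import R_GAS, T_REF_DEFAULT
from .curves import CurveTable
from .twostate import ThermalStepParams, dg_thermal

__all__ = [
    "AssociationStepParams",
    "LinkageParams",
    "Conditions",
    "SpeciesState",
    "EquilibriumConstants",
    "equilibrium_constants",
    "solve_species",
    "monomer_fraction",
    "assembled_fraction",
    "apparent_native_midpoint",
    "peptide_rescue_curve",
    "LinkageSolverError",
]

_LN_EXP_MAX = 700.0  # exp() overflow guard; larger arguments map to inf


def _safe_exp(a: float) -> float:
    return math.inf if a > _LN_EXP_MAX else math.exp(a)


class LinkageSolverError(RuntimeError):
    """Raised when the mass-balance root finder fails to converge."""


@dataclass(frozen=True)
class AssociationStepParams:
    """van't Hoff parameterization of an association or binding step.

    dG_ref : step free energy at T_ref, kJ mol^-1 (per reaction as written,
        e.g. per hexamer for 6S -> H).
    dH_ref : step enthalpy at T_ref, kJ mol^-1.
    dCp : heat-capacity change, kJ mol^-1 K^-1.
    T_ref : reference temperature, K.
    stoichiometry : number of associating units (6 for 6S->H, 2 for 2H->H2,
        1 for 1:1 peptide binding); fixed by the scheme.
    """

    dG_ref: float
    dH_ref: float
    dCp: float = 0.0
    T_ref: float = T_REF_DEFAULT
    stoichiometry: int = 1

    def __post_init__(self) -> None:
        if not self.T_ref > 0:
            raise ValueError("T_ref must be > 0")

    def delta_g(self, T) -> np.ndarray | float:
        """dG(T) from dH(T) - T dS(T) with dS_ref = (dH_ref - dG_ref)/T_ref."""
        T = np.asarray(T, float)
        if np.any(T <= 0):
            raise ValueError("temperature must be > 0 K")
        dS_ref = (self.dH_ref - self.dG_ref) / self.T_ref
        dH = self.dH_ref + self.dCp * (T - self.T_ref)
        dS = dS_ref + self.dCp * np.log(T / self.T_ref)
        return dH - T * dS

    def delta_h(self, T) -> np.ndarray | float:
        return self.dH_ref + self.dCp * (np.asarray(T, float) - self.T_ref)


#: Inert association step (K = 0 at all T): dG_ref = +inf is not
#: representable, so generators use a very large positive dG instead.
def inert_step(stoichiometry: int = 1) -> AssociationStepParams:
    return AssociationStepParams(dG_ref=1e4, dH_ref=0.0, stoichiometry=stoichiometry)


@dataclass(frozen=True)
class LinkageParams:
    """Thermodynamic parameters of the five-species scheme."""

    step_NS: ThermalStepParams
    step_NU: ThermalStepParams
    assoc_H: AssociationStepParams
    assoc_H2: AssociationStepParams
    bind_P: AssociationStepParams = field(default_factory=inert_step)

    def __post_init__(self) -> None:
        if self.assoc_H.stoichiometry != 6:
            raise ValueError("assoc_H stoichiometry is fixed at 6")
        if self.assoc_H2.stoichiometry != 2:
            raise ValueError("assoc_H2 stoichiometry is fixed at 2")


@dataclass(frozen=True)
class Conditions:
    """One experimental condition: total monomer, temperature, total peptide."""

    C_tot: float
    T: float
    P_tot: float = 0.0

    def __post_init__(self) -> None:
        if not self.C_tot > 0:
            raise ValueError("C_tot must be > 0")
        if not self.T > 0:
            raise ValueError("T must be > 0 K")
        if self.P_tot < 0:
            raise ValueError("P_tot must be >= 0")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Natural-log equilibrium constants of the five steps at one T."""

    ln_KS: float
    ln_KU: float
    ln_KH: float
    ln_KH2: float
    ln_KP: float

    @property
    def K_S(self) -> float:
        return _safe_exp(self.ln_KS)

    @property
    def K_U(self) -> float:
        return _safe_exp(self.ln_KU)

    @property
    def K_H(self) -> float:
        return _safe_exp(self.ln_KH)

    @property
    def K_H2(self) -> float:
        return _safe_exp(self.ln_KH2)

    @property
    def K_P(self) -> float:
        return _safe_exp(self.ln_KP)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations and per-monomer fractions at one condition.

    H counts 6 monomers and H2 counts 12, so the six fractions sum to 1.
    """

    conc_N: float
    conc_NP: float
    conc_S: float
    conc_U: float
    conc_H: float
    conc_H2: float
    conc_P_free: float
    conditions: Conditions

    @property
    def frac_N(self) -> float:
        return self.conc_N / self.conditions.C_tot

    @property
    def frac_NP(self) -> float:
        return self.conc_NP / self.conditions.C_tot

    @property
    def frac_S(self) -> float:
        return self.conc_S / self.conditions.C_tot

    @property
    def frac_U(self) -> float:
        return self.conc_U / self.conditions.C_tot

    @property
    def frac_H(self) -> float:
        return 6.0 * self.conc_H / self.conditions.C_tot

    @property
    def frac_H2(self) -> float:
        return 12.0 * self.conc_H2 / self.conditions.C_tot

    def fractions(self) -> dict[str, float]:
        return {
            "N": self.frac_N,
            "NP": self.frac_NP,
            "S": self.frac_S,
            "U": self.frac_U,
            "H": self.frac_H,
            "H2": self.frac_H2,
        }


def equilibrium_constants(params: LinkageParams, T: float) -> EquilibriumConstants:
    """ln K = -dG(T)/(R T) for each step, computed in log space."""
    if not T > 0:
        raise ValueError("T must be > 0 K")
    rt = R_GAS * T
    return EquilibriumConstants(
        ln_KS=-float(dg_thermal(params.step_NS, T)) / rt,
        ln_KU=-float(dg_thermal(params.step_NU, T)) / rt,
        ln_KH=-float(params.assoc_H.delta_g(T)) / rt,
        ln_KH2=-float(params.assoc_H2.delta_g(T)) / rt,
        ln_KP=-float(params.bind_P.delta_g(T)) / rt,
    )


def _total_monomer(t: float, K: EquilibriumConstants, C_tot: float, P_tot: float) -> float:
    """Monomer mass balance evaluated at ln[N] = t (log-space, overflow-safe)."""
    ln_s = K.ln_KS + t
    ln_u = K.ln_KU + t
    ln_h = K.ln_KH + 6.0 * ln_s
    ln_h2 = K.ln_KH2 + 2.0 * K.ln_KH + 12.0 * ln_s
    total = _safe_exp(t) + _safe_exp(ln_s) + _safe_exp(ln_u)
    total += 6.0 * _safe_exp(ln_h) + 12.0 * _safe_exp(ln_h2)
    if P_tot > 0.0:
        # NP = P_tot * K_P x / (1 + K_P x), a logistic in ln(K_P x)
        z = K.ln_KP + t
        total += P_tot / (1.0 + _safe_exp(-z)) if z > -_LN_EXP_MAX else 0.0
    return total


def solve_species(params: LinkageParams, cond: Conditions) -> SpeciesState:
    """Solve the coupled equilibria at one condition by bisection on ln[N].

    The monomer mass balance is strictly increasing in [N], so the root is
    unique and bracketed in (0, C_tot]. Returns a :class:`SpeciesState`
    satisfying mass balance and detailed balance to solver tolerance.
    """
    K = equilibrium_constants(params, cond.T)
    C, P = cond.C_tot, cond.P_tot

    hi = math.log(C)
    lo = hi + math.log(1e-14)
    # extend the bracket downward if the monomer pool is K-dominated
    n_extend = 0
    while _total_monomer(lo, K, C, P) >= C:
        lo -= 32.0
        n_extend += 1
        if n_extend > 20:
            raise LinkageSolverError(
                f"could not bracket mass balance: f(lo)={_total_monomer(lo, K, C, P):.3e}"
                f" >= C_tot={C:.3e} at ln x={lo:.1f}"
            )

    for _ in range(300):
        mid = 0.5 * (lo + hi)
        if _total_monomer(mid, K, C, P) > C:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-12:
            break
    else:
        raise LinkageSolverError(
            f"bisection did not converge: bracket [{lo:.15f}, {hi:.15f}]"
        )

    t = 0.5 * (lo + hi)
    x = math.exp(t)
    conc_S = _safe_exp(K.ln_KS + t)
    conc_U = _safe_exp(K.ln_KU + t)
    conc_H = _safe_exp(K.ln_KH + 6.0 * (K.ln_KS + t))
    conc_H2 = _safe_exp(K.ln_KH2 + 2.0 * K.ln_KH + 12.0 * (K.ln_KS + t))
    if P > 0.0:
        z = K.ln_KP + t
        conc_NP = P / (1.0 + _safe_exp(-z)) if z > -_LN_EXP_MAX else 0.0
        conc_P_free = P - conc_NP
    else:
        conc_NP = 0.0
        conc_P_free = 0.0
    return SpeciesState(
        conc_N=x,
        conc_NP=conc_NP,
        conc_S=conc_S,
        conc_U=conc_U,
        conc_H=conc_H,
        conc_H2=conc_H2,
        conc_P_free=conc_P_free,
        conditions=cond,
    )


def monomer_fraction(state: SpeciesState) -> float:
    """Monomeric fraction (N + NP + S + U); complements frac_H + frac_H2."""
    return state.frac_N + state.frac_NP + state.frac_S + state.frac_U


def assembled_fraction(state: SpeciesState) -> float:
    """Fraction of monomers sequestered in hexamer or dodecamer."""
    return state.frac_H + state.frac_H2


def apparent_native_midpoint(
    params: LinkageParams,
    C_tot: float,
    P_tot: float,
    T_grid,
) -> float | None:
    """Temperature at which the native population (N + NP) crosses 0.5.

    Scans the monotone temperature grid, linearly interpolating the first
    downward crossing of 0.5. Returns ``None`` when the native fraction
    never crosses 0.5 on the grid (no transition within the window).
    """
    T_grid = np.asarray(T_grid, float)
    if T_grid.ndim != 1 or len(T_grid) < 2 or np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be a strictly increasing 1-D grid")
    fn = np.array(
        [
            (lambda s: s.frac_N + s.frac_NP)(
                solve_species(params, Conditions(C_tot=C_tot, T=float(T), P_tot=P_tot))
            )
            for T in T_grid
        ]
    )
    g = fn - 0.5
    sign_change = np.nonzero(g[:-1] * g[1:] <= 0)[0]
    sign_change = [i for i in sign_change if g[i] != g[i + 1]]
    if not sign_change:
        return None
    i = sign_change[0]
    w = g[i] / (g[i] - g[i + 1])
    return float(T_grid[i] + w * (T_grid[i + 1] - T_grid[i]))


def peptide_rescue_curve(
    params: LinkageParams,
    C_tot: float,
    T: float,
    P_grid,
) -> CurveTable:
    """Monomer fraction versus total C-peptide at fixed C_tot and T.

    Peptide binding to N pulls the linked equilibria away from the
    assembled species, so the curve is monotone nondecreasing and tends
    to 1 as P_tot grows.
    """
    P_grid = np.asarray(P_grid, float)
    if np.any(P_grid < 0) or np.any(np.diff(P_grid) < 0):
        raise ValueError("P_grid must be nonnegative and sorted")
    y = [
        monomer_fraction(solve_species(params, Conditions(C_tot=C_tot, T=T, P_tot=float(P))))
        for P in P_grid
    ]
    import pandas as pd

    return CurveTable(
        pd.DataFrame({"x": P_grid, "y": y}),
        kind="peptide_titration",
        meta={"C_tot": C_tot, "T": T, "x_units": "M", "y": "monomer_fraction"},
    )
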