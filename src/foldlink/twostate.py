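"""Closed-form two-state folding models.

Three classical descriptions of a two-state folding equilibrium N <-> U:

* chemical denaturation under the linear extrapolation model (LEM),
  dG(D) = dG0 - m_eq * D;
* thermal stability via the Gibbs-Helmholtz relation,
  dG(T) = dHm (1 - T/Tm) + dCp [(T - Tm) - T ln(T/Tm)];
* chevron kinetics, ln k(D) linear in denaturant for each of the folding
  and unfolding rate constants, with the observed relaxation rate being
  their sum.

Units: kJ mol^-1 for energies, M for denaturant, K for temperature,
s^-1 for rates. Kinetic m-values are slopes of R*T*ln k versus D
(kJ mol^-1 M^-1), the single supported convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .constants import R_GAS

__all__ = [
    "LinearBaseline",
    "TwoStateChemParams",
    "ChevronParams",
    "ThermalStepParams",
    "dg_chem",
    "frac_unfolded_chem",
    "signal_chem",
    "dg_thermal",
    "frac_unfolded_thermal",
    "relaxation_rate",
    "folding_rate",
    "unfolding_rate",
]


@dataclass(frozen=True)
class LinearBaseline:
    """Linear signal baseline a + b*x (signal units; slope per M or per K)."""

    a: float = 0.0
    b: float = 0.0

    def __call__(self, x):
        return self.a + self.b * np.asarray(x, float)


@dataclass(frozen=True)
class TwoStateChemParams:
    """Linear-extrapolation-model parameters for chemical denaturation.

    dG0 : unfolding free energy in water, kJ mol^-1.
    m_eq : equilibrium denaturant dependence (m-value), kJ mol^-1 M^-1, > 0.
    native, unfolded : linear signal baselines of the two states.
    """

    dG0: float
    m_eq: float
    native: LinearBaseline = field(default_factory=lambda: LinearBaseline(1.0, 0.0))
    unfolded: LinearBaseline = field(default_factory=LinearBaseline)

    def __post_init__(self) -> None:
        if not self.m_eq > 0:
            raise ValueError("m_eq must be > 0")

    @property
    def Cm(self) -> float:
        """Denaturation midpoint dG0/m_eq, M."""
        return self.dG0 / self.m_eq


@dataclass(frozen=True)
class ChevronParams:
    """Two-state chevron parameters.

    kf0, ku0 : folding/unfolding rate constants in water, s^-1, > 0.
    mf, mu : kinetic m-values (slopes of R*T*ln k vs D), kJ mol^-1 M^-1,
        with mf <= 0 <= mu.
    """

    kf0: float
    ku0: float
    mf: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.kf0 > 0 and self.ku0 > 0):
            raise ValueError("rate constants must be positive")
        if not (self.mf <= 0.0 <= self.mu):
            raise ValueError("require mf <= 0 <= mu")


@dataclass(frozen=True)
class ThermalStepParams:
    """Gibbs-Helmholtz description of one conformational step.

    Tm : midpoint temperature, K (dG(Tm) = 0 exactly).
    dHm : van't Hoff enthalpy at Tm, kJ mol^-1.
    dCp : heat-capacity change, kJ mol^-1 K^-1.
    """

    Tm: float
    dHm: float
    dCp: float = 0.0

    def __post_init__(self) -> None:
        if not self.Tm > 0:
            raise ValueError("Tm must be > 0")

    def delta_h(self, T) -> np.ndarray | float:
        """Step enthalpy at T: dHm + dCp (T - Tm), kJ mol^-1."""
        return self.dHm + self.dCp * (np.asarray(T, float) - self.Tm)


def _check_D(D) -> np.ndarray:
    D = np.asarray(D, float)
    if np.any(D < 0):
        raise ValueError("denaturant concentration must be >= 0")
    return D


def _check_T(T) -> np.ndarray:
    T = np.asarray(T, float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0 K")
    return T


def dg_chem(params: TwoStateChemParams, D):
    """Unfolding free energy dG0 - m_eq*D at denaturant D (kJ mol^-1)."""
    D = _check_D(D)
    return params.dG0 - params.m_eq * D


def frac_unfolded_chem(params: TwoStateChemParams, D, T=298.0):
    """Two-state unfolded population 1/(1 + exp(dG(D)/RT)); 0.5 at Cm."""
    T = _check_T(T)
    dG = dg_chem(params, D)
    return expit(-dG / (R_GAS * T))


def signal_chem(params: TwoStateChemParams, D, T=298.0):
    """Baseline-weighted two-state observable for a denaturation curve."""
    D = _check_D(D)
    fu = frac_unfolded_chem(params, D, T)
    return params.native(D) * (1.0 - fu) + params.unfolded(D) * fu


def dg_thermal(step: ThermalStepParams, T):
    """Gibbs-Helmholtz free energy of the step at T (kJ mol^-1)."""
    T = _check_T(T)
    Tm, dHm, dCp = step.Tm, step.dHm, step.dCp
    return dHm * (1.0 - T / Tm) + dCp * ((T - Tm) - T * np.log(T / Tm))


def frac_unfolded_thermal(step: ThermalStepParams, T):
    """Two-state high-T-state population 1/(1 + exp(dG(T)/RT))."""
    T = _check_T(T)
    return expit(-dg_thermal(step, T) / (R_GAS * T))


def folding_rate(params: ChevronParams, D, T=298.0):
    """kf(D) = kf0 exp(mf D / RT); mf <= 0 so folding slows with D."""
    D, T = _check_D(D), _check_T(T)
    return params.kf0 * np.exp(params.mf * D / (R_GAS * T))


def unfolding_rate(params: ChevronParams, D, T=298.0):
    """ku(D) = ku0 exp(mu D / RT)."""
    D, T = _check_D(D), _check_T(T)
    return params.ku0 * np.exp(params.mu * D / (R_GAS * T))


def relaxation_rate(params: ChevronParams, D, T=298.0, convention="free-energy-slope"):
    """Observed two-state relaxation rate lambda(D) = kf(D) + ku(D), s^-1.

    ``convention`` selects the kinetic m-value interpretation; only
    "free-energy-slope" (ln k = ln k0 + m D / RT, m in kJ mol^-1 M^-1)
    is supported.
    """
    if convention != "free-energy-slope":
        raise ValueError(f"unknown kinetic m-value convention: {convention!r}")
    return folding_rate(params, D, T) + unfolding_rate(params, D, T)
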