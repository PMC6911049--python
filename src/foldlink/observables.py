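"""Forward synthesis of measured signals from the linkage model.

Maps species populations onto the observables actually recorded in the
wet lab: optical melts (population-weighted linear per-species baselines),
DSC excess heat capacity (temperature derivative of the excess enthalpy,
with peak extraction), and species-distribution tables of the kind
resolved by SEC / analytical ultracentrifugation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .linkage import Conditions, LinkageParams, SpeciesState, solve_species
from .curves import CurveTable

__all__ = [
    "SignalBasis",
    "DscTrace",
    "melt_curve",
    "excess_enthalpy",
    "dsc_thermogram",
    "species_distribution",
]

SPECIES = ("N", "NP", "S", "U", "H", "H2")


@dataclass(frozen=True)
class SignalBasis:
    """Per-species linear signal coefficients (intercept, slope per K).

    Species sharing a photophysical state may share coefficients. The
    default mimics tryptophan fluorescence of the native tertiary
    environment: N and NP bright with a common linear baseline; the
    fold-switched, unfolded and assembled species dark (the first
    transition removes the entire fluorescence signal).
    """

    coeffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "N": (1.0, -0.002),
            "NP": (1.0, -0.002),
            "S": (0.0, 0.0),
            "U": (0.0, 0.0),
            "H": (0.0, 0.0),
            "H2": (0.0, 0.0),
        }
    )

    def __post_init__(self) -> None:
        missing = [s for s in SPECIES if s not in self.coeffs]
        if missing:
            raise ValueError(f"missing signal coefficients for species {missing}")

    @classmethod
    def uniform(cls, a: float = 1.0, b: float = 0.0) -> "SignalBasis":
        return cls({s: (a, b) for s in SPECIES})

    @classmethod
    def two_state(cls, a_native=1.0, b_native=0.0, a_other=0.0, b_other=0.0) -> "SignalBasis":
        """Native-bright basis with all non-native species on one baseline."""
        c = {s: (a_other, b_other) for s in SPECIES}
        c["N"] = (a_native, b_native)
        c["NP"] = (a_native, b_native)
        return cls(c)

    def signal(self, state: SpeciesState, T: float) -> float:
        fr = state.fractions()
        return sum(fr[s] * (a + b * T) for s, (a, b) in self.coeffs.items())


@dataclass(frozen=True)
class DscTrace:
    """Excess molar heat capacity trace with detected transition peaks.

    temperature : strictly increasing grid, K.
    cp_excess : excess heat capacity per mole monomer, kJ mol^-1 K^-1.
    peak_temperatures : interior local maxima above the prominence
        threshold, sorted ascending; possibly empty.
    """

    temperature: np.ndarray
    cp_excess: np.ndarray
    peak_temperatures: tuple[float, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T_K": self.temperature, "Cp_excess_kJ_per_mol_K": self.cp_excess}
        )


def melt_curve(
    params: LinkageParams,
    basis: SignalBasis,
    C_tot: float,
    P_tot: float,
    T_grid,
) -> CurveTable:
    """Population-weighted optical melt y(T) = sum_i frac_i (a_i + b_i T)."""
    T_grid = np.asarray(T_grid, float)
    y = [
        basis.signal(solve_species(params, Conditions(C_tot=C_tot, T=float(T), P_tot=P_tot)), float(T))
        for T in T_grid
    ]
    return CurveTable(
        pd.DataFrame({"x": T_grid, "y": y}),
        kind="thermal_melt",
        meta={"C_tot": C_tot, "P_tot": P_tot, "x_units": "K"},
    )


def excess_enthalpy(params: LinkageParams, cond: Conditions) -> float:
    """Excess molar enthalpy per mole monomer, referenced to the N state.

    Each population contributes the enthalpy of reaching it from N:
    S and U carry their step enthalpies; assembled monomers additionally
    carry the per-monomer share of the association enthalpies (1/6 of the
    hexamerization enthalpy; the dodecamer adds 1/12 of the ring-stacking
    enthalpy); NP carries the binding enthalpy.
    """
    st = solve_species(params, cond)
    T = cond.T
    dh_ns = float(params.step_NS.delta_h(T))
    dh_nu = float(params.step_NU.delta_h(T))
    dh_h = float(params.assoc_H.delta_h(T))
    dh_h2 = float(params.assoc_H2.delta_h(T))
    dh_p = float(params.bind_P.delta_h(T))
    return (
        st.frac_S * dh_ns
        + st.frac_U * dh_nu
        + st.frac_H * (dh_ns + dh_h / 6.0)
        + st.frac_H2 * (dh_ns + dh_h / 6.0 + dh_h2 / 12.0)
        + st.frac_NP * dh_p
    )


def dsc_thermogram(
    params: LinkageParams,
    C_tot: float,
    P_tot: float,
    T_grid,
    dT: float = 0.02,
    prominence_frac: float = 0.01,
) -> DscTrace:
    """Excess heat capacity by central differentiation of the excess enthalpy.

    Cp_exc(T) = [h(T+dT) - h(T-dT)] / (2 dT); peaks are interior local
    maxima exceeding ``prominence_frac`` of the trace maximum, with
    three-point parabolic refinement of the peak position. For a pure
    two-state step with dCp = 0 the peak sits at Tm with height
    dHm^2 / (4 R Tm^2).
    """
    T_grid = np.asarray(T_grid, float)
    if not dT > 0:
        raise ValueError("dT must be > 0")
    if np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be strictly increasing")
    if np.min(np.diff(T_grid)) < 2.0 * dT:
        raise ValueError("T_grid spacing must be >= 2*dT for central differences")

    def h(T: float) -> float:
        return excess_enthalpy(params, Conditions(C_tot=C_tot, T=T, P_tot=P_tot))

    cp = np.array([(h(T + dT) - h(T - dT)) / (2.0 * dT) for T in T_grid])

    peaks: list[float] = []
    top = float(np.max(cp)) if len(cp) else 0.0
    if top > 0:
        idx, _ = find_peaks(cp, prominence=prominence_frac * top)
        for i in idx:
            # parabolic refinement on the three points around the maximum
            y0, y1, y2 = cp[i - 1], cp[i], cp[i + 1]
            denom = y0 - 2.0 * y1 + y2
            offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            step = T_grid[i + 1] - T_grid[i] if offset >= 0 else T_grid[i] - T_grid[i - 1]
            peaks.append(float(T_grid[i] + offset * step))
            if i < 2 or i > len(cp) - 3:
                warnings.warn(
                    "DSC peak detected at the grid edge; grid may be too "
                    "coarse or too narrow relative to the transition width",
                    stacklevel=2,
                )
    return DscTrace(
        temperature=T_grid, cp_excess=cp, peak_temperatures=tuple(sorted(peaks))
    )


def species_distribution(
    params: LinkageParams, cond: Conditions, monomer_mass: float
) -> pd.DataFrame:
    """Monomer/hexamer/dodecamer table as resolved by SEC or AUC.

    Rows M (all monomeric species pooled), H and H2 with per-monomer
    fractions summing to 1 and molar masses of 1x, 6x and 12x the
    monomer mass (daltons).
    """
    st = solve_species(params, cond)
    frac_m = st.frac_N + st.frac_NP + st.frac_S + st.frac_U
    return pd.DataFrame(
        {
            "species": ["M", "H", "H2"],
            "monomer_fraction": [frac_m, st.frac_H, st.frac_H2],
            "molar_mass_Da": [monomer_mass, 6.0 * monomer_mass, 12.0 * monomer_mass],
        }
    )
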