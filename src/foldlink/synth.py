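"""Seeded generators for every dataset shape the pipeline consumes.

Each generator evaluates the corresponding forward model on a grid and
adds Gaussian noise: additive and homoscedastic for optical signals
(standard deviation given either in signal units or as a fraction of the
clean-signal range), and additive on ln(rate) for relaxation rates, which
are log-normal in practice.

Determinism: every generator is a pure function of (configuration, seed).
The pseudorandom stream for a dataset is derived from the master seed in
the :class:`NoiseSpec` together with a stable hash of the generator
configuration, so replicate suites never collide streams.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import CurveTable
from .enzyme import initial_velocity
from .linkage import LinkageParams, peptide_rescue_curve
from .observables import SignalBasis, dsc_thermogram, melt_curve
from .twostate import ChevronParams, TwoStateChemParams, relaxation_rate, signal_chem

__all__ = [
    "NoiseSpec",
    "gen_chem_denaturation",
    "gen_chevron",
    "gen_thermal_melts",
    "gen_dsc_series",
    "gen_peptide_titration",
    "gen_velocity_curves",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise description.

    sd : standard deviation; interpreted as a fraction of the clean-signal
        range when ``relative`` is True (the default), in signal units
        otherwise. For rate data the sd is always in ln-rate units.
    seed : master seed of the pseudorandom stream.
    relative : whether sd scales with the clean-signal range.
    """

    sd: float = 0.02
    seed: int = 0
    relative: bool = True

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def _config_hash(*parts) -> str:
    """Stable short hash of an arbitrary generator configuration."""
    blob = json.dumps([repr(p) for p in parts], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _rng_for(noise: NoiseSpec, config_hash: str) -> np.random.Generator:
    child = int(config_hash, 16) % (2**32)
    return np.random.default_rng(np.random.SeedSequence([noise.seed, child]))


def _abs_sd(noise: NoiseSpec, clean: np.ndarray) -> float:
    if not noise.relative:
        return noise.sd
    rng_span = float(np.max(clean) - np.min(clean))
    return noise.sd * (rng_span if rng_span > 0 else 1.0)


def _provenance(noise: NoiseSpec, config_hash: str) -> dict:
    return {"seed": noise.seed, "config_hash": config_hash, "noise_sd": noise.sd,
            "noise_relative": noise.relative}


def gen_chem_denaturation(
    params: TwoStateChemParams, D_grid, T: float, noise: NoiseSpec
) -> CurveTable:
    """Noisy two-state chemical-denaturation curve (signal vs denaturant)."""
    D_grid = np.asarray(D_grid, float)
    if len(D_grid) < 8 or np.any(np.diff(D_grid) < 0):
        raise ValueError("D_grid must be sorted with at least 8 points")
    if not (D_grid[0] < params.Cm < D_grid[-1]):
        warnings.warn("denaturant grid does not span the transition midpoint", stacklevel=2)
    clean = signal_chem(params, D_grid, T)
    h = _config_hash("chem", params, D_grid.tolist(), T)
    sd = _abs_sd(noise, clean)
    y = clean + _rng_for(noise, h).normal(0.0, sd, size=len(D_grid)) if sd > 0 else clean
    return CurveTable(
        pd.DataFrame({"x": D_grid, "y": y, "sigma": sd}),
        kind="chem_denaturation",
        meta={"T": T, "x_units": "M"},
        provenance=_provenance(noise, h),
    )


def gen_chevron(
    params: ChevronParams, D_grid, T: float, noise: NoiseSpec
) -> CurveTable:
    """Noisy chevron dataset: relaxation rate vs denaturant.

    Noise is applied on ln(rate) with sd in ln units (``relative`` is
    ignored), so rates stay positive and errors are log-normal.
    """
    D_grid = np.asarray(D_grid, float)
    if np.any(np.diff(D_grid) < 0):
        raise ValueError("D_grid must be sorted")
    lam = relaxation_rate(params, D_grid, T)
    h = _config_hash("chevron", params, D_grid.tolist(), T)
    ln_lam = np.log(lam)
    if noise.sd > 0:
        ln_lam = ln_lam + _rng_for(noise, h).normal(0.0, noise.sd, size=len(D_grid))
    return CurveTable(
        pd.DataFrame({"x": D_grid, "y": np.exp(ln_lam), "sigma": noise.sd}),
        kind="chevron",
        meta={"T": T, "x_units": "M", "sigma_units": "ln_rate"},
        provenance=_provenance(noise, h),
    )


def gen_thermal_melts(
    params: LinkageParams,
    basis: SignalBasis,
    C_tot_list,
    T_grid,
    noise: NoiseSpec,
    P_tot: float = 0.0,
) -> CurveTable:
    """Stack of noisy optical melts, one series per protein concentration."""
    frames = []
    h = _config_hash("melts", params, basis, list(C_tot_list), np.asarray(T_grid).tolist(), P_tot)
    rng = _rng_for(noise, h)
    for C in C_tot_list:
        clean_tab = melt_curve(params, basis, C, P_tot, T_grid)
        clean = clean_tab.y
        sd = _abs_sd(noise, clean)
        y = clean + rng.normal(0.0, sd, size=len(clean)) if sd > 0 else clean
        frames.append(
            pd.DataFrame(
                {"x": clean_tab.x, "y": y, "sigma": sd, "series": C, "C_tot": C,
                 "P_tot": P_tot}
            )
        )
    return CurveTable(
        pd.concat(frames, ignore_index=True),
        kind="thermal_melt",
        meta={"P_tot": P_tot, "x_units": "K"},
        provenance=_provenance(noise, h),
    )


def gen_dsc_series(
    params: LinkageParams, C_tot_list, T_grid, noise: NoiseSpec, P_tot: float = 0.0
) -> CurveTable:
    """Stack of noisy DSC thermograms, one series per protein concentration."""
    frames = []
    h = _config_hash("dsc", params, list(C_tot_list), np.asarray(T_grid).tolist(), P_tot)
    rng = _rng_for(noise, h)
    for C in C_tot_list:
        trace = dsc_thermogram(params, C, P_tot, T_grid)
        clean = trace.cp_excess
        sd = _abs_sd(noise, clean)
        y = clean + rng.normal(0.0, sd, size=len(clean)) if sd > 0 else clean
        frames.append(
            pd.DataFrame(
                {"x": trace.temperature, "y": y, "sigma": sd, "series": C, "C_tot": C}
            )
        )
    return CurveTable(
        pd.concat(frames, ignore_index=True),
        kind="dsc",
        meta={"P_tot": P_tot, "x_units": "K", "y_units": "kJ_per_mol_K"},
        provenance=_provenance(noise, h),
    )


def gen_peptide_titration(
    params: LinkageParams, C_tot: float, T: float, P_grid, noise: NoiseSpec
) -> CurveTable:
    """Noisy monomer-recovery curve versus total C-peptide."""
    clean_tab = peptide_rescue_curve(params, C_tot, T, P_grid)
    clean = clean_tab.y
    h = _config_hash("peptide", params, C_tot, T, np.asarray(P_grid).tolist())
    sd = _abs_sd(noise, clean)
    y = clean + _rng_for(noise, h).normal(0.0, sd, size=len(clean)) if sd > 0 else clean
    return CurveTable(
        pd.DataFrame({"x": clean_tab.x, "y": y, "sigma": sd}),
        kind="peptide_titration",
        meta={"C_tot": C_tot, "T": T, "x_units": "M"},
        provenance=_provenance(noise, h),
    )


def gen_velocity_curves(Vmax: float, Km_app: float, S_grid, noise: NoiseSpec) -> CurveTable:
    """Noisy Michaelis-Menten initial-velocity curve versus substrate."""
    S_grid = np.asarray(S_grid, float)
    clean = initial_velocity(Vmax, Km_app, S_grid)
    h = _config_hash("velocity", Vmax, Km_app, S_grid.tolist())
    sd = _abs_sd(noise, clean)
    y = clean + _rng_for(noise, h).normal(0.0, sd, size=len(clean)) if sd > 0 else clean
    return CurveTable(
        pd.DataFrame({"x": S_grid, "y": y, "sigma": sd}),
        kind="velocity",
        meta={"x_units": "M"},
        provenance=_provenance(noise, h),
    )
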