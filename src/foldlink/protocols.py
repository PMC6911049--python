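"""Reference simulate-and-refit recovery protocols for the packaged fixtures.

These wrap the generators and fitters into the standard benchmark used
throughout the documentation: generate seeded replicates from the fixture
parameters, refit each, and summarize the recovered parameters. Chemical
denaturation uses 25 points across the transition with 2% (of range)
Gaussian noise; chevrons use 20 points spanning both arms with 1% noise
on ln(rate), summarized by the geometric mean (rates are log-normal).
"""

from __future__ import annotations

import numpy as np

from . import config
from .constants import R_GAS
from .estimation import fit_chevron, fit_lem, recovery_study
from .results import RecoveryReport
from .synth import NoiseSpec, gen_chem_denaturation, gen_chevron

__all__ = ["lem_recovery", "chevron_recovery", "chevron_grid"]

_D_MAX = {"ci2_wt": 7.0, "ci2_eng": 5.0}


def lem_recovery(
    variant: str,
    R: int = 100,
    master_seed: int = 1,
    noise_sd: float = 0.02,
    n_points: int = 25,
) -> RecoveryReport:
    """Replicate LEM recovery of dG0 and Cm for ``"ci2_wt"``/``"ci2_eng"``."""
    params = config.chem_params(variant)
    D = np.linspace(0.0, _D_MAX[variant], n_points)
    return recovery_study(
        generate=lambda s: gen_chem_denaturation(
            params, D, 298.0, NoiseSpec(sd=noise_sd, seed=s)
        ),
        fitter=fit_lem,
        true_params={"dG0": params.dG0, "m_eq": params.m_eq, "Cm": params.Cm},
        R=R,
        master_seed=master_seed,
        noise_sd=noise_sd,
    )


def chevron_grid(variant: str, n_points: int = 20, T: float = 298.0) -> np.ndarray:
    """Denaturant grid spanning both chevron arms: [0, 2 x minimum].

    The chevron minimum sits where the two exponential arms balance,
    D_min = RT ln(kf0 |mf| / (ku0 mu)) / (mu - mf).
    """
    p = config.chevron_params(variant)
    rt = R_GAS * T
    d_min = rt * np.log((p.kf0 * -p.mf) / (p.ku0 * p.mu)) / (p.mu - p.mf)
    return np.linspace(0.0, 2.0 * d_min, n_points)


def chevron_recovery(
    variant: str,
    R: int = 100,
    master_seed: int = 1,
    noise_sd: float = 0.01,
    n_points: int = 20,
) -> dict:
    """Replicate chevron recovery; geometric-mean rate constants.

    Returns a summary dict with geometric means of kf0/ku0, arithmetic
    means of the kinetic m-values, and the failure count.
    """
    params = config.chevron_params(variant)
    D = chevron_grid(variant, n_points)
    seeds = np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=R)
    ln_kf, ln_ku, mf, mu, failed = [], [], [], [], 0
    for s in seeds:
        try:
            fit = fit_chevron(
                gen_chevron(params, D, 298.0, NoiseSpec(sd=noise_sd, seed=int(s)))
            )
        except Exception:
            failed += 1
            continue
        if not fit.converged:
            failed += 1
            continue
        ln_kf.append(np.log(fit["kf0"]))
        ln_ku.append(np.log(fit["ku0"]))
        mf.append(fit["mf"])
        mu.append(fit["mu"])
    return {
        "kf0_geomean": float(np.exp(np.mean(ln_kf))),
        "ku0_geomean": float(np.exp(np.mean(ln_ku))),
        "mf_mean": float(np.mean(mf)),
        "mu_mean": float(np.mean(mu)),
        "n_replicates": R,
        "n_failed": failed,
        "true": {"kf0": params.kf0, "ku0": params.ku0, "mf": params.mf, "mu": params.mu},
    }
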