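"""Shared fixtures: printed parameter sets and linkage-model helpers."""

import numpy as np
import pytest

from foldlink import config
from foldlink.constants import R_GAS
from foldlink.linkage import AssociationStepParams, LinkageParams
from foldlink.twostate import ThermalStepParams


@pytest.fixture(scope="session")
def wt_chem():
    return config.chem_params("ci2_wt")


@pytest.fixture(scope="session")
def eng_chem():
    return config.chem_params("ci2_eng")


@pytest.fixture(scope="session")
def wt_chevron():
    return config.chevron_params("ci2_wt")


@pytest.fixture(scope="session")
def eng_chevron():
    return config.chevron_params("ci2_eng")


@pytest.fixture(scope="session")
def eng_linkage():
    return config.linkage_params("ci2_eng")


@pytest.fixture(scope="session")
def trunc_linkage():
    """CI2_1-58 fixture with active C-peptide binding."""
    return config.linkage_params("ci2_1_58")


def linkage_from_constants(
    K_S, K_U, K_H, K_H2, K_P, T=298.0
) -> LinkageParams:
    """Build LinkageParams realizing given equilibrium constants at T.

    Conformational steps use a Gibbs-Helmholtz step with Tm = 2T (so
    dG(T) = dHm/2 = -RT ln K); association steps pin dG_ref at T.
    K = 0 is encoded as a hugely unfavorable step.
    """
    rt = R_GAS * T

    def conf(K):
        if K == 0:
            return ThermalStepParams(Tm=2 * T, dHm=2e4, dCp=0.0)
        return ThermalStepParams(Tm=2 * T, dHm=-2 * rt * np.log(K), dCp=0.0)

    def assoc(K, n):
        dg = 1e4 if K == 0 else -rt * float(np.log(K))
        return AssociationStepParams(dG_ref=dg, dH_ref=0.0, T_ref=T, stoichiometry=n)

    return LinkageParams(
        step_NS=conf(K_S),
        step_NU=conf(K_U),
        assoc_H=assoc(K_H, 6),
        assoc_H2=assoc(K_H2, 2),
        bind_P=assoc(K_P, 1),
    )


def grid_scan_monomer(params: LinkageParams, C_tot, T, P_tot=0.0):
    """Independent oracle: locate [N] by scanning the mass balance on a grid.

    Two-stage scan (coarse log grid, then fine linear grid between the
    bracketing points) entirely independent of the package's bisection
    path: species terms are evaluated directly from the equilibrium
    constants with explicit powers.
    """
    from foldlink.linkage import equilibrium_constants

    K = equilibrium_constants(params, T)
    ks, ku = K.K_S, K.K_U
    kp = K.K_P

    def total(x):
        s = ks * x
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            t = x + s + ku * x + 6.0 * np.exp(K.ln_KH + 6 * np.log(s)) \
                + 12.0 * np.exp(K.ln_KH2 + 2 * K.ln_KH + 12 * np.log(s))
            if P_tot > 0:
                t = t + P_tot * kp * x / (1.0 + kp * x)
        return t

    x = np.logspace(np.log10(C_tot) - 14, np.log10(C_tot), 200_000)
    tot = total(x)
    i = int(np.argmax(tot >= C_tot))
    lo = x[i - 1] if i > 0 else x[0]
    x2 = np.linspace(lo, x[i], 200_000)
    tot2 = total(x2)
    j = int(np.argmax(tot2 >= C_tot))
    return float(x2[j])
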