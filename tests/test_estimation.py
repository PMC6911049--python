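"""Fitting layer: noise-free identity, consistency, global linkage fits."""

import dataclasses

import numpy as np
import pytest

from foldlink.estimation import (
    fit_chevron,
    fit_lem,
    fit_linkage_global,
    fit_thermal_two_state,
    recovery_study,
)
from foldlink.linkage import LinkageParams
from foldlink.observables import SignalBasis
from foldlink.synth import (
    NoiseSpec,
    gen_chem_denaturation,
    gen_chevron,
    gen_peptide_titration,
    gen_thermal_melts,
)
from foldlink.twostate import LinearBaseline, ThermalStepParams, TwoStateChemParams

from conftest import linkage_from_constants

D25 = np.linspace(0.0, 7.0, 25)


class TestFitLem:
    def test_noise_free_identity_wt(self, wt_chem):
        curve = gen_chem_denaturation(wt_chem, D25, 298.0, NoiseSpec(sd=0.0, seed=0))
        fit = fit_lem(curve)
        assert fit.converged
        assert fit["dG0"] == pytest.approx(30.9, rel=1e-6)
        assert fit.extras["Cm"] == pytest.approx(4.07, rel=1e-6)

    def test_noise_free_identity_eng(self, eng_chem):
        curve = gen_chem_denaturation(
            eng_chem, np.linspace(0.0, 5.0, 25), 298.0, NoiseSpec(sd=0.0, seed=0)
        )
        fit = fit_lem(curve)
        assert fit["dG0"] == pytest.approx(10.9, rel=1e-6)
        assert fit.extras["Cm"] == pytest.approx(1.28, rel=1e-6)

    def test_midpoint_bias_small_at_two_percent_noise(self, wt_chem):
        cms = [
            fit_lem(gen_chem_denaturation(wt_chem, D25, 298.0, NoiseSpec(sd=0.02, seed=s))).extras["Cm"]
            for s in range(40)
        ]
        assert abs(np.mean(cms) - 4.07) / 4.07 < 0.01


class TestFitChevron:
    def test_noise_free_identity_wt(self, wt_chevron):
        D = np.linspace(0.0, 49.0, 20)
        fit = fit_chevron(gen_chevron(wt_chevron, D, 298.0, NoiseSpec(sd=0.0, seed=0)))
        assert fit.converged and not fit.extras["ill_conditioned"]
        assert fit["kf0"] == pytest.approx(44.0, rel=1e-6)
        assert fit["ku0"] == pytest.approx(1.9e-4, rel=1e-6)
        assert fit["mf"] == pytest.approx(-0.78, rel=1e-6)
        assert fit["mu"] == pytest.approx(0.51, rel=1e-6)

    def test_noise_free_identity_eng(self, eng_chevron):
        D = np.linspace(0.0, 15.0, 20)
        fit = fit_chevron(gen_chevron(eng_chevron, D, 298.0, NoiseSpec(sd=0.0, seed=0)))
        assert fit["kf0"] == pytest.approx(25.0, rel=1e-6)
        assert fit["ku0"] == pytest.approx(0.58, rel=1e-6)

    def test_single_arm_flagged_ill_conditioned(self, wt_chevron):
        D = np.linspace(0.0, 7.0, 12)  # folding arm only for these parameters
        with pytest.warns(UserWarning, match="ill-conditioned"):
            fit = fit_chevron(gen_chevron(wt_chevron, D, 298.0, NoiseSpec(sd=0.0, seed=0)))
        assert fit.extras["ill_conditioned"]


class TestFitThermal:
    def test_noise_free_identity(self, eng_linkage):
        p = linkage_from_constants(K_S=0.0, K_U=1.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        p = dataclasses.replace(p, step_NU=ThermalStepParams(Tm=337.0, dHm=300.0))
        T = np.arange(305.0, 370.0, 0.5)
        curve = gen_thermal_melts(p, SignalBasis(), [1e-4], T, NoiseSpec(sd=0.0, seed=0))
        fit = fit_thermal_two_state(curve.get_series(1e-4))
        assert fit.converged
        assert fit["Tm"] == pytest.approx(337.0, abs=1e-3)
        assert fit["dHm"] == pytest.approx(300.0, rel=1e-4)

    def test_tm_recovery_within_tenth_kelvin_at_one_percent_noise(self):
        p = linkage_from_constants(K_S=0.0, K_U=1.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        p = dataclasses.replace(p, step_NU=ThermalStepParams(Tm=337.0, dHm=300.0))
        T = np.arange(305.0, 370.0, 0.5)
        tms = []
        for s in range(10):
            curve = gen_thermal_melts(p, SignalBasis(), [1e-4], T, NoiseSpec(sd=0.01, seed=s))
            tms.append(fit_thermal_two_state(curve.get_series(1e-4))["Tm"])
        assert abs(np.mean(tms) - 337.0) < 0.1

    def test_narrow_grid_warns_about_confounding(self):
        p = linkage_from_constants(K_S=0.0, K_U=1.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        p = dataclasses.replace(p, step_NU=ThermalStepParams(Tm=337.0, dHm=300.0))
        T = np.arange(330.0, 344.0, 0.5)  # covers only the transition core
        curve = gen_thermal_melts(p, SignalBasis(), [1e-4], T, NoiseSpec(sd=0.0, seed=0))
        with pytest.warns(UserWarning, match="confounded"):
            fit_thermal_two_state(curve.get_series(1e-4))


class TestFitLinkageGlobal:
    def test_multi_concentration_melt_recovery(self, eng_linkage):
        """Free switch-step Tm and hexamer dG recovered within 5% at 1% noise."""
        T = np.arange(287.0, 379.0, 1.0)
        series = gen_thermal_melts(
            eng_linkage, SignalBasis(), [6e-6, 6e-5, 6e-4], T, NoiseSpec(sd=0.01, seed=4)
        )
        start = eng_linkage
        start = dataclasses.replace(
            start, step_NS=dataclasses.replace(start.step_NS, Tm=350.0)
        )
        start = dataclasses.replace(
            start, assoc_H=dataclasses.replace(start.assoc_H, dG_ref=-150.0)
        )
        fit = fit_linkage_global(
            series, start, ["step_NS.Tm", "assoc_H.dG_ref"], basis=SignalBasis(), n_restarts=3
        )
        assert fit.converged
        assert fit["step_NS.Tm"] == pytest.approx(359.0, rel=0.05)
        assert fit["assoc_H.dG_ref"] == pytest.approx(-166.0, rel=0.05)

    def test_peptide_titration_recovers_binding_constant(self, trunc_linkage):
        """Free peptide-binding dG recovered within 10% from a titration."""
        P = np.concatenate([[0.0], np.logspace(-5, -2, 20)])
        series = gen_peptide_titration(trunc_linkage, 80e-6, 298.0, P, NoiseSpec(sd=0.01, seed=8))
        series.meta["C_tot"], series.meta["T"] = 80e-6, 298.0
        start = dataclasses.replace(
            trunc_linkage, bind_P=dataclasses.replace(trunc_linkage.bind_P, dG_ref=-15.0)
        )
        fit = fit_linkage_global(series, start, ["bind_P.dG_ref"], n_restarts=3)
        assert fit.converged
        assert fit["bind_P.dG_ref"] == pytest.approx(-19.0, rel=0.10)

    def test_unidentifiable_mask_rejected(self, eng_linkage):
        T = np.arange(300.0, 370.0, 2.0)
        series = gen_thermal_melts(eng_linkage, SignalBasis(), [6e-4], T, NoiseSpec(sd=0.0, seed=0))
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_linkage_global(series, eng_linkage, ["assoc_H.dG_ref"], basis=SignalBasis())

    def test_nested_two_state_limit_matches_thermal_fit(self):
        """With assembly disabled the global fit reduces to the two-state fit."""
        p = linkage_from_constants(K_S=0.0, K_U=1.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        p = dataclasses.replace(p, step_NU=ThermalStepParams(Tm=337.0, dHm=300.0))
        T = np.arange(305.0, 370.0, 0.5)
        series = gen_thermal_melts(p, SignalBasis(), [1e-4], T, NoiseSpec(sd=0.005, seed=2))
        start = dataclasses.replace(p, step_NU=ThermalStepParams(Tm=330.0, dHm=250.0))
        glob = fit_linkage_global(
            series, start, ["step_NU.Tm", "step_NU.dHm"], basis=SignalBasis(), n_restarts=3
        )
        direct = fit_thermal_two_state(series.get_series(1e-4))
        assert glob["step_NU.Tm"] == pytest.approx(direct["Tm"], abs=0.05)
        assert glob["step_NU.dHm"] == pytest.approx(direct["dHm"], rel=0.01)


class TestRecoveryStudy:
    def test_single_noise_free_replicate_has_zero_bias(self, wt_chem):
        report = recovery_study(
            generate=lambda s: gen_chem_denaturation(wt_chem, D25, 298.0, NoiseSpec(sd=0.0, seed=s)),
            fitter=fit_lem,
            true_params={"dG0": 30.9, "Cm": 4.07},
            R=1,
            master_seed=0,
        )
        assert report.n_failed == 0
        assert abs(report.param("dG0")["bias"]) < 1e-4
        assert report.param("dG0")["rmse"] >= abs(report.param("dG0")["bias"])

    def test_rmse_nonincreasing_as_noise_shrinks(self, wt_chem):
        rmses = []
        for sd in (0.02, 0.01, 0.005):
            rep = recovery_study(
                generate=lambda s, sd=sd: gen_chem_denaturation(
                    wt_chem, D25, 298.0, NoiseSpec(sd=sd, seed=s)
                ),
                fitter=fit_lem,
                true_params={"dG0": 30.9},
                R=25,
                master_seed=42,
                noise_sd=sd,
            )
            rmses.append(rep.param("dG0")["rmse"])
        assert rmses[0] >= rmses[1] >= rmses[2]

    def test_failures_are_counted_not_dropped(self, wt_chem):
        def flaky_fitter(curve):
            if curve.provenance["seed"] % 2 == 0:
                raise RuntimeError("synthetic failure")
            return fit_lem(curve)

        report = recovery_study(
            generate=lambda s: gen_chem_denaturation(wt_chem, D25, 298.0, NoiseSpec(sd=0.01, seed=s)),
            fitter=flaky_fitter,
            true_params={"dG0": 30.9},
            R=10,
            master_seed=1,
        )
        assert report.n_failed > 0
        assert report.n_failed + len(
            [1 for _ in range(report.n_replicates - report.n_failed)]
        ) == report.n_replicates
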