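"""Five-species linkage solver: constants, mass balance, linkage behavior."""

import numpy as np
import pytest

from foldlink.constants import R_GAS
from foldlink.linkage import (
    AssociationStepParams,
    Conditions,
    LinkageParams,
    apparent_native_midpoint,
    assembled_fraction,
    equilibrium_constants,
    monomer_fraction,
    peptide_rescue_curve,
    solve_species,
)
from foldlink.twostate import ThermalStepParams

from conftest import grid_scan_monomer, linkage_from_constants


class TestEquilibriumConstants:
    def test_zero_free_energy_gives_unit_constant(self):
        p = linkage_from_constants(K_S=1.0, K_U=0.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        K = equilibrium_constants(p, 298.0)
        assert K.K_S == pytest.approx(1.0, rel=1e-12)

    def test_unit_constant_at_unfolding_midpoint(self):
        p = LinkageParams(
            step_NS=ThermalStepParams(Tm=359.0, dHm=100.0),
            step_NU=ThermalStepParams(Tm=337.0, dHm=300.0),
            assoc_H=AssociationStepParams(dG_ref=-100.0, dH_ref=0.0, stoichiometry=6),
            assoc_H2=AssociationStepParams(dG_ref=-20.0, dH_ref=0.0, stoichiometry=2),
        )
        assert equilibrium_constants(p, 337.0).K_U == pytest.approx(1.0, rel=1e-12)

    def test_association_log_constant_hand_value(self):
        p = LinkageParams(
            step_NS=ThermalStepParams(Tm=359.0, dHm=100.0),
            step_NU=ThermalStepParams(Tm=337.0, dHm=300.0),
            assoc_H=AssociationStepParams(dG_ref=-170.0, dH_ref=0.0, T_ref=298.0, stoichiometry=6),
            assoc_H2=AssociationStepParams(dG_ref=-20.0, dH_ref=0.0, stoichiometry=2),
        )
        # ln K_H = 170 / (R * 298)
        assert equilibrium_constants(p, 298.0).ln_KH == pytest.approx(
            170.0 / (R_GAS * 298.0), rel=1e-12
        )

    def test_stoichiometries_are_fixed(self):
        with pytest.raises(ValueError):
            LinkageParams(
                step_NS=ThermalStepParams(Tm=359.0, dHm=100.0),
                step_NU=ThermalStepParams(Tm=337.0, dHm=300.0),
                assoc_H=AssociationStepParams(dG_ref=-170.0, dH_ref=0.0, stoichiometry=4),
                assoc_H2=AssociationStepParams(dG_ref=-20.0, dH_ref=0.0, stoichiometry=2),
            )


class TestSolveSpecies:
    def test_inert_monomer(self):
        p = linkage_from_constants(K_S=0.0, K_U=0.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        st = solve_species(p, Conditions(C_tot=1e-3, T=298.0))
        assert st.frac_N == pytest.approx(1.0, abs=1e-9)
        assert monomer_fraction(st) == pytest.approx(1.0, abs=1e-9)

    def test_two_state_split(self):
        p = linkage_from_constants(K_S=1.0, K_U=0.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        st = solve_species(p, Conditions(C_tot=1e-3, T=298.0))
        assert st.frac_N == pytest.approx(0.5, abs=1e-9)
        assert st.frac_S == pytest.approx(0.5, abs=1e-9)

    def test_derived_case_matches_grid_scan_oracle(self):
        p = linkage_from_constants(K_S=0.1, K_U=0.0, K_H=1e30, K_H2=1e4, K_P=0.0)
        cond = Conditions(C_tot=1e-3, T=298.0)
        st = solve_species(p, cond)
        x = grid_scan_monomer(p, cond.C_tot, cond.T)
        K = equilibrium_constants(p, cond.T)
        s = K.K_S * x
        assert st.frac_N == pytest.approx(x / cond.C_tot, abs=1e-6)
        assert st.frac_S == pytest.approx(s / cond.C_tot, abs=1e-6)
        assert st.frac_H == pytest.approx(6 * K.K_H * s**6 / cond.C_tot, abs=1e-6)
        assert st.frac_H2 == pytest.approx(
            12 * K.K_H2 * (K.K_H * s**6) ** 2 / cond.C_tot, abs=1e-6
        )
        assert monomer_fraction(st) == pytest.approx((x + s) / cond.C_tot, abs=1e-6)

    def test_oracle_equivalence_randomized(self):
        """solve_species matches the dense grid scan on 50 random systems."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = linkage_from_constants(
                K_S=10.0 ** rng.uniform(-3, 2),
                K_U=10.0 ** rng.uniform(-4, 1),
                K_H=10.0 ** rng.uniform(5, 32),
                K_H2=10.0 ** rng.uniform(0, 6),
                K_P=10.0 ** rng.uniform(1, 5),
            )
            C = 10.0 ** rng.uniform(-6, -2)
            P = rng.choice([0.0, 10.0 ** rng.uniform(-5, -2)])
            st = solve_species(p, Conditions(C_tot=C, T=298.0, P_tot=P))
            x = grid_scan_monomer(p, C, 298.0, P)
            assert st.conc_N == pytest.approx(x, rel=2e-5, abs=1e-18)
            for f in st.fractions().values():
                assert -1e-12 <= f <= 1 + 1e-12

    def test_mass_conservation_random_draws(self):
        """Monomer and peptide mass balances hold to 1e-9 relative, 1000 draws."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = linkage_from_constants(
                K_S=10.0 ** rng.uniform(-3, 2),
                K_U=10.0 ** rng.uniform(-4, 2),
                K_H=10.0 ** rng.uniform(0, 32),
                K_H2=10.0 ** rng.uniform(0, 8),
                K_P=10.0 ** rng.uniform(0, 6),
                T=rng.uniform(273.0, 380.0),
            )
            C = 10.0 ** rng.uniform(-7, -2)
            P = rng.choice([0.0, 10.0 ** rng.uniform(-6, -2)])
            cond = Conditions(C_tot=C, T=p.step_NS.Tm / 2, P_tot=P)
            st = solve_species(p, cond)
            total = (
                st.conc_N + st.conc_NP + st.conc_S + st.conc_U
                + 6 * st.conc_H + 12 * st.conc_H2
            )
            assert total == pytest.approx(C, rel=1e-9)
            assert st.conc_P_free + st.conc_NP == pytest.approx(P, rel=1e-9, abs=1e-21)

    def test_detailed_balance_on_returned_state(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            p = linkage_from_constants(
                K_S=10.0 ** rng.uniform(-2, 2),
                K_U=10.0 ** rng.uniform(-2, 2),
                K_H=10.0 ** rng.uniform(5, 30),
                K_H2=10.0 ** rng.uniform(0, 6),
                K_P=10.0 ** rng.uniform(1, 5),
            )
            C = 10.0 ** rng.uniform(-6, -2)
            cond = Conditions(C_tot=C, T=298.0, P_tot=1e-4)
            st = solve_species(p, cond)
            K = equilibrium_constants(p, 298.0)
            assert st.conc_S / st.conc_N == pytest.approx(K.K_S, rel=1e-8)
            if st.conc_H > 0 and np.isfinite(st.conc_S**6) and st.conc_S**6 > 0:
                assert st.conc_H / st.conc_S**6 == pytest.approx(K.K_H, rel=1e-8)
            if st.conc_H2 > 0 and st.conc_H**2 > 0:
                assert st.conc_H2 / st.conc_H**2 == pytest.approx(K.K_H2, rel=1e-8)
            if st.conc_P_free > 0:
                assert st.conc_NP / (st.conc_N * st.conc_P_free) == pytest.approx(
                    K.K_P, rel=1e-8
                )

    def test_dilute_limit_reduces_to_three_state_monomer(self):
        """As C_tot -> 0 populations follow 1 : K_S : K_U exactly."""
        p = linkage_from_constants(K_S=0.5, K_U=2.0, K_H=1e25, K_H2=1e4, K_P=0.0)
        st = solve_species(p, Conditions(C_tot=1e-12, T=298.0))
        z = 1.0 + 0.5 + 2.0
        assert st.frac_N == pytest.approx(1.0 / z, rel=1e-8)
        assert st.frac_S == pytest.approx(0.5 / z, rel=1e-8)
        assert st.frac_U == pytest.approx(2.0 / z, rel=1e-8)

    def test_fractions_sum_to_one(self, eng_linkage):
        for T in (290.0, 315.0, 340.0, 365.0):
            st = solve_species(eng_linkage, Conditions(C_tot=6e-4, T=T))
            assert sum(st.fractions().values()) == pytest.approx(1.0, abs=1e-9)


class TestLinkageBehavior:
    def test_assembled_fraction_nondecreasing_in_concentration(self, eng_linkage):
        fa = [
            assembled_fraction(solve_species(eng_linkage, Conditions(C_tot=C, T=315.0)))
            for C in (6e-6, 6e-5, 2e-4, 6e-4)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fa, fa[1:]))

    def test_assembly_rises_then_falls_with_temperature(self, eng_linkage):
        T = np.linspace(285.0, 380.0, 96)
        fa = np.array(
            [assembled_fraction(solve_species(eng_linkage, Conditions(C_tot=6e-4, T=t))) for t in T]
        )
        i = int(np.argmax(fa))
        assert 0 < i < len(T) - 1
        assert fa[i] > 0.5
        assert fa[0] < 0.05 and fa[-1] < 0.05

    def test_native_midpoint_decreases_with_concentration(self, eng_linkage):
        grid = np.arange(285.0, 380.0, 0.25)
        mid_lo = apparent_native_midpoint(eng_linkage, 6e-6, 0.0, grid)
        mid_hi = apparent_native_midpoint(eng_linkage, 6e-4, 0.0, grid)
        assert mid_lo is not None and mid_hi is not None
        assert mid_hi < mid_lo

    def test_two_state_limit_recovers_closed_form_midpoint(self):
        p = linkage_from_constants(K_S=0.0, K_U=1.0, K_H=0.0, K_H2=0.0, K_P=0.0)
        # disable assembly entirely; step_NU Tm = 337 by direct construction
        p = LinkageParams(
            step_NS=p.step_NS,
            step_NU=ThermalStepParams(Tm=337.0, dHm=300.0),
            assoc_H=p.assoc_H,
            assoc_H2=p.assoc_H2,
            bind_P=p.bind_P,
        )
        grid = np.arange(320.0, 355.0, 0.02)
        mid = apparent_native_midpoint(p, 1e-4, 0.0, grid)
        assert mid == pytest.approx(337.0, abs=0.05)

    def test_no_transition_returns_none(self, eng_linkage):
        assert apparent_native_midpoint(eng_linkage, 6e-6, 0.0, np.arange(280.0, 285.0, 1.0)) is None

    def test_rescue_monotone_and_saturating(self, trunc_linkage):
        P = np.concatenate([[0.0], np.logspace(-5, -1, 30)])
        tab = peptide_rescue_curve(trunc_linkage, 80e-6, 298.0, P)
        y = tab.y
        assert np.all(np.diff(y) >= -1e-10)
        assert y[-1] > 0.99

    def test_inert_peptide_gives_flat_curve(self, eng_linkage):
        P = np.linspace(0.0, 4e-3, 12)
        tab = peptide_rescue_curve(eng_linkage, 6e-4, 315.0, P)
        assert np.ptp(tab.y) < 1e-9

    def test_zero_peptide_entry_consistent_with_direct_solution(self, trunc_linkage):
        tab = peptide_rescue_curve(trunc_linkage, 80e-6, 298.0, np.array([0.0, 1e-3]))
        direct = monomer_fraction(solve_species(trunc_linkage, Conditions(C_tot=80e-6, T=298.0)))
        assert tab.y[0] == pytest.approx(direct, rel=1e-12)

    def test_half_rescue_needs_more_peptide_when_warm(self, trunc_linkage):
        """Temperature and C-peptide compete: warmer assemblies resist rescue."""
        P = np.concatenate([[0.0], np.logspace(-6, -0.5, 60)])
        half = {}
        for T in (298.0, 310.0):
            y = peptide_rescue_curve(trunc_linkage, 80e-6, T, P).y
            i = int(np.argmax(y >= 0.5))
            assert i > 0
            half[T] = np.interp(0.5, [y[i - 1], y[i]], [P[i - 1], P[i]])
        assert half[310.0] > half[298.0]


class TestValidation:
    def test_conditions_reject_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            Conditions(C_tot=0.0, T=298.0)

    def test_conditions_reject_negative_peptide(self):
        with pytest.raises(ValueError):
            Conditions(C_tot=1e-4, T=298.0, P_tot=-1e-6)

    def test_midpoint_requires_monotone_grid(self, eng_linkage):
        with pytest.raises(ValueError):
            apparent_native_midpoint(eng_linkage, 1e-4, 0.0, np.array([300.0, 290.0]))
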