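"""Ternary free energy, coexistence solving and aggregation kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from maturation.thermo import (
    BoundaryCompositionError,
    Composition,
    InteractionParams,
    KineticParams,
    aggregation_trajectory,
    brute_force_equilibrium,
    free_energy_density,
    simulate_maturation,
    solve_binary_binodal,
    solve_coexistence,
    thermo_state,
    _total_free_energy,
)


def bisect_binodal(chi):
    """Independent 1D oracle: dense branch of the symmetric binary binodal."""
    g = lambda p: np.log(p / (1 - p)) - chi * (2 * p - 1)
    return brentq(g, 0.5 + 1e-9, 1 - 1e-12, xtol=1e-14)


class TestFreeEnergy:
    def test_ideal_ternary_entropy(self):
        c = Composition(1 / 3, 1 / 3, 1 / 3)
        assert free_energy_density(c, InteractionParams()) == pytest.approx(
            np.log(1 / 3), abs=1e-12
        )

    def test_pure_solvent_limit(self):
        c = Composition(0.0, 0.0, 1.0)
        p = InteractionParams(chi12=1.0, chi1s=3.0, chi2s=2.0)
        assert free_energy_density(c, p) == 0.0

    def test_term_by_term_hand_value(self):
        # 0.3 ln 0.3 + 0.2 ln 0.2 + 0.5 ln 0.5 + (3*0.3 + 2.1*0.2)*0.5
        c = Composition(0.3, 0.2, 0.5)
        p = InteractionParams(chi1s=3.0, chi2s=2.1)
        expected = (
            0.3 * np.log(0.3) + 0.2 * np.log(0.2) + 0.5 * np.log(0.5) + 0.66
        )
        assert free_energy_density(c, p) == pytest.approx(expected, abs=1e-12)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            Composition(-0.1, 0.5, 0.6)


class TestThermoState:
    def test_symmetric_ideal_mu1_zero(self):
        st = thermo_state(Composition(0.4, 0.2, 0.4), InteractionParams())
        assert st.mu1 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "comp,params",
        [
            ((0.3, 0.2, 0.5), InteractionParams(chi1s=3.0, chi2s=2.1)),
            ((0.1, 0.6, 0.3), InteractionParams(chi12=0.8, chi1s=1.2, chi2s=2.5)),
            ((0.25, 0.25, 0.5), InteractionParams(chi1s=2.0, chi2s=2.0, v1=2.0)),
        ],
    )
    def test_mu_matches_finite_differences(self, comp, params):
        c = Composition(*comp)
        st = thermo_state(c, params)
        h = 1e-7

        def f(p1, p2):
            return free_energy_density(Composition.from_protein(p1, p2), params)

        fd1 = (f(c.phi1 + h, c.phi2) - f(c.phi1 - h, c.phi2)) / (2 * h)
        fd2 = (f(c.phi1, c.phi2 + h) - f(c.phi1, c.phi2 - h)) / (2 * h)
        assert st.mu1 == pytest.approx(params.vs * fd1, rel=1e-7)
        assert st.mu2 == pytest.approx(params.vs * fd2, rel=1e-7)
        assert st.Pi == pytest.approx(-st.f + c.phi1 * fd1 + c.phi2 * fd2, rel=1e-6)

    def test_near_pure_solvent_pressure_vanishes(self):
        st = thermo_state(
            Composition.from_protein(1e-9, 1e-9), InteractionParams(chi1s=3.0)
        )
        assert abs(st.Pi) < 1e-6

    def test_boundary_composition_raises(self):
        with pytest.raises(BoundaryCompositionError):
            thermo_state(Composition(0.0, 0.5, 0.5), InteractionParams())


class TestBinaryLimit:
    def test_chi3_binodal_matches_bisection(self):
        dense, dilute = solve_binary_binodal(3.0)
        ref = bisect_binodal(3.0)
        assert dense == pytest.approx(ref, abs=1e-10)
        assert dilute == pytest.approx(1 - ref, abs=1e-10)

    def test_binodal_symmetric_about_half(self):
        for chi in (2.2, 2.7, 3.5):
            dense, dilute = solve_binary_binodal(chi)
            assert dense + dilute == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("chi", [0.5, 1.0, 1.5, 1.99])
    def test_no_demixing_below_critical_chi(self, chi):
        assert solve_binary_binodal(chi) is None
        eq = solve_coexistence(
            Composition.from_protein(0.5, 0.0), InteractionParams(chi1s=chi)
        )
        assert eq.single_phase

    def test_coexistence_on_binary_edge(self):
        eq = solve_coexistence(
            Composition.from_protein(0.5, 0.0), InteractionParams(chi1s=3.0)
        )
        ref = bisect_binodal(3.0)
        assert not eq.single_phase
        assert eq.dense.phi1 == pytest.approx(ref, abs=1e-4)
        assert eq.dilute.phi1 == pytest.approx(1 - ref, abs=1e-4)
        assert eq.nu == pytest.approx(0.5, abs=1e-6)


class TestCoexistence:
    def test_no_interactions_single_phase(self):
        eq = solve_coexistence(Composition.from_protein(0.3, 0.2), InteractionParams())
        assert eq.single_phase

    def test_indistinguishable_components_preserve_ratio(self):
        # chi1s == chi2s, chi12 = 0: solvent cannot tell 1 from 2
        p = InteractionParams(chi1s=2.8, chi2s=2.8)
        avg = Composition.from_protein(0.3, 0.15)
        eq = solve_coexistence(avg, p)
        assert not eq.single_phase
        ratio = avg.phi1 / avg.phi2
        assert eq.dense.phi1 / eq.dense.phi2 == pytest.approx(ratio, rel=1e-6)
        assert eq.dilute.phi1 / eq.dilute.phi2 == pytest.approx(ratio, rel=1e-6)

    def test_mass_balance_and_equal_potentials(self, regimeA):
        params, _ = regimeA
        avg = Composition.from_protein(0.35, 0.2)
        eq = solve_coexistence(avg, params)
        assert not eq.single_phase
        back = eq.average()
        assert back.phi1 == pytest.approx(avg.phi1, abs=1e-8)
        assert back.phi2 == pytest.approx(avg.phi2, abs=1e-8)
        stI = thermo_state(eq.dense, params)
        stII = thermo_state(eq.dilute, params)
        assert abs(stI.mu1 - stII.mu1) < 1e-7
        assert abs(stI.mu2 - stII.mu2) < 1e-7
        assert abs(stI.Pi - stII.Pi) < 1e-7

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            params = InteractionParams(
                chi1s=rng.uniform(2.2, 4.0), chi2s=rng.uniform(2.2, 4.0)
            )
            avg = Composition.from_protein(
                rng.uniform(0.25, 0.5), rng.uniform(0.1, 0.3)
            )
            bf = brute_force_equilibrium(avg, params, grid_n=120)
            sv = solve_coexistence(avg, params)
            f_sv = _total_free_energy(sv, params)
            f_bf = _total_free_energy(bf, params)
            assert f_sv <= f_bf + 1e-3

    def test_brute_force_no_interactions_homogeneous(self):
        eq = brute_force_equilibrium(
            Composition.from_protein(0.3, 0.2), InteractionParams(), grid_n=60
        )
        assert eq.single_phase

    def test_brute_force_minimization_property(self, regimeA):
        params, kin = regimeA
        avg = Composition.from_protein(kin.phi_tot, 0.0)
        eq = brute_force_equilibrium(avg, params, grid_n=100)
        assert _total_free_energy(eq, params) <= free_energy_density(avg, params)


class TestKinetics:
    def test_initial_condition_is_monomeric(self):
        kin = KineticParams(k1=0.2, k2=0.1, phi_tot=0.55)
        p1, p2 = aggregation_trajectory(kin, [0.0])
        assert p1[0] == pytest.approx(0.55)
        assert p2[0] == 0.0

    def test_long_time_limit(self):
        kin = KineticParams(k1=0.2, k2=0.1, phi_tot=0.55)
        p1, p2 = aggregation_trajectory(kin, [1e6])
        assert p1[0] == pytest.approx(0.55 * 0.1 / 0.3, rel=1e-9)
        assert p2[0] == pytest.approx(0.55 * 0.2 / 0.3, rel=1e-9)

    def test_no_forward_reaction_stays_monomeric(self):
        kin = KineticParams(k1=0.0, k2=0.3, phi_tot=0.4)
        p1, _ = aggregation_trajectory(kin, np.linspace(0, 10, 11))
        assert np.allclose(p1, 0.4)

    def test_zero_rates_constant(self):
        kin = KineticParams(k1=0.0, k2=0.0, phi_tot=0.4)
        p1, p2 = aggregation_trajectory(kin, np.linspace(0, 5, 6))
        assert np.allclose(p1, 0.4) and np.allclose(p2, 0.0)

    def test_conservation_exact(self):
        kin = KineticParams(k1=0.37, k2=0.11, phi_tot=0.62)
        t = np.linspace(0, 30, 301)
        p1, p2 = aggregation_trajectory(kin, t)
        assert np.max(np.abs(p1 + p2 - 0.62)) < 1e-15

    def test_closed_form_matches_ode_integration(self):
        kin = KineticParams(k1=0.2, k2=0.1, phi_tot=0.55)
        t = np.linspace(0, 20, 21)
        p1, _ = aggregation_trajectory(kin, t)
        sol = solve_ivp(
            lambda _, y: [-kin.k1 * y[0] + kin.k2 * (kin.phi_tot - y[0])],
            (0, 20),
            [kin.phi_tot],
            t_eval=t,
            rtol=1e-12,
            atol=1e-14,
        )
        assert np.max(np.abs(sol.y[0] - p1)) < 1e-8

    def test_initial_rate(self):
        kin = KineticParams(k1=0.2, k2=0.1, phi_tot=0.55)
        h = 1e-7
        p1, _ = aggregation_trajectory(kin, [0.0, h])
        assert (p1[1] - p1[0]) / h == pytest.approx(-0.2 * 0.55, rel=1e-5)


class TestMaturation:
    def test_regimeA_solvent_enters_droplet(self, regimeA, sim_times):
        params, kin = regimeA
        traj = simulate_maturation(kin, params, sim_times)
        phis_I = traj.dense_solvent_fraction()
        assert np.all(np.diff(phis_I) >= -1e-9)
        assert phis_I[-1] > phis_I[0]

    def test_regimeB_solvent_expelled(self, regimeB, sim_times):
        params, kin = regimeB
        traj = simulate_maturation(kin, params, sim_times)
        phis_I = traj.dense_solvent_fraction()
        assert np.all(np.diff(phis_I) <= 1e-9)
        assert phis_I[-1] < phis_I[0]

    def test_solvent_flux_depends_on_concentration(self, regimeA, sim_times):
        params, _ = regimeA
        lo = simulate_maturation(
            KineticParams(0.2, 0.1, 0.55), params, sim_times
        ).dense_solvent_fraction()
        hi = simulate_maturation(
            KineticParams(0.2, 0.1, 0.8), params, sim_times
        ).dense_solvent_fraction()
        assert np.max(np.abs(lo - hi)) > 1e-4

    def test_trajectory_mass_balance(self, regimeA, sim_times):
        params, kin = regimeA
        traj = simulate_maturation(kin, params, sim_times)
        assert np.max(np.abs(traj.avg_phi1 + traj.avg_phi2 - kin.phi_tot)) < 1e-10
        for eq, a1, a2 in zip(traj.equilibria, traj.avg_phi1, traj.avg_phi2):
            back = eq.average()
            assert abs(back.phi1 - a1) < 1e-8
            assert abs(back.phi2 - a2) < 1e-8
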