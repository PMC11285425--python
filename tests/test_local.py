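"""Single-habitat deterministic dynamics: right-hand sides, fixed points,
stability, transients and the critical trajectory."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from aerophage import (
    SpeciesParams,
    coexistence_fixed_point,
    critical_region_test,
    critical_trajectory,
    integrate_local,
    lv_rhs,
    stability_report,
)
from aerophage.local import COEXISTENCE, DET_UNSTABLE, PHAGE_FREE, InfeasibleFixedPoint


def random_feasible_params(rng):
    """Random parameter draw guaranteed to admit a coexistence fixed point."""
    g = rng.uniform(0.5, 2.0)
    K = 10 ** rng.uniform(1, 4)
    beta = rng.integers(3, 80)
    delta_s = rng.uniform(0.1, 2.0)
    u = rng.uniform(0.02, 0.6)  # ns*/K
    eta = delta_s / ((beta - 1) * u * K)
    bact = SpeciesParams.bacterium(g=g, K=K)
    phage = SpeciesParams.phage(eta=eta, beta=float(beta), delta_s=delta_s)
    return bact, phage


class TestRhs:
    def test_vanishes_at_handworked_fixed_point(self, workhorse):
        dns, dms = lv_rhs(1.0, [9.0], *[workhorse[0], [workhorse[1]]], 0.0)
        assert dns == pytest.approx(0.0, abs=1e-14)
        assert dms[0] == pytest.approx(0.0, abs=1e-14)

    def test_host_free_phage_decay(self, workhorse):
        bact, phage = workhorse
        dns, dms = lv_rhs(0.0, [5.0], bact, [phage], 0.0)
        assert dns == 0.0
        assert dms[0] == pytest.approx(-5.0 * phage.delta_s)

    def test_rejects_negative_density_and_strain_mismatch(self, workhorse):
        bact, phage = workhorse
        with pytest.raises(ValueError):
            lv_rhs(-1.0, [1.0], bact, [phage], 0.0)
        with pytest.raises(ValueError):
            lv_rhs(1.0, [1.0, 2.0], bact, [phage], 0.0)

    def test_multi_strain_host_equation_sums_predation(self, workhorse):
        bact, phage = workhorse
        ph2 = phage.with_(delta_s=0.5)
        dns, dms = lv_rhs(2.0, [3.0, 4.0], bact, [phage, ph2], 0.0)
        expected = bact.g * 2 * (1 - 2 / bact.K) - 2 * (0.1 * 3 + 0.1 * 4)
        assert dns == pytest.approx(expected)
        assert dms[1] == pytest.approx(10 * 0.1 * 2 * 4 - 0.5 * 4)


class TestFixedPoint:
    @pytest.mark.parametrize(
        "loss,ns,ms",
        [(0.0, 1.0, 9.0), (0.1, 1.1, 7.9)],
    )
    def test_handworked_values(self, workhorse, loss, ns, ms):
        rep = coexistence_fixed_point(*workhorse, loss_rate=loss)
        assert rep.feasible == COEXISTENCE
        assert rep.ns_star == pytest.approx(ns)
        assert rep.ms_star == pytest.approx(ms)

    def test_loss_equal_growth_is_deterministically_unstable(self, workhorse):
        rep = coexistence_fixed_point(*workhorse, loss_rate=1.0)
        assert rep.feasible == DET_UNSTABLE

    def test_large_decay_gives_phage_free_equilibrium(self, workhorse):
        bact, phage = workhorse
        rep = coexistence_fixed_point(bact, phage.with_(delta_s=20.0))
        assert rep.feasible == PHAGE_FREE
        assert rep.ns_free == pytest.approx(bact.K)

    def test_agrees_with_numerical_root_on_random_draws(self, rng):
        """Closed form vs an independent numerical root of the RHS."""
        for _ in range(30):
            bact, phage = random_feasible_params(rng)
            loss = rng.uniform(0, 0.2) * bact.g
            rep = coexistence_fixed_point(bact, phage, loss)
            if rep.feasible != COEXISTENCE:
                continue

            def f(y):
                dns, dms = lv_rhs(abs(y[0]), [abs(y[1])], bact, [phage], loss)
                return [dns / abs(y[0]), dms[0] / abs(y[1])]

            root = fsolve(f, [rep.ns_star * 1.3, rep.ms_star * 0.7], full_output=False)
            assert abs(root[0]) == pytest.approx(rep.ns_star, rel=1e-8)
            assert abs(root[1]) == pytest.approx(rep.ms_star, rel=1e-8)

    def test_rhs_vanishes_at_fixed_point_100_draws(self, rng):
        for _ in range(100):
            bact, phage = random_feasible_params(rng)
            rep = coexistence_fixed_point(bact, phage)
            assert rep.feasible == COEXISTENCE
            dns, dms = lv_rhs(rep.ns_star, [rep.ms_star], bact, [phage], 0.0)
            scale = bact.g * rep.ns_star
            assert abs(dns) <= 1e-10 * scale
            assert abs(dms[0]) <= 1e-10 * phage.delta_s * rep.ms_star


class TestStability:
    def test_handworked_eigenvalues_and_tau_per(self, workhorse):
        rep = stability_report(*workhorse)
        lam = rep.eigenvalues[0]
        assert lam.real == pytest.approx(-0.05)
        assert abs(lam.imag) == pytest.approx(0.9473647660748208, rel=1e-9)
        assert rep.tau_per == pytest.approx(20.0)
        assert rep.spiral

    def test_tau_per_halves_when_delta_s_doubles(self, workhorse):
        bact, phage = workhorse
        bact = bact.with_(K=100.0)  # keep both fixed points deep in feasibility
        t1 = stability_report(bact, phage).tau_per
        t2 = stability_report(bact, phage.with_(delta_s=2.0)).tau_per
        assert t2 == pytest.approx(t1 / 2, rel=1e-9)

    def test_tau_per_inverse_in_delta_s_over_100x_range(self, workhorse):
        bact, phage = workhorse
        bact = bact.with_(K=1000.0)
        products = [
            stability_report(bact, phage.with_(delta_s=ds)).tau_per * ds
            for ds in (0.1, 1.0, 10.0)
        ]
        assert max(products) - min(products) <= 1e-6 * products[0]

    def test_stable_spiral_on_random_draws(self, rng):
        for _ in range(50):
            bact, phage = random_feasible_params(rng)
            rep = stability_report(bact, phage)
            assert rep.eigenvalues[0].real < 0

    def test_infeasible_fixed_point_rejected(self, workhorse):
        bact, phage = workhorse
        with pytest.raises(InfeasibleFixedPoint):
            stability_report(bact, phage.with_(delta_s=20.0))


class TestIntegrateLocal:
    def test_constant_at_fixed_point(self, workhorse):
        bact, phage = workhorse
        rep = coexistence_fixed_point(bact, phage)
        sol = integrate_local(
            (rep.ns_star, [rep.ms_star]), bact, [phage], 0.0, (0, 50.0),
            t_eval=np.linspace(0, 50, 20),
        )
        assert np.allclose(sol.y[0], rep.ns_star, rtol=1e-7)
        assert np.allclose(sol.y[1], rep.ms_star, rtol=1e-7)

    def test_perturbation_decays_at_rate_tau_per(self, desk_species):
        """Log-envelope slope of the damped spiral matches -1/tau_per."""
        from scipy.signal import argrelmax

        bact, phage = desk_species
        rep = stability_report(bact, phage)
        t_eval = np.linspace(0, 8 * rep.tau_per, 8000)
        sol = integrate_local(
            (rep.ns_star * 1.01, [rep.ms_star]), bact, [phage], 0.0,
            (0, t_eval[-1]), t_eval=t_eval, rtol=1e-11, atol=1e-9,
        )
        dev = np.abs(sol.y[0] - rep.ns_star) / rep.ns_star
        peaks = argrelmax(dev)[0]
        slope = np.polyfit(t_eval[peaks], np.log(dev[peaks]), 1)[0]
        assert slope == pytest.approx(-1.0 / rep.tau_per, rel=0.02)

    def test_oscillation_amplitude_grows_as_delta_s_drops(self, desk_species):
        """Transients from a fixed relative perturbation swing wider for
        fitter (lower delta_s) phages."""
        bact, phage = desk_species
        amps = []
        for ds in (0.8, 0.4, 0.2, 0.1):
            rep = stability_report(bact, phage.with_(delta_s=ds))
            t_eval = np.linspace(0, 10 * rep.tau_per, 4000)
            sol = integrate_local(
                (rep.ns_star * 0.5, [rep.ms_star]), bact, [phage.with_(delta_s=ds)],
                0.0, (0, t_eval[-1]), t_eval=t_eval, rtol=1e-10, atol=1e-8,
            )
            ns = sol.y[0] / rep.ns_star
            amps.append(ns.max() - ns.min())
        assert all(a < b for a, b in zip(amps, amps[1:]))

    def test_two_phage_competitive_exclusion(self, desk_species):
        """On a shared host the strain with lower delta_s eliminates the other."""
        bact, _ = desk_species
        strong = SpeciesParams.phage(eta=desk_eta(), beta=50.0, delta_s=0.05)
        weak = SpeciesParams.phage(eta=desk_eta(), beta=50.0, delta_s=0.2)
        rep = coexistence_fixed_point(bact, strong)
        sol = integrate_local(
            (rep.ns_star, [rep.ms_star, rep.ms_star]), bact, [strong, weak],
            0.0, (0, 400.0), t_eval=np.linspace(0, 400, 400), rtol=1e-10, atol=1e-10,
        )
        assert sol.y[2][-1] < 1e-4 * sol.y[2][0]
        assert sol.y[1][-1] > 0.01 * rep.ms_star


def desk_eta():
    from aerophage.constants import DESK

    return DESK["eta"]


class TestCriticalTrajectory:
    def test_fixed_point_is_safe(self, desk_species):
        bact, phage = desk_species
        rep = coexistence_fixed_point(bact, phage)
        verdict, _ = critical_region_test(
            (rep.ns_star, rep.ms_star), bact, phage, 0.0, rho_ext=1.0
        )
        assert verdict == "safe"

    def test_phage_arrival_at_carrying_capacity_dooms_host(self, desk_species):
        """A habitat at K cannot absorb any phage migration: the transient
        drives the host below the extinction floor."""
        bact, phage = desk_species
        for ms0 in (1.0, 100.0):
            verdict, species = critical_region_test(
                (bact.K, ms0), bact, phage, 0.0, rho_ext=1.0
            )
            assert verdict == "doomed"
            assert species == "bacteria"

    def test_without_threshold_closed_lv_never_absorbs(self, desk_species):
        bact, phage = desk_species
        rep = coexistence_fixed_point(bact, phage)
        verdict, _ = critical_region_test(
            (bact.K, 3 * rep.ms_star), bact, phage, 0.0, rho_ext=1e-60
        )
        assert verdict == "safe"

    def test_doom_is_monotone_above_the_upper_branch(self, desk_species):
        """Scanning upward from the fixed point, once a phage dose dooms the
        habitat every larger dose does too."""
        bact, phage = desk_species
        ns0 = 0.06 * bact.K
        rep = coexistence_fixed_point(bact, phage)
        verdicts = [
            critical_region_test((ns0, ms0), bact, phage, 0.0, rho_ext=1.0)[0]
            for ms0 in np.geomspace(rep.ms_star, 50 * rep.ms_star, 12)
        ]
        switched = "".join("d" if v == "doomed" else "s" for v in verdicts)
        assert "ds" not in switched  # once doomed, stays doomed

    def test_boundary_matches_dense_scan(self, desk_species):
        bact, phage = desk_species
        rep = coexistence_fixed_point(bact, phage)
        ns0 = 0.06 * bact.K
        poly = critical_trajectory(
            bact, phage, 0.0, 1.0, [ns0], rel_tol=1e-4, ms_max=100 * rep.ms_star
        )
        ms_crit = poly[0, 1]
        assert np.isfinite(ms_crit) and ms_crit > 0
        grid = np.geomspace(ms_crit / 1.3, ms_crit * 1.3, 25)
        verdicts = [
            critical_region_test((ns0, m), bact, phage, 0.0, rho_ext=1.0)[0]
            for m in grid
        ]
        last_safe = grid[max(i for i, v in enumerate(verdicts) if v == "safe")]
        assert ms_crit == pytest.approx(last_safe, rel=0.15)

    def test_ms_crit_vanishes_at_carrying_capacity(self, desk_species):
        bact, phage = desk_species
        poly = critical_trajectory(bact, phage, 0.0, 1.0, [bact.K])
        assert poly[0, 1] == 0.0

    def test_short_horizon_warns(self, desk_species):
        bact, phage = desk_species
        rep = coexistence_fixed_point(bact, phage)
        with pytest.warns(UserWarning):
            critical_region_test(
                (rep.ns_star, rep.ms_star), bact, phage, 0.0, rho_ext=1.0, horizon=1.0
            )

    def test_loss_above_growth_drains_phage_free_habitat(self, desk_species):
        """With loss >= g even logistic growth cannot sustain the host."""
        bact, phage = desk_species
        sol = integrate_local(
            (bact.K, [0.0]), bact, [phage], loss_rate=1.2 * bact.g,
            t_span=(0, 100.0), t_eval=np.linspace(0, 100, 500),
        )
        assert sol.y[0][-1] < 1.0  # below rho_ext = one individual per box
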