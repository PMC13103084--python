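import math

import numpy as np
import pytest

from arid14c.isotopes import LAMBDA_14C
from arid14c.pools import (OnePoolFit, ages_and_transit, fit_one_pool,
                           fit_two_pool, simulate_one_pool,
                           simulate_two_pool, _two_pool_summary)


def flat_steady_delta(k):
    """Closed-form Δ¹⁴C of a pool under a constant 0‰ atmosphere."""
    return (k / (k + LAMBDA_14C) - 1.0) * 1000.0


class TestSimulateOnePool:
    def test_flat_atmosphere_closed_form(self, flat_curve):
        k = 1.0 / 1939.0
        f = k / (k + LAMBDA_14C)
        assert f == pytest.approx(0.81, abs=0.001)
        delta = simulate_one_pool(k, flat_curve, 2018.0)
        assert delta == pytest.approx(flat_steady_delta(k), abs=1e-6)

    def test_fast_pool_tracks_atmosphere(self, curve):
        delta = simulate_one_pool(1.0, curve, 2018.0)
        assert abs(delta - curve.at(2018)) < 15.0

    def test_slow_pool_approaches_dead_carbon(self, curve):
        deltas = [simulate_one_pool(k, curve, 2018.0)
                  for k in (1e-3, 1e-4, 1e-5)]
        assert deltas[0] > deltas[1] > deltas[2]
        assert deltas[2] < -900.0

    def test_monotone_in_k_for_old_pools(self, curve):
        ages = np.linspace(150.0, 10000.0, 120)
        deltas = [simulate_one_pool(1.0 / a, curve, 2018.0) for a in ages]
        assert all(a > b for a, b in zip(deltas, deltas[1:]))

    def test_background_corrected_offset(self, curve):
        raw = simulate_one_pool(0.01, curve, 2018.0)
        corr = simulate_one_pool(0.01, curve, 2018.0,
                                 background_corrected=True)
        assert raw - corr == pytest.approx(curve.at(2018))

    def test_invalid_rate_rejected(self, curve):
        with pytest.raises(ValueError):
            simulate_one_pool(0.0, curve, 2018.0)


class TestFitOnePool:
    def test_round_trip_known_rate(self, curve):
        k_true = 1.0 / 500.0
        obs = simulate_one_pool(k_true, curve, 2018.0,
                                background_corrected=True)
        fit = fit_one_pool(obs, curve, 2018.0)
        assert fit.age_years == pytest.approx(500.0, abs=1.0)

    def test_flat_atmosphere_age_closed_form(self, flat_curve):
        for f in (0.5, 0.81, 0.95):
            expected_age = 8267.0 * (1.0 - f) / f
            obs = (f - 1.0) * 1000.0
            fit = fit_one_pool(obs, flat_curve, 2018.0, tol_permil=1e-3)
            assert fit.age_years == pytest.approx(expected_age, rel=0.005)

    def test_bomb_ambiguous_observation_prefers_longer_transit(self, curve):
        fit = fit_one_pool(100.0, curve, 2018.0)
        assert fit.n_solutions == 2
        assert fit.selection == "longer_transit"
        assert fit.age_years == max(fit.all_ages)
        # independent grid-scan oracle: enumerate sign changes directly
        ks = np.logspace(-5, 1, 4000)
        deltas = np.array([simulate_one_pool(k, curve, 2018.0,
                                             background_corrected=True)
                           for k in ks])
        crossings = np.flatnonzero((deltas[:-1] - 100.0)
                                   * (deltas[1:] - 100.0) < 0)
        assert len(crossings) == 2
        bracket_ages = np.sort(1.0 / ks[crossings])
        assert fit.age_years == pytest.approx(bracket_ages[-1], rel=0.01)

    def test_negative_observation_unique_root(self, curve):
        fit = fit_one_pool(-39.2, curve, 2018.0)
        assert fit.n_solutions == 1 and fit.selection == "unique"

    def test_out_of_range_observation_rejected(self, curve):
        with pytest.raises(ValueError, match="outside"):
            fit_one_pool(900.0, curve, 2018.0)

    def test_residual_within_tolerance(self, curve):
        fit = fit_one_pool(-190.0, curve, 2018.0, tol_permil=0.1)
        assert abs(fit.residual) < 0.1

    def test_parameter_recovery_under_noise(self, curve, rng):
        # 50 sites, ages log-uniform 50–5000 y, 2‰ observation noise
        ages = 10 ** rng.uniform(math.log10(50), math.log10(5000), 50)
        errs = []
        for age in ages:
            obs = simulate_one_pool(1.0 / age, curve, 2018.0,
                                    background_corrected=True)
            obs += rng.normal(0.0, 2.0)
            fit = fit_one_pool(obs, curve, 2018.0)
            errs.append(abs(fit.age_years - age) / age)
        assert np.median(errs) < 0.05


class TestSimulateTwoPool:
    def test_parallel_degenerate_equals_one_pool_bitwise(self, curve):
        one = simulate_one_pool(0.1, curve, 2018.0)
        bulk, resp = simulate_two_pool("parallel", 0.1, 1e-4, 1.0,
                                       curve, 2018.0)
        assert bulk == one and resp == one

    def test_series_no_transfer_equals_one_pool_bitwise(self, curve):
        one = simulate_one_pool(0.05, curve, 2018.0)
        bulk, resp = simulate_two_pool("series", 0.05, 1e-4, 0.0,
                                       curve, 2018.0)
        assert bulk == one and resp == one

    def test_parallel_flat_atmosphere_closed_form(self, flat_curve):
        kf, ks, gamma = 1.0 / 10.0, 1.0 / 5000.0, 0.9
        bulk, resp = simulate_two_pool("parallel", kf, ks, gamma,
                                       flat_curve, 2018.0)
        zf = kf / (kf + LAMBDA_14C)
        zs = ks / (ks + LAMBDA_14C)
        cf, cs = gamma / kf, (1 - gamma) / ks
        exp_bulk = ((cf * zf + cs * zs) / (cf + cs) - 1.0) * 1000.0
        exp_resp = (gamma * zf + (1 - gamma) * zs - 1.0) * 1000.0
        assert bulk == pytest.approx(exp_bulk, abs=1e-6)
        assert resp == pytest.approx(exp_resp, abs=1e-6)

    def test_series_flat_atmosphere_closed_form(self, flat_curve):
        kf, ks, a21 = 1.0 / 10.0, 1.0 / 1000.0, 0.5
        bulk, resp = simulate_two_pool("series", kf, ks, a21,
                                       flat_curve, 2018.0)
        zf = kf / (kf + LAMBDA_14C)
        zs = ks * zf / (ks + LAMBDA_14C)   # slow pool fed by fast pool
        cf, cs = 1.0 / kf, a21 / ks
        exp_bulk = ((cf * zf + cs * zs) / (cf + cs) - 1.0) * 1000.0
        exp_resp = ((1 - a21) * zf + a21 * zs - 1.0) * 1000.0
        assert bulk == pytest.approx(exp_bulk, abs=1e-6)
        assert resp == pytest.approx(exp_resp, abs=1e-6)

    def test_invalid_parameters_rejected(self, curve):
        with pytest.raises(ValueError):
            simulate_two_pool("parallel", 0.001, 0.1, 0.5, curve, 2018.0)
        with pytest.raises(ValueError):
            simulate_two_pool("ring", 0.1, 0.001, 0.5, curve, 2018.0)


class TestFitTwoPool:
    def test_identifiable_round_trip_with_fixed_k_fast(self, curve):
        kf, ks, gamma = 1.0 / 20.0, 1.0 / 2000.0, 0.8
        bulk, resp = simulate_two_pool("parallel", kf, ks, gamma,
                                       curve, 2018.0,
                                       background_corrected=True)
        fit = fit_two_pool(bulk, resp, "parallel", curve, 2018.0,
                           k_fast_age_min=20.0, k_fast_age_max=20.0,
                           k_fast_points=1)
        assert fit.k_slow == pytest.approx(ks, rel=0.01)
        assert fit.partition == pytest.approx(gamma, rel=0.01)

    def test_equal_observations_collapse_to_one_pool(self, curve):
        obs = simulate_one_pool(1.0 / 800.0, curve, 2018.0,
                                background_corrected=True)
        fit = fit_two_pool(obs, obs, "parallel", curve, 2018.0)
        assert max(abs(r) for r in fit.residuals) < 1.0
        assert (fit.partition < 0.02 or fit.partition > 0.98
                or fit.k_fast / fit.k_slow < 1.05)

    def test_cohort_means_put_mass_in_slow_pool(self, curve):
        fit = fit_two_pool(-190.0, -39.2, "parallel", curve, 2018.0)
        assert fit.mass_frac_slow > 0.9
        assert max(abs(r) for r in fit.residuals) < 1.0

    def test_unreachable_observations_rejected(self, curve):
        with pytest.raises(ValueError, match="within"):
            fit_two_pool(900.0, 900.0, "parallel", curve, 2018.0)


class TestAgesAndTransit:
    def test_one_pool_equality(self, curve):
        fit = OnePoolFit(k=1.0 / 520.0, age_years=520.0, fitted_delta14c=0.0,
                         residual=0.0, n_solutions=1, selection="unique")
        assert ages_and_transit(fit) == (520.0, 520.0)

    def test_parallel_pure_fast(self):
        s = _two_pool_summary("parallel", 0.1, 1e-4, 1.0)
        assert s["mean_transit_time"] == pytest.approx(10.0)

    def test_series_transit_hand_arithmetic(self):
        s = _two_pool_summary("series", 1.0 / 10.0, 1.0 / 1000.0, 0.5)
        assert s["mean_transit_time"] == pytest.approx(510.0)

    def test_series_system_age_against_particle_oracle(self, rng):
        kf, ks, a21 = 1.0 / 10.0, 1.0 / 1000.0, 0.5
        s = _two_pool_summary("series", kf, ks, a21)
        n = 400_000
        cf, cs = 1.0 / kf, a21 / ks
        in_slow = rng.uniform(size=n) < cs / (cf + cs)
        age_fast = rng.exponential(1.0 / kf, n)
        age_slow = rng.exponential(1.0 / kf, n) + rng.exponential(1.0 / ks, n)
        mc_age = np.where(in_slow, age_slow, age_fast).mean()
        assert s["mean_system_age"] == pytest.approx(mc_age, rel=0.02)

    def test_transit_equals_stock_per_unit_input(self):
        # steady-state identity for both structures
        for structure, part in (("parallel", 0.7), ("series", 0.4)):
            s = _two_pool_summary(structure, 1.0 / 15.0, 1.0 / 3000.0, part)
            assert s["mean_transit_time"] == pytest.approx(
                s["total_stock"], rel=1e-6)
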