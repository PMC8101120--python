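"""Deterministic ODE model: oracle agreement, conservation, derived metrics.

The closed form I(t) = a/mu + (I0 - a/mu) e^{-mu t} (a = lambda*H0) under the
stationary-healthy closure is the exact solution of the patient equation and
serves as the independent oracle for the numerical integrator.  One frozen
cross-check against an external ODE solver (R deSolve, lsoda, rtol 1e-10,
Iran parameters) guards against a shared mistake in model assembly.
"""

import dataclasses
import math

import numpy as np
import pytest

import ibdforecast as ib
from ibdforecast.deterministic import _corner_rates


# External oracle: R deSolve (lsoda) solution of the same system, Iran
# parameters, frozen to the printed digits.
DESOLVE_IRAN = {3: 31545.87340, 8: 44134.01434, 13: 56354.64480, 18: 68218.49425}


class TestOdeRhs:
    def test_incidence_term_alone(self):
        rates = ib.ModelRates(lambda_inc=3.11e-5, mu_ibd=0.0, d_background=0.0)
        dh, di, dd = ib.ode_rhs((100_000.0, 0.0, 0.0), rates, births=0.0)
        assert di == pytest.approx(3.11)
        assert dd == 0.0

    def test_births_only(self):
        rates = ib.ModelRates(0.0, 0.0, 0.0)
        assert ib.ode_rhs((0.0, 0.0, 0.0), rates, births=7.0) == (7.0, 0.0, 0.0)

    def test_stationary_closure_freezes_healthy_pool(self, iran_state, iran_rates):
        births = iran_rates.resolve_births(iran_state.healthy)
        dh, _, _ = ib.ode_rhs(
            (iran_state.healthy, iran_state.ibd, 0.0), iran_rates, births)
        assert dh == pytest.approx(0.0, abs=1e-9)


class TestIntegrate:
    def test_matches_closed_form_all_regions_all_years(self, asia_table):
        for p in asia_table:
            s0 = ib.derive_initial_state(p)
            rates = ib.to_model_rates(p)
            traj = ib.integrate(s0, rates, 18, 1.0)
            for t in range(19):
                oracle = ib.closed_form_prevalence(s0, rates, t)
                assert traj.ibd[t] == pytest.approx(oracle, rel=1e-6)

    def test_matches_external_desolve_solution(self, iran_state, iran_rates):
        traj = ib.integrate(iran_state, iran_rates, 18, 1.0)
        for t, expected in DESOLVE_IRAN.items():
            assert traj.ibd[t] == pytest.approx(expected, rel=1e-7)

    def test_conservation_people_never_created(self, asia_table):
        for p in asia_table:
            s0 = ib.derive_initial_state(p)
            traj = ib.integrate(s0, ib.to_model_rates(p), 18, 1.0)
            births = traj.rates_used.birth_inflow
            elapsed = traj.grid - traj.grid[0]
            total = traj.healthy + traj.ibd + traj.dead_cum
            expected = s0.total_alive + births * elapsed
            assert np.allclose(total, expected, rtol=1e-8)

    def test_pure_decay_when_incidence_zero(self, iran_state):
        rates = ib.ModelRates(0.0, 0.01, 0.005, birth_inflow=0.0)
        traj = ib.integrate(iran_state, rates, 10, 1.0)
        t = np.arange(11)
        assert np.allclose(traj.ibd, iran_state.ibd * np.exp(-0.01 * t), rtol=1e-8)

    def test_linear_growth_when_mortality_zero(self, iran_state):
        rates = ib.ModelRates(3.11e-5, 0.0, 4.6397e-3)
        traj = ib.integrate(iran_state, rates, 10, 1.0)
        a = rates.lambda_inc * iran_state.healthy
        t = np.arange(11)
        assert np.allclose(traj.ibd, iran_state.ibd + a * t, rtol=1e-8)

    def test_monotone_concave_toward_equilibrium(self, asia_table):
        """With a/mu > I0 (true for all regions) I(t) rises, concave."""
        for p in asia_table:
            s0 = ib.derive_initial_state(p)
            rates = ib.to_model_rates(p)
            assert rates.lambda_inc * s0.healthy / rates.mu_ibd > s0.ibd
            traj = ib.integrate(s0, rates, 18, 1.0)
            diffs = np.diff(traj.ibd)
            assert np.all(diffs > 0)
            assert np.all(np.diff(diffs) < 0)
            assert traj.ibd[-1] < rates.lambda_inc * s0.healthy / rates.mu_ibd

    def test_grid_refinement_leaves_shared_points_unchanged(self, iran_state, iran_rates):
        coarse = ib.integrate(iran_state, iran_rates, 18, 1.0)
        fine = ib.integrate(iran_state, iran_rates, 18, 0.5)
        assert np.allclose(coarse.ibd, fine.ibd[::2], rtol=1e-9)

    def test_invalid_horizon_or_step(self, iran_state, iran_rates):
        with pytest.raises(ValueError):
            ib.integrate(iran_state, iran_rates, -1, 1.0)
        with pytest.raises(ValueError):
            ib.integrate(iran_state, iran_rates, 18, 0.0)


class TestClosedForm:
    def test_identity_at_t_zero(self, iran_state, iran_rates):
        assert ib.closed_form_prevalence(iran_state, iran_rates, 0.0) == iran_state.ibd

    def test_asymptote_is_equilibrium(self, iran_state, iran_rates):
        eq = iran_rates.lambda_inc * iran_state.healthy / iran_rates.mu_ibd
        assert ib.closed_form_prevalence(iran_state, iran_rates, 1e6) == pytest.approx(eq)

    def test_iran_2035_value(self, iran_state, iran_rates):
        # a/mu = 462,721; I0 = 23,812; mu = 0.16/27
        assert ib.closed_form_prevalence(iran_state, iran_rates, 18) == pytest.approx(
            68_218.5, abs=1.0)

    def test_requires_stationary_closure(self, iran_state, iran_rates):
        with pytest.raises(ValueError, match="stationary"):
            ib.closed_form_prevalence(
                iran_state, iran_rates.with_births(0.0), 5.0)


class TestProjectInterval:
    def test_band_collapses_at_start(self, iran):
        band = ib.project_interval(iran, 18)
        assert band.ibd_low[0] == pytest.approx(band.ibd_high[0], rel=1e-12)
        assert band.ibd_point[0] == pytest.approx(23812.0)

    def test_band_strictly_brackets_point_at_horizon(self, iran):
        band = ib.project_interval(iran, 18)
        assert band.ibd_low[-1] < band.ibd_point[-1] < band.ibd_high[-1]

    def test_ordering_invariant_everywhere(self, asia_table):
        for p in asia_table:
            band = ib.project_interval(p, 18)
            assert np.all(band.ibd_low <= band.ibd_point + 1e-9)
            assert np.all(band.ibd_point <= band.ibd_high + 1e-9)

    def test_degenerate_ui_gives_zero_width(self, toy_region):
        p = dataclasses.replace(
            toy_region,
            prevalence_ratio=ib.Uncertain.exact(1000.0),
            ibd_death_rate=ib.Uncertain.exact(5.0),
            background_death_rate=ib.Uncertain.exact(800.0),
        )
        band = ib.project_interval(p, 10)
        assert np.allclose(band.ibd_low, band.ibd_high, rtol=1e-9)

    def test_envelope_covers_every_corner(self, iran):
        band = ib.project_interval(iran, 18)
        for _, rates, st in _corner_rates(iran):
            traj = ib.integrate(st, rates, 18, 1.0)
            assert np.all(traj.ibd >= band.ibd_low - 1e-6)
            assert np.all(traj.ibd <= band.ibd_high + 1e-6)


class TestSensitivity:
    def test_iran_elasticities_match_closed_form_oracle(self, iran, iran_state, iran_rates):
        """Elasticity w.r.t. onset = (a/mu)(1-e^{-mu t}) / I(t) = 0.686 at t=18."""
        res = ib.sensitivity(iran, t=18)
        a = iran_rates.lambda_inc * iran_state.healthy
        mu = iran_rates.mu_ibd
        i18 = ib.closed_form_prevalence(iran_state, iran_rates, 18)
        expected = a / mu * (1 - math.exp(-mu * 18)) / i18
        assert expected == pytest.approx(0.6862, abs=5e-4)
        # the oracle holds H at H0; the integrator lets the perturbed onset
        # rate deplete the healthy pool slightly (relative gap ~4e-4)
        assert res.elasticities["lambda_inc"] == pytest.approx(expected, rel=1e-3)

    def test_signs_follow_model_structure(self, asia_table):
        for p in asia_table[:3]:
            res = ib.sensitivity(p, t=18)
            assert res.elasticities["lambda_inc"] >= 0
            assert res.elasticities["mu_ibd"] <= 0
            assert res.elasticities["d_background"] <= 0
            assert res.elasticities["birth_inflow"] >= 0

    def test_central_difference_second_order(self, iran):
        e1 = ib.sensitivity(iran, t=18, rel_perturbation=2e-3).elasticities["lambda_inc"]
        e2 = ib.sensitivity(iran, t=18, rel_perturbation=1e-3).elasticities["lambda_inc"]
        assert abs(e1 - e2) < 1e-6

    def test_invalid_perturbation(self, iran):
        with pytest.raises(ValueError):
            ib.sensitivity(iran, t=18, rel_perturbation=0.0)


class TestDoublingTime:
    def test_iran_doubling_from_2020_near_thirteen_years(self, iran_state, iran_rates):
        """Analytic inversion of the closed form gives 12.82 years."""
        traj = ib.integrate(iran_state, iran_rates, 18, 1.0)
        dt = ib.doubling_time(traj, 2020)
        a, mu = iran_rates.lambda_inc * iran_state.healthy, iran_rates.mu_ibd
        eq = a / mu
        i2020 = ib.closed_form_prevalence(iran_state, iran_rates, 3)
        exact = -math.log((2 * i2020 - eq) / (iran_state.ibd - eq)) / mu - 3
        assert exact == pytest.approx(12.82, abs=0.01)
        # trajectory-based value uses linear interpolation between years
        assert dt == pytest.approx(exact, abs=0.05)

    def test_east_asia_never_doubles_by_2035(self, asia_table):
        p = next(q for q in asia_table if q.region_name == "East Asia")
        traj = ib.integrate(ib.derive_initial_state(p), ib.to_model_rates(p), 18, 1.0)
        assert ib.doubling_time(traj, 2020) == math.inf

    def test_equilibrium_trajectory_never_doubles(self, iran_state):
        # lambda*H0 = mu*I0 -> constant patient count
        mu = 0.01
        lam = mu * iran_state.ibd / iran_state.healthy
        rates = ib.ModelRates(lam, mu, 0.005)
        traj = ib.integrate(iran_state, rates, 18, 1.0)
        assert ib.doubling_time(traj, 2017) == math.inf

    def test_off_grid_reference_rejected(self, iran_state, iran_rates):
        traj = ib.integrate(iran_state, iran_rates, 18, 1.0)
        with pytest.raises(KeyError):
            ib.doubling_time(traj, 2020.5)


class TestFoldChange:
    def test_identity_same_year(self, iran_state, iran_rates):
        traj = ib.integrate(iran_state, iran_rates, 18, 1.0)
        assert ib.fold_change(traj, 2025, 2025) == 1.0

    def test_iran_2020_to_2035(self, iran_state, iran_rates):
        """Closed-form ratio 68,218 / 31,546 = 2.162."""
        traj = ib.integrate(iran_state, iran_rates, 18, 1.0)
        assert ib.fold_change(traj, 2020, 2035) == pytest.approx(2.162, abs=0.005)

    def test_at_least_one_for_growing_trajectories(self, asia_table):
        for p in asia_table:
            traj = ib.integrate(ib.derive_initial_state(p), ib.to_model_rates(p), 18, 1.0)
            assert ib.fold_change(traj, 2017, 2035) >= 1.0
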