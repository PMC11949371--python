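"""Unit and property tests for the weekly-cycle cohort engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import respondsim as rs
from respondsim.strata import ANI, NANI, AI, NAI


class TestRateProbConversion:
    @pytest.mark.parametrize("rate,dt,expected,tol", [
        (0.0, 1.0, 0.0, 0.0),
        (0.2876820724517809, 1.0, 0.25, 1e-12),  # inverts a 25% probability
        (50.0, 1.0, 1.0, 1e-10),                 # saturation
    ])
    def test_known_values(self, rate, dt, expected, tol):
        assert rs.rate_to_prob(rate, dt) == pytest.approx(expected, abs=tol)

    def test_invalid_arguments(self):
        with pytest.raises(rs.ConfigError):
            rs.rate_to_prob(-0.1)
        with pytest.raises(rs.ConfigError):
            rs.rate_to_prob(0.1, dt=0.0)
        with pytest.raises(rs.ConfigError):
            rs.prob_to_rate(1.0)

    def test_post_treatment_exit_rate_from_quarter_probability(self):
        # a weekly exit probability of 25% corresponds to rate ~0.29
        assert rs.prob_to_rate(0.25) == pytest.approx(0.29, abs=0.005)

    @given(r1=st.floats(0, 5), r2=st.floats(0, 5), dt=st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_rate(self, r1, r2, dt):
        lo, hi = sorted((r1, r2))
        p_lo, p_hi = rs.rate_to_prob(lo, dt), rs.rate_to_prob(hi, dt)
        assert p_lo <= p_hi <= 1.0
        if hi * dt < 30:  # below float64 saturation of 1 - exp(-x)
            assert p_hi < 1.0


class TestArrivals:
    def test_degenerate_single_stratum(self):
        out = rs.compute_arrivals(100.0, np.ones((1, 1)),
                                  np.array([1.0, 0, 0, 0]))
        assert out[ANI, 0, 0] == pytest.approx(100.0)
        assert out.sum() == pytest.approx(100.0)

    def test_zero_arrivals(self):
        out = rs.compute_arrivals(0.0, np.ones((2, 2)) / 4,
                                  np.array([0.7, 0, 0.3, 0]))
        assert np.all(out == 0)

    def test_uniform_four_strata(self):
        # 356 arrivals (lower 2015 prior bound) over 4 equal strata
        out = rs.compute_arrivals(356.0, np.ones((2, 2)) / 4,
                                  np.array([0.7, 0, 0.3, 0]))
        per_stratum = out.sum(axis=0)
        assert np.allclose(per_stratum, 89.0)

    def test_bad_proportions(self):
        with pytest.raises(rs.ConfigError):
            rs.compute_arrivals(10.0, np.ones((2, 2)), np.array([1.0, 0, 0, 0]))


class TestOverdoseMachinery:
    def test_detox_rate_multiplier(self):
        base = np.full((2, 2), 0.01)
        assert np.allclose(rs.detox_entry_rate(base, 1.0), base)
        assert np.allclose(rs.detox_entry_rate(base, 2.0), 0.02)

    def test_identity_multipliers_reduce_to_baseline(self):
        base = np.full((1, 1), 0.002)
        rates = rs.overdose_rates(base, 1.0, np.ones(3), 1.0, inj_od_ratio=1.0)
        # every non-detox state shares the baseline in active states
        non_detox = [0, 1, 2, 3, 5, 6, 7, 8]
        assert np.allclose(rates[non_detox, ANI], 0.002)
        assert np.allclose(rates[non_detox, AI], 0.002)
        assert np.all(rates[4] == 0)          # detox carries no overdose risk
        assert np.all(rates[:, (NANI, NAI)] == 0)  # non-active: no risk

    def test_multiplier_arithmetic(self):
        base = np.full((1, 1), 0.001)
        rates = rs.overdose_rates(base, 1.5, np.zeros(3), 2.0)
        assert rates[0, ANI, 0, 0] == pytest.approx(0.0015)
        assert rates[5, ANI, 0, 0] == pytest.approx(0.003)
        assert np.all(rates[1:4] == 0)  # m_t = 0 silences treatment overdoses
        assert rates[0, AI, 0, 0] == pytest.approx(0.003)  # injection ratio 2

    def test_invariant_violations(self):
        base = np.full((1, 1), 0.001)
        with pytest.raises(rs.ConfigError):
            rs.overdose_rates(base, 1.0, np.array([1.2, 0, 0]), 2.0)
        with pytest.raises(rs.ConfigError):
            rs.overdose_rates(base, 1.0, np.zeros(3), 0.5)

    def test_split_fatal_boundaries(self):
        od = np.array([80.0, 20.0])
        total, alloc = rs.split_fatal(od, 0.0)
        assert total == 0 and np.all(alloc == 0)
        total, alloc = rs.split_fatal(od, 1.0)
        assert total == pytest.approx(100.0)

    def test_split_fatal_proportional_allocation(self):
        # oracle by direct arithmetic: 10% of 100 pooled = 10 deaths, 8 + 2
        total, alloc = rs.split_fatal(np.array([80.0, 20.0]), 0.1)
        assert total == pytest.approx(10.0)
        assert np.allclose(alloc, [8.0, 2.0])
        with pytest.raises(rs.ConfigError):
            rs.split_fatal(np.array([1.0]), 1.5)


class TestInitiationEffect:
    def test_identity_and_full_drop(self):
        flow = np.array([10.0, 5.0, 20.0, 2.0])
        assert np.allclose(rs.apply_initiation_effect(flow, np.ones(2)), flow)
        dropped = rs.apply_initiation_effect(flow, np.zeros(2))
        assert dropped[ANI] == 0 and dropped[AI] == 0
        assert dropped[NANI] == 15.0 and dropped[NAI] == 22.0

    def test_partial_keep(self):
        flow = np.zeros(4)
        flow[AI] = 100.0
        out = rs.apply_initiation_effect(flow, np.array([1.0, 0.3]))
        assert out[AI] == pytest.approx(30.0)
        assert out[NAI] == pytest.approx(70.0)

    def test_detox_forces_non_active(self):
        flow = np.array([10.0, 1.0, 6.0, 1.0])
        out = rs.apply_initiation_effect(flow, np.ones(2), detox=True)
        assert out[ANI] == 0 and out[AI] == 0
        assert out.sum() == pytest.approx(flow.sum())


def _zeroed_toy(arrivals=0.0):
    import _microsim
    fixed, calib = _microsim.toy_inputs(n0=1000.0, arrivals=arrivals)
    zero = np.zeros((1, 1))
    fixed = rs.FixedInputs(
        strata=fixed.strata, years=fixed.years, n0=fixed.n0, t0=fixed.t0,
        p0=fixed.p0, demo_props=fixed.demo_props,
        arrival_oud_split=fixed.arrival_oud_split,
        lambda_moud=np.zeros((3, 1, 1)), lambda_detox_base=zero,
        lambda_tp=np.zeros(4), lambda_pn=0.0, gamma_t=fixed.gamma_t,
        rho_t=np.zeros((3, 8)), baseline_od=np.zeros((3, 1, 1)),
        inj_od_ratio=1.0, beta_n=zero, beta_t=zero, beta_p=zero)
    calib = rs.CalibratedInputs(
        arrivals=np.full(3, arrivals), eta=np.ones(3), gamma_p=np.ones(2),
        rho_n=np.zeros((1, 8)), rho_p=np.zeros((1, 8)), m_n=1.0,
        m_t=np.zeros(3), m_p=2.0, f=np.zeros(3))
    return fixed, calib


class TestWeeklyStep:
    def test_null_dynamics(self):
        fixed, calib = _zeroed_toy()
        cohort = rs.initial_cohort(fixed)[0]
        before = cohort.copy()
        cohort, ledger = rs.step_week(cohort, fixed, calib, 0)
        assert np.allclose(cohort, before)
        assert ledger["fatal_overdoses"] == 0
        assert ledger["other_deaths"] == 0

    def test_arrivals_only_growth(self):
        fixed, calib = _zeroed_toy(arrivals=50.0)
        cohort = rs.initial_cohort(fixed)[0]
        start = cohort.sum()
        for week in range(10):
            cohort, _ = rs.step_week(cohort, fixed, calib, week)
        assert cohort.sum() == pytest.approx(start + 500.0, rel=1e-12)

    def test_negative_occupancy_raises(self):
        fixed, calib = _zeroed_toy()
        cohort = rs.initial_cohort(fixed)
        cohort[0, 0, 0, 0, 0] = -5.0
        with pytest.raises(rs.IntegrityError):
            rs.step_week_batch(cohort, fixed, rs.CalibratedBatch.from_single(calib), 0)


class TestConservationAndInvariants:
    def test_population_conservation_every_cycle(self, fixed, midpoint):
        cohort = rs.initial_cohort(fixed)[0]
        total = cohort.sum()
        for week in range(26):
            cohort, ledger = rs.step_week(cohort, fixed, midpoint, week)
            total += (ledger["arrivals"] - ledger["other_deaths"]
                      - ledger["fatal_overdoses"])
            assert cohort.sum() == pytest.approx(total, rel=1e-9)

    def test_detox_occupancy_stays_non_active(self, fixed, midpoint):
        cohort = rs.initial_cohort(fixed)[0]
        for week in range(20):
            cohort, ledger = rs.step_week(cohort, fixed, midpoint, week)
            assert cohort[4, ANI].sum() == 0
            assert cohort[4, AI].sum() == 0
            assert ledger["overdoses_by_health"][4] == 0

    def test_annual_accounting_identity(self, fixed, midpoint, midpoint_outputs):
        # year-end alive must equal initial population plus cumulative
        # arrivals minus cumulative deaths (and total = alive + deaths)
        out = midpoint_outputs
        arrivals_per_year = midpoint.arrivals * 52
        expected_alive = fixed.total_initial
        for yi in range(3):
            expected_alive += (arrivals_per_year[yi] - out.fatal_overdoses[yi]
                               - out.other_deaths[yi])
            assert out.alive[yi] == pytest.approx(expected_alive, rel=1e-9)
            assert out.total_oud[yi] == pytest.approx(
                out.alive[yi] + out.fatal_overdoses[yi] + out.other_deaths[yi])

    def test_zero_fatal_proportion_means_zero_fatal(self, fixed, midpoint):
        calib = rs.CalibratedInputs(
            arrivals=midpoint.arrivals, eta=midpoint.eta,
            gamma_p=midpoint.gamma_p, rho_n=midpoint.rho_n,
            rho_p=midpoint.rho_p, m_n=midpoint.m_n, m_t=midpoint.m_t,
            m_p=midpoint.m_p, f=np.zeros(3))
        out = rs.run_simulation(fixed, calib)
        assert np.all(out.fatal_overdoses == 0)
        assert np.all(out.total_oud == out.alive + out.other_deaths)

    def test_monotonicity_in_mn_and_arrivals(self, fixed, midpoint):
        base = rs.run_simulation(fixed, midpoint)
        import dataclasses
        more_od = dataclasses.replace(midpoint, m_n=midpoint.m_n * 1.3)
        out = rs.run_simulation(fixed, more_od)
        assert np.all(out.fatal_overdoses >= base.fatal_overdoses)
        more_arr = dataclasses.replace(midpoint,
                                       arrivals=midpoint.arrivals * 1.5)
        out = rs.run_simulation(fixed, more_arr)
        assert np.all(out.alive >= base.alive)

    def test_horizon_validation(self, fixed, midpoint):
        with pytest.raises(rs.ConfigError):
            rs.run_simulation(fixed, midpoint, n_weeks=55)
        with pytest.raises(rs.ConfigError):
            rs.run_simulation(fixed, midpoint, n_weeks=52 * 4)

    def test_batch_matches_single(self, fixed, midpoint):
        single = rs.run_simulation(fixed, midpoint)
        batch = rs.run_simulation_batch(fixed, [midpoint, midpoint])
        assert np.allclose(batch.total_oud[0], single.total_oud)
        assert np.allclose(batch.total_oud[0], batch.total_oud[1])


class TestMicrosimOracle:
    """Cohort expectations vs an independent agent-based Monte-Carlo run."""

    def test_aggregates_within_three_se(self, microsim_comparison):
        expected, observed = microsim_comparison
        for key in ("alive", "n_active", "fatal", "other", "detox_entries",
                    "overdoses"):
            e, o = expected[key], observed[key]
            se = max(np.sqrt(e), 1.0)
            assert abs(o - e) <= 3 * se, f"{key}: expected {e}, got {o}"

    def test_health_group_occupancy_within_three_se(self, microsim_comparison):
        expected, observed = microsim_comparison
        for e, o in zip(expected["occ_group"], observed["occ_group"]):
            assert abs(o - e) <= 3 * max(np.sqrt(e), 1.0)
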