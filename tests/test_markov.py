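"""Cohort engine: conservation, half-cycle accounting, discounting."""

import numpy as np
import pytest

from ds3markov import (
    CohortTrace,
    HealthState,
    LifeTable,
    Scenario,
    Severity,
    life_expectancy,
    life_years,
    occupancy_shares,
    qalys,
    run_cohort,
)
from ds3markov.mortality import MAX_AGE
from ds3markov.transitions import ScenarioKey, YEARS_ON_TX

MILD = HealthState.from_rank(1)


def flat_table(q: float) -> LifeTable:
    qx = np.full(MAX_AGE + 1, q)
    qx[-1] = 1.0
    return LifeTable(np.arange(MAX_AGE + 1), qx)


def matrix_set(mat: np.ndarray, severity=Severity.MILD, spleen="intact"):
    return {ScenarioKey(t, severity, spleen): mat for t in YEARS_ON_TX}


def random_stochastic(rng) -> np.ndarray:
    m = rng.random((9, 9))
    return m / m.sum(axis=1, keepdims=True)


class TestRunCohort:
    def test_certain_death_absorbs_cohort_after_one_cycle(self):
        trace = run_cohort(Scenario(MILD), matrix_set(np.eye(9)), flat_table(1.0))
        assert trace.occupancy[0, 0] == 1.0
        np.testing.assert_allclose(trace.occupancy[1:, 9], 1.0)

    def test_identity_matrix_zero_mortality_is_fixed_point(self):
        trace = run_cohort(
            Scenario(MILD, horizon=40), matrix_set(np.eye(9)), flat_table(0.0)
        )
        np.testing.assert_allclose(trace.occupancy[:, 0], 1.0)

    def test_alive_mass_equals_survival_curve(self, matrices, mortality_curve):
        """Transitions conserve alive mass, so the trace's alive fraction is
        exactly the survival curve of the mortality module."""
        from ds3markov.mortality import survival_curve

        trace = run_cohort(Scenario(MILD), matrices, mortality_curve)
        np.testing.assert_allclose(
            trace.alive.sum(axis=1), survival_curve(mortality_curve, 32), atol=1e-12
        )

    def test_mass_conserved_and_dead_monotone(self, matrices, mortality_curve):
        trace = run_cohort(
            Scenario(HealthState.from_rank(7), spleen="splenectomized"),
            matrices,
            mortality_curve,
        )
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(trace.occupancy[:, 9]) >= -1e-15)

    def test_missing_matrix_key_reported(self, mortality_curve):
        mats = matrix_set(np.eye(9), severity=Severity.MODERATE)
        with pytest.raises(KeyError, match="Dmild"):
            run_cohort(Scenario(MILD), mats, mortality_curve)

    def test_trace_frame_has_ages_and_labels(self, matrices, mortality_curve):
        df = run_cohort(Scenario(MILD), matrices, mortality_curve).to_frame()
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert df["age"].iloc[0] == 32 and df.shape[1] == 12


class TestLifeYears:
    def test_certain_death_credits_half_year(self):
        trace = run_cohort(Scenario(MILD), matrix_set(np.eye(9)), flat_table(1.0))
        assert life_years(trace) == pytest.approx(0.5)

    def test_invariant_to_transition_matrices(self, mortality_curve, rng):
        """Person-years depend only on mortality: oracle equality with
        life_expectancy across random transition-matrix sets."""
        expected = life_expectancy(mortality_curve, 32)
        for _ in range(20):
            mats = matrix_set(random_stochastic(rng))
            trace = run_cohort(Scenario(MILD), mats, mortality_curve)
            assert life_years(trace) == pytest.approx(expected, abs=1e-9)

    def test_default_scenario_remaining_life_years(self, matrices, mortality_curve):
        trace = run_cohort(Scenario(MILD), matrices, mortality_curve)
        assert life_years(trace) == pytest.approx(42.29, abs=0.01)


class TestQalys:
    def test_half_cycle_exact_for_constant_occupancy(self):
        trace = run_cohort(
            Scenario(MILD, horizon=25), matrix_set(np.eye(9)), flat_table(0.0)
        )
        undisc, disc = qalys(trace, np.ones(9), discount_rate=0.0)
        assert undisc == pytest.approx(25.0)
        assert disc == pytest.approx(undisc)

    def test_one_cycle_discounting_conventions(self):
        """Full occupancy for one cycle, then extinction: the half-cycle
        increment is 0.5, discounted by 1 (start timing) or 1/1.035 (end)."""
        trace = run_cohort(Scenario(MILD), matrix_set(np.eye(9)), flat_table(1.0))
        _, disc_start = qalys(trace, np.ones(9), 0.035, timing="start")
        _, disc_end = qalys(trace, np.ones(9), 0.035, timing="end")
        assert disc_start == pytest.approx(0.5, abs=1e-12)
        assert disc_end == pytest.approx(0.4831, abs=1e-4)

    def test_discounted_below_undiscounted(self, matrices, mortality_curve, utilities):
        trace = run_cohort(Scenario(MILD), matrices, mortality_curve)
        undisc, disc = qalys(trace, utilities, 0.035)
        assert disc < undisc
        undisc0, disc0 = qalys(trace, utilities, 0.0)
        assert disc0 == pytest.approx(undisc0)

    def test_mild_intact_cohort_matches_published_qalys(
        self, matrices, mortality_curve, utilities
    ):
        trace = run_cohort(Scenario(MILD, spleen="intact"), matrices, mortality_curve)
        undisc, disc = qalys(trace, utilities, 0.035)
        assert undisc == pytest.approx(31.16, rel=0.02)
        assert disc == pytest.approx(15.73, rel=0.02)


class TestOccupancyShares:
    def test_single_state_trace_gives_100_percent(self):
        trace = run_cohort(
            Scenario(MILD, horizon=30), matrix_set(np.eye(9)), flat_table(0.02)
        )
        shares = occupancy_shares(trace)
        assert shares[0] == pytest.approx(100.0)
        assert shares.sum() == pytest.approx(100.0)

    def test_mild_intact_dominant_share(self, matrices, mortality_curve):
        shares = occupancy_shares(
            run_cohort(Scenario(MILD, spleen="intact"), matrices, mortality_curve)
        )
        assert shares[0] == pytest.approx(69.72, abs=2.0)
        assert shares.sum() == pytest.approx(100.0)


def test_trace_validation_rejects_bad_occupancy():
    occ = np.zeros((3, 10))
    occ[:, 0] = 1.0
    occ[1, 9] = 0.5  # row no longer sums to 1
    with pytest.raises(ValueError, match="sum to 1"):
        CohortTrace(occ, np.arange(3) + 32.0)
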