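"""Regression refits: likelihood oracle, equivariances, degenerate inputs."""

import math

import numpy as np
import pandas as pd
import pytest

from ds3markov import default_transition_coefficients
from ds3markov.estimation import (
    fit_transition_model,
    fit_utility_model,
    ordered_logit_loglike,
)
from ds3markov.simulate import SimulationSpec, simulate_panel, simulate_utility_panel


def tiny_state_panel() -> pd.DataFrame:
    rows = [
        (0, 1, 1, 1, "1", "mild", "intact"),
        (0, 2, 4, 1, "2", "mild", "intact"),
        (0, 3, 2, 4, "3plus", "mild", "intact"),
        (1, 1, 4, 4, "1", "moderate", "splenectomized"),
        (1, 2, 6, 4, "2", "moderate", "splenectomized"),
        (2, 1, 9, 7, "1", "marked", "splenectomized"),
        (2, 2, 7, 9, "2", "marked", "splenectomized"),
        (3, 1, 1, 2, "1", "mild", "intact"),
    ]
    return pd.DataFrame(
        rows,
        columns=["patient", "year", "state", "prev_state", "years_on_tx", "baseline_d", "spleen"],
    )


class TestOrderedLogitLikelihood:
    def test_matches_hand_enumeration_on_tiny_panel(self, trans_coefs):
        """Brute-force oracle: per-row category probability from the
        cumulative logistic, summed by hand."""
        panel = tiny_state_panel()
        expected = 0.0
        for _, row in panel.iterrows():
            lp = 0.0
            if row.prev_state >= 2:
                lp += trans_coefs.prev_state[int(row.prev_state)]
            if row.years_on_tx != "1":
                lp += trans_coefs.years_on_tx[row.years_on_tx]
            if row.baseline_d != "mild":
                lp += trans_coefs.baseline_d[row.baseline_d]
            if row.spleen == "intact":
                lp += trans_coefs.not_splenectomized
            cuts = (-math.inf,) + trans_coefs.cutpoints + (math.inf,)
            k = int(row.state)
            p = 1 / (1 + math.exp(-(cuts[k] - lp))) - 1 / (1 + math.exp(-(cuts[k - 1] - lp)))
            expected += math.log(p)
        assert ordered_logit_loglike(panel, trans_coefs) == pytest.approx(expected, abs=1e-10)


@pytest.fixture(scope="module")
def recovery_panel():
    spec = SimulationSpec(
        n_patients=500, n_years=10, seed=0,
        followup_mean=10, followup_sd=0, utility_obs_per_patient=2,
    )
    states = simulate_panel(spec)
    return spec, states


class TestTransitionFit:
    def test_single_outcome_category_rejected(self):
        panel = tiny_state_panel()
        panel["state"] = 1
        with pytest.raises(ValueError, match="categories"):
            fit_transition_model(panel)

    def test_row_duplication_leaves_point_estimates_unchanged(self, recovery_panel):
        _, states = recovery_panel
        sub = states  # full panel keeps all 9 outcome categories observed
        c1, _ = fit_transition_model(sub)
        c2, _ = fit_transition_model(pd.concat([sub, sub], ignore_index=True))
        v1, v2 = c1.to_dict(), c2.to_dict()
        for term in v1:
            assert v1[term] == pytest.approx(v2[term], abs=5e-4)

    def test_fitted_loglike_not_below_truth(self, recovery_panel, trans_coefs):
        """The MLE cannot have lower in-sample likelihood than the generating
        coefficients."""
        _, states = recovery_panel
        fitted, _ = fit_transition_model(states)
        assert ordered_logit_loglike(states, fitted) >= ordered_logit_loglike(
            states, trans_coefs
        ) - 1e-6

    def test_parameter_recovery_within_sampling_error(self, recovery_panel):
        _, states = recovery_panel
        fitted, ses = fit_transition_model(states)
        truth = default_transition_coefficients().to_dict()
        fit = fitted.to_dict()
        z = {k: (fit[k] - truth[k]) / ses[k] for k in truth}
        assert max(abs(v) for v in z.values()) < 3.0, z


class TestUtilityFit:
    def test_zero_noise_recovers_exactly(self, recovery_panel):
        spec, states = recovery_panel
        spec0 = SimulationSpec(
            n_patients=500, n_years=10, seed=0, followup_mean=10, followup_sd=0,
            utility_noise_sd=0.0, utility_obs_per_patient=3,
        )
        panel = simulate_utility_panel(spec0, states)
        fitted, _ = fit_utility_model(panel)
        truth = spec0.utility_coefs.to_dict()
        for term in ("constant", "d_moderate", "bone_pain", "ssc", "female", "age_at_init"):
            assert getattr(fitted, term) == pytest.approx(truth[term], abs=1e-8)

    def test_constant_shift_moves_only_intercept(self, recovery_panel):
        spec, states = recovery_panel
        panel = simulate_utility_panel(spec, states)
        base, _ = fit_utility_model(panel)
        shifted = panel.copy()
        shifted["utility"] = shifted["utility"] - 0.2  # stays inside the EQ-5D range
        refit, _ = fit_utility_model(shifted)
        assert refit.constant == pytest.approx(base.constant - 0.2, abs=1e-8)
        for term in ("d_moderate", "d_marked", "d_severe", "bone_pain", "ssc"):
            assert getattr(refit, term) == pytest.approx(getattr(base, term), abs=1e-8)

    def test_recovery_within_sampling_error(self, recovery_panel):
        spec, states = recovery_panel
        panel = simulate_utility_panel(spec, states)
        fitted, ses = fit_utility_model(panel)
        truth = spec.utility_coefs.to_dict()
        z = {k: (getattr(fitted, k) - truth[k]) / ses[k] for k in ses}
        assert max(abs(v) for v in z.values()) < 3.0, z

    def test_recycled_prediction_equals_mean_of_row_predictions(self, recovery_panel):
        """Identity link: prediction at covariate means = mean of per-row
        predictions with state indicators fixed."""
        from ds3markov import CovariateProfile, HealthState, state_utility

        spec, states = recovery_panel
        panel = simulate_utility_panel(spec, states)
        fitted, _ = fit_utility_model(panel)
        target = HealthState.from_rank(4)
        per_row = [
            state_utility(target, fitted, CovariateProfile(f, a))
            for f, a in zip(panel["female"], panel["age_at_init"])
        ]
        at_means = state_utility(
            target, fitted, CovariateProfile(fitted.mean_female, fitted.mean_age)
        )
        assert at_means == pytest.approx(np.mean(per_row), abs=1e-10)

    def test_fewer_than_two_patients_rejected(self, recovery_panel):
        spec, states = recovery_panel
        panel = simulate_utility_panel(spec, states)
        single = panel[panel.patient == panel.patient.iloc[0]]
        with pytest.raises(ValueError, match="patients"):
            fit_utility_model(single)

    def test_collinear_design_rejected(self, recovery_panel):
        spec, states = recovery_panel
        panel = simulate_utility_panel(spec, states)
        panel = panel[panel.state <= 7]  # drop both severe states
        with pytest.raises(ValueError, match="collinear"):
            fit_utility_model(panel)


def test_end_to_end_closure_of_the_parameter_pipeline(
    recovery_panel, mortality_curve, utilities
):
    """simulate -> refit -> matrices -> cohort: projections from refitted
    coefficients agree with projections from the generating coefficients."""
    from ds3markov import (
        HealthState,
        Scenario,
        all_matrices,
        qalys,
        run_cohort,
    )

    _, states = recovery_panel
    fitted, _ = fit_transition_model(states)
    truth = default_transition_coefficients()
    results = {}
    for name, coefs in (("truth", truth), ("fitted", fitted)):
        trace = run_cohort(
            Scenario(HealthState.from_rank(1)), all_matrices(coefs), mortality_curve
        )
        results[name] = qalys(trace, utilities, 0.035)
    assert results["fitted"][0] == pytest.approx(results["truth"][0], rel=0.05)
    assert results["fitted"][1] == pytest.approx(results["truth"][1], rel=0.05)
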