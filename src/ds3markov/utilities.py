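"""Health-state utilities by recycled predictions.

The utility regression has an identity link, so the recycled prediction —
the mean of per-subject predictions with the state indicators fixed —
equals the prediction at the sample covariate means.  Each state's utility
is the linear predictor at those means, with the published rule that the
bone-pain effect is included for every state containing severe skeletal
complications (SSC), not just the mild-with-bone-pain state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import UtilityCoefficients
from .states import STATES, HealthState

__all__ = ["CovariateProfile", "state_utility", "utility_table"]


@dataclass(frozen=True)
class CovariateProfile:
    """Covariate values at which utilities are predicted.

    Defaults are the estimation-sample means (69.1% female, age 53.9 at
    treatment initiation), which is what recycled predictions average over.
    """

    prop_female: float = 0.691
    mean_age_at_init: float = 53.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError(
                f"prop_female must be in [0, 1], got {self.prop_female}"
            )


def state_utility(
    state: HealthState,
    coefs: UtilityCoefficients,
    profile: CovariateProfile | None = None,
) -> float:
    """Predicted utility of one health state at the profile's covariate values.

    utility = constant + severity contrast
              + bone_pain * [state has BP or SSC] + ssc * [state has SSC]
              + female * prop_female + age_at_init * mean_age_at_init
    """
    profile = profile if profile is not None else CovariateProfile()
    u = (
        coefs.constant
        + coefs.severity_contrast(state.severity)
        + coefs.bone_pain * (state.has_bp or state.has_ssc)
        + coefs.ssc * state.has_ssc
        + coefs.female * profile.prop_female
        + coefs.age_at_init * profile.mean_age_at_init
    )
    if not 0.0 <= u <= 1.0:
        warnings.warn(
            f"predicted utility {u:.4f} for state {state.label!r} lies outside "
            "[0, 1]; no censoring is applied",
            stacklevel=2,
        )
    return float(u)


def utility_table(
    coefs: UtilityCoefficients, profile: CovariateProfile | None = None
) -> np.ndarray:
    """Utilities of all nine states as a vector indexed by rank - 1."""
    return np.array([state_utility(s, coefs, profile) for s in STATES])
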