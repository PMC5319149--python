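"""Annual transition probability matrices among the nine alive states.

A single proportional-odds (ordered logistic) regression drives all
transitions: the next-year state rank has cumulative probabilities
P(rank <= k) = sigma(cut_k - x*beta), where the linear predictor x*beta sums
the previous-state contrast, the years-on-treatment contrast, the
baseline-severity contrast, and the intact-spleen term.  With every
covariate categorical and fixed within a scenario, the recycled prediction
coincides with the direct prediction, so each of the 24 scenario matrices
(3 treatment-duration levels x 4 baseline severities x 2 spleen statuses)
is built row by row from the category probabilities at each previous state.

Death is not a category of this model; the Markov engine overlays
age-specific mortality separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

import numpy as np
from scipy.special import expit

from .params import TransitionCoefficients
from .states import STATES, HealthState, Severity

__all__ = [
    "ScenarioKey",
    "YEARS_ON_TX",
    "linear_predictor",
    "category_probabilities",
    "transition_matrix",
    "all_matrices",
    "clamp_years_on_tx",
]

#: Treatment-duration categories: first year, second year, third and later.
YEARS_ON_TX = ("1", "2", "3plus")
SPLEEN = ("splenectomized", "intact")


@dataclass(frozen=True)
class ScenarioKey:
    """Covariate cell defining one transition matrix.

    24 distinct keys exist: years_on_tx in {1, 2, 3plus} x baseline
    severity in {mild, moderate, marked, severe} x spleen status in
    {splenectomized, intact}.
    """

    years_on_tx: str
    baseline_d: Severity
    spleen: str

    def __post_init__(self) -> None:
        if self.years_on_tx not in YEARS_ON_TX:
            raise ValueError(f"years_on_tx must be one of {YEARS_ON_TX}")
        if self.spleen not in SPLEEN:
            raise ValueError(f"spleen must be one of {SPLEEN}")
        if not isinstance(self.baseline_d, Severity):
            object.__setattr__(self, "baseline_d", Severity(self.baseline_d))

    @property
    def label(self) -> str:
        return f"T{self.years_on_tx}_D{self.baseline_d.value}_{self.spleen}"


def clamp_years_on_tx(cycle: int) -> str:
    """Map a 1-based cycle index to the treatment-duration category."""
    if cycle < 1:
        raise ValueError(f"cycle index must be >= 1, got {cycle}")
    return "1" if cycle == 1 else ("2" if cycle == 2 else "3plus")


def linear_predictor(
    prev: HealthState, key: ScenarioKey, coefs: TransitionCoefficients
) -> float:
    """x*beta for a row: previous-state + treatment-year + baseline-D + spleen terms."""
    lp = coefs.prev_contrast(prev)
    if key.years_on_tx != "1":
        lp += coefs.years_on_tx[key.years_on_tx]
    if key.baseline_d is not Severity.MILD:
        lp += coefs.baseline_d[key.baseline_d.value]
    if key.spleen == "intact":
        lp += coefs.not_splenectomized
    return float(lp)


def category_probabilities(lp: float, cutpoints) -> np.ndarray:
    """Per-rank probabilities from the cumulative logistic at one linear predictor.

    P(rank <= k) = expit(cut_k - lp) for k = 1..8; category probabilities are
    successive differences, with P(rank = 9) absorbing the upper tail.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.shape != (8,):
        raise ValueError(f"expected 8 cutpoints, got shape {cuts.shape}")
    if np.any(np.diff(cuts) < 0):
        raise ValueError("cutpoints must be nondecreasing")
    cum = expit(cuts - lp)
    probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    # tiny negatives can appear when adjacent cutpoints are equal
    return np.clip(probs, 0.0, 1.0)


def transition_matrix(
    key: ScenarioKey, coefs: TransitionCoefficients
) -> np.ndarray:
    """9x9 row-stochastic matrix; row r = next-state distribution from state r+1."""
    rows = [
        category_probabilities(linear_predictor(s, key, coefs), coefs.cutpoints)
        for s in STATES
    ]
    mat = np.vstack(rows)
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


def iter_keys() -> Iterator[ScenarioKey]:
    for t, d, s in product(YEARS_ON_TX, Severity, SPLEEN):
        yield ScenarioKey(t, d, s)


def all_matrices(coefs: TransitionCoefficients) -> dict[ScenarioKey, np.ndarray]:
    """All 24 annual transition matrices keyed by (years on treatment, baseline D, spleen)."""
    return {key: transition_matrix(key, coefs) for key in iter_keys()}
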