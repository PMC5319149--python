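"""Markov cohort engine: annual cycles, QALYs, occupancy shares.

A cohort starts with mass 1 in one health state and moves through annual
cycles until extinction (age 110 by default).  Each cycle applies
age-specific mortality uniformly across alive states (mortality depends on
age, not on the DS3 state), then redistributes survivors with the
transition matrix for the scenario's covariate cell; the cell's
treatment-duration category advances 1 -> 2 -> 3plus with the cycle index
while baseline severity and splenectomy status stay fixed for the whole
run.  Because transitions conserve alive mass, total person-years equal
the life expectancy implied by the mortality curve alone, whatever the
transition matrices.

QALYs and person-years use the half-cycle correction: each cycle credits
the average of its start and end occupancy.  Discounting (3.5%/year by
default) multiplies cycle t's half-cycle-corrected increment by
(1+r)^-(t-1) — time zero at the start of the first cycle, so first-year
benefits are undiscounted, as in spreadsheet cohort models
(``timing="end"`` selects (1+r)^-t instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import MAX_AGE
from .params import LifeTable, TransitionCoefficients
from .states import STATE_LABELS, HealthState
from .transitions import ScenarioKey, all_matrices, clamp_years_on_tx

__all__ = [
    "Scenario",
    "CohortTrace",
    "run_cohort",
    "qalys",
    "occupancy_shares",
    "life_years",
]


@dataclass(frozen=True)
class Scenario:
    """One simulated cohort: start state, fixed covariates, and run settings."""

    start_state: HealthState
    spleen: str = "intact"
    start_age: int = 32
    prop_female: float = 0.5  # recorded; transitions carry no sex term
    discount_rate: float = 0.035
    horizon: int | None = None  # cycles; None runs to extinction at MAX_AGE

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        if not 0 <= self.start_age < MAX_AGE:
            raise ValueError(f"start_age must be in [0, {MAX_AGE}), got {self.start_age}")
        if self.spleen not in ("splenectomized", "intact"):
            raise ValueError(f"unknown spleen status {self.spleen!r}")

    @property
    def n_cycles(self) -> int:
        # running to MAX_AGE + 1 lets the terminal q = 1 extinguish the cohort
        return self.horizon if self.horizon is not None else MAX_AGE + 1 - self.start_age


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy history: rows = cycles 0..H, columns = 9 alive states + dead."""

    occupancy: np.ndarray  # shape (H+1, 10), fractions of the initial cohort
    ages: np.ndarray  # age at each cycle boundary

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 10:
            raise ValueError(f"occupancy must be (H+1, 10), got {occ.shape}")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("occupancy rows must each sum to 1")
        if np.any(np.diff(occ[:, 9]) < -1e-12):
            raise ValueError("dead occupancy must be nondecreasing")

    @property
    def alive(self) -> np.ndarray:
        """Alive-state occupancy, shape (H+1, 9)."""
        return self.occupancy[:, :9]

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[*STATE_LABELS, "dead"])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def run_cohort(
    scenario: Scenario,
    matrices: dict[ScenarioKey, np.ndarray] | TransitionCoefficients,
    mortality: LifeTable,
) -> CohortTrace:
    """Propagate the cohort through annual cycles of death-then-transition.

    ``matrices`` may be the dict from :func:`ds3markov.transitions.all_matrices`
    or the raw coefficients (matrices are then built on the fly).  The
    scenario's baseline severity is the severity component of its start
    state, fixed for the whole run.
    """
    if isinstance(matrices, TransitionCoefficients):
        matrices = all_matrices(matrices)

    n = scenario.n_cycles
    occ = np.zeros((n + 1, 10))
    occ[0, scenario.start_state.rank - 1] = 1.0
    ages = scenario.start_age + np.arange(n + 1)

    for t in range(1, n + 1):
        age = int(ages[t - 1])
        q = mortality.q(min(age, mortality.max_age))
        key = ScenarioKey(
            clamp_years_on_tx(t), scenario.start_state.severity, scenario.spleen
        )
        try:
            mat = matrices[key]
        except KeyError:
            raise KeyError(f"no transition matrix for scenario cell {key.label}") from None
        alive = occ[t - 1, :9] * (1.0 - q)
        occ[t, :9] = alive @ mat
        occ[t, 9] = occ[t - 1, 9] + occ[t - 1, :9].sum() * q
        # guard against drift over long horizons
        occ[t] /= occ[t].sum()

    return CohortTrace(occ, ages)


def _half_cycle_increments(values: np.ndarray) -> np.ndarray:
    """Per-cycle increments (value at start + value at end) / 2, length H."""
    return 0.5 * (values[:-1] + values[1:])


def qalys(
    trace: CohortTrace,
    utilities: np.ndarray,
    discount_rate: float = 0.035,
    timing: str = "start",
) -> tuple[float, float]:
    """(undiscounted, discounted) total QALYs under the half-cycle correction.

    ``timing`` fixes the discount exponent of cycle t (1-based):
    ``"start"`` uses (1+r)^-(t-1) (first-year increments undiscounted),
    ``"end"`` uses (1+r)^-t.
    """
    utilities = np.asarray(utilities, dtype=float)
    if utilities.shape != (9,):
        raise ValueError(f"utilities must be a 9-vector, got {utilities.shape}")
    if timing not in ("start", "end"):
        raise ValueError(f"timing must be 'start' or 'end', got {timing!r}")
    per_cycle = _half_cycle_increments(trace.alive @ utilities)
    t = np.arange(1, len(per_cycle) + 1, dtype=float)
    exponent = t - 1.0 if timing == "start" else t
    factors = (1.0 + discount_rate) ** (-exponent)
    return float(per_cycle.sum()), float((per_cycle * factors).sum())


def life_years(trace: CohortTrace) -> float:
    """Total half-cycle-corrected person-years alive."""
    return float(_half_cycle_increments(trace.alive.sum(axis=1)).sum())


def occupancy_shares(trace: CohortTrace) -> np.ndarray:
    """Percent of remaining lifetime spent in each of the 9 states (sums to 100)."""
    person_years = _half_cycle_increments(trace.alive).sum(axis=0)
    total = person_years.sum()
    if total <= 0:
        raise ValueError("trace has no person-years alive")
    return 100.0 * person_years / total
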