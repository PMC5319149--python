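"""GD1-specific mortality: Gompertz calibration and life-table splicing.

Disease-specific mortality for treated Gaucher type 1 patients is modelled
with a Gompertz hazard h(x) = a * exp(b * x) whose two parameters are
identified from published summary life expectancies (life expectancy at
birth, and remaining life expectancy at age 32).  Because a Gompertz curve
fitted to a reduced life expectancy can fall *below* general-population
mortality at high ages, the model uses the elementwise maximum of the
disease-specific and general-population annual death probabilities.

Life expectancies here use the half-interval convention
``e(x) = 0.5 + sum_t S(x, t)``, crediting half a year in the year of
death — the same half-cycle convention as the Markov engine, so the
engine's person-years and these life expectancies agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import LifeTable

__all__ = [
    "GompertzParams",
    "gompertz_annual_prob",
    "gompertz_curve",
    "splice",
    "life_expectancy",
    "survival_curve",
    "calibrate",
    "default_mortality_curve",
    "make_synthetic_uk_life_table",
]

MAX_AGE = 110  # cohort-extinction bound; occupancy beyond here is negligible

#: Published summary targets: overall life expectancy at birth for treated
#: GD1 (68 y) and the remaining life years at age 32 used by the cohort
#: analyses (42.29 y).
DEFAULT_TARGETS = {"e0": 68.0, "e32": 42.29}
#: Spleen-stratified life expectancies at birth, available as alternative
#: calibration targets (remaining-life target then scales with e0).
SPLEEN_E0 = {"splenectomized": 64.0, "intact": 72.0}


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard h(x) = a * exp(b * x); b = 0 is the constant-hazard limit."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"baseline hazard a must be positive, got {self.a}")
        if self.b < 0:
            raise ValueError(f"log-hazard slope b must be nonnegative, got {self.b}")


def gompertz_annual_prob(params: GompertzParams, age) -> np.ndarray | float:
    """Annual death probability q(age) = 1 - exp(-H) with H the hazard
    integrated over [age, age+1]."""
    age = np.asarray(age, dtype=float)
    a, b = params.a, params.b
    if b == 0.0:
        q = np.full_like(age, 1.0 - np.exp(-a))
    else:
        integrated = (a / b) * (np.exp(b * (age + 1.0)) - np.exp(b * age))
        q = 1.0 - np.exp(-integrated)
    return q if q.ndim else float(q)


def gompertz_curve(params: GompertzParams, max_age: int = MAX_AGE) -> LifeTable:
    """Gompertz death probabilities tabulated for ages 0..max_age (terminal q = 1)."""
    ages = np.arange(max_age + 1)
    q = np.asarray(gompertz_annual_prob(params, ages), dtype=float)
    q[-1] = 1.0
    return LifeTable(ages, q)


def splice(gd1: LifeTable, general: LifeTable) -> LifeTable:
    """Elementwise maximum of the disease-specific and general-population q(x)."""
    if gd1.max_age != general.max_age:
        raise ValueError(
            f"age-range mismatch: {gd1.max_age} vs {general.max_age}"
        )
    return LifeTable(gd1.ages, np.maximum(gd1.qx, general.qx))


def survival_curve(curve: LifeTable, from_age: int) -> np.ndarray:
    """S(from_age, t) for t = 0..(max_age - from_age + 1); S(., 0) = 1."""
    q = curve.qx[from_age:]
    return np.concatenate([[1.0], np.cumprod(1.0 - q)])


def life_expectancy(curve: LifeTable, from_age: int) -> float:
    """Remaining life expectancy at ``from_age`` with the half-interval convention."""
    if not 0 <= from_age <= curve.max_age:
        raise ValueError(f"from_age {from_age} outside table range")
    s = survival_curve(curve, from_age)
    return float(s[1:].sum() + 0.5)


def calibrate(
    general: LifeTable,
    targets: dict[str, float] | None = None,
    tol: float = 1e-10,
) -> GompertzParams:
    """Find Gompertz (a, b) whose spliced curve matches both life-expectancy targets.

    Solves the 2-d root problem e(0) = targets['e0'], e(32) = targets['e32']
    on the curve spliced with ``general``, parameterized as (log a, b) so the
    positivity constraint is automatic.

    Raises
    ------
    RuntimeError
        If the root finder does not converge; the message carries the
        residual life-expectancy errors in years.
    """
    targets = dict(DEFAULT_TARGETS if targets is None else targets)
    e0_gen = life_expectancy(general, 0)
    if targets["e0"] >= e0_gen:
        raise ValueError(
            f"target e0={targets['e0']} not below the general-population "
            f"e0={e0_gen:.2f}; disease-specific calibration is infeasible"
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        params = GompertzParams(a=float(np.exp(x[0])), b=float(abs(x[1])))
        spliced = splice(gompertz_curve(params, general.max_age), general)
        return np.array(
            [
                life_expectancy(spliced, 0) - targets["e0"],
                life_expectancy(spliced, 32) - targets["e32"],
            ]
        )

    sol = optimize.root(residuals, x0=np.array([np.log(5e-3), 0.04]), tol=tol)
    res = residuals(sol.x)
    if not sol.success or np.max(np.abs(res)) > 1e-4:
        raise RuntimeError(
            f"Gompertz calibration did not converge: residuals e0={res[0]:.2e} y, "
            f"e32={res[1]:.2e} y"
        )
    return GompertzParams(a=float(np.exp(sol.x[0])), b=float(abs(sol.x[1])))


def default_mortality_curve(
    general: LifeTable | None = None, targets: dict[str, float] | None = None
) -> tuple[LifeTable, GompertzParams]:
    """Calibrated, spliced GD1 mortality curve with its fitted Gompertz parameters."""
    from .params import default_life_table

    general = general if general is not None else default_life_table()
    params = calibrate(general, targets)
    return splice(gompertz_curve(params, general.max_age), general), params


# Gompertz-Makeham parameters for the packaged synthetic UK-like life table
# (accident floor A, senescent amplitude R, slope alpha); chosen to give
# e0 ~ 80.7 y, in the range of recent UK period tables.
_MAKEHAM = {"A": 2.0e-4, "R": 8.0e-6, "alpha": 0.11}


def make_synthetic_uk_life_table(max_age: int = MAX_AGE) -> LifeTable:
    """Synthetic general-population life table (Gompertz-Makeham).

    A smooth stand-in approximating UK period mortality, shipped so the
    package needs no external download; any real life table with the same
    CSV schema (age, qx) can be substituted.
    """
    A, R, al = _MAKEHAM["A"], _MAKEHAM["R"], _MAKEHAM["alpha"]
    ages = np.arange(max_age + 1, dtype=float)
    integrated = A + (R / al) * (np.exp(al * (ages + 1.0)) - np.exp(al * ages))
    q = 1.0 - np.exp(-integrated)
    q[-1] = 1.0
    return LifeTable(ages.astype(int), q)
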