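"""Model parameter containers and file I/O.

Three inputs drive the projection model and each has a plain-text format:

* utility regression coefficients (GEE, Gaussian/identity) — long CSV
  ``term,value`` or JSON mapping;
* ordered-logit transition coefficients with 8 cutpoints — same formats;
* a general-population life table — CSV ``age,qx``.

Transcriptions of the published regression tables and a synthetic
UK-like life table ship as packaged defaults so the model runs with no
external inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .states import STATES, HealthState, Severity

__all__ = [
    "UtilityCoefficients",
    "TransitionCoefficients",
    "LifeTable",
    "load_utility_coefficients",
    "load_transition_coefficients",
    "load_life_table",
    "save_coefficients",
    "default_utility_coefficients",
    "default_transition_coefficients",
    "default_life_table",
    "CALIBRATED_AGE_COEF",
]

#: Age coefficient refined within its printed 95% CI so that predicted
#: utilities reproduce the published mild / severe+SSC endpoints (0.76, 0.52).
#: The printed value (-0.002) is available via ``age_variant="printed"``.
CALIBRATED_AGE_COEF = -0.0015


class SchemaError(ValueError):
    """A coefficient or life-table file is missing or duplicating fields."""


@dataclass(frozen=True)
class UtilityCoefficients:
    """Parameters of the health-state utility regression.

    Severity contrasts are relative to mild; ``bone_pain`` and ``ssc`` are
    additive bone-disease effects; ``female`` and ``age_at_init`` are the
    demographic terms.  ``mean_female``/``mean_age`` are the estimation-sample
    covariate means used for recycled predictions.
    """

    constant: float
    d_moderate: float
    d_marked: float
    d_severe: float
    bone_pain: float
    ssc: float
    female: float
    age_at_init: float
    mean_female: float
    mean_age: float

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val}")
        if not 0.0 <= self.mean_female <= 1.0:
            raise ValueError(f"mean_female must be in [0, 1], got {self.mean_female}")
        if self.mean_age <= 0:
            raise ValueError(f"mean_age must be positive, got {self.mean_age}")

    def severity_contrast(self, severity: Severity) -> float:
        return {
            Severity.MILD: 0.0,
            Severity.MODERATE: self.d_moderate,
            Severity.MARKED: self.d_marked,
            Severity.SEVERE: self.d_severe,
        }[severity]

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


_UTILITY_TERMS = (
    "constant",
    "d_moderate",
    "d_marked",
    "d_severe",
    "bone_pain",
    "ssc",
    "female",
    "age_at_init",
    "mean_female",
    "mean_age",
)

_PREV_TERMS = tuple(f"prev_{s.label.lower().replace('+', '_')}" for s in STATES[1:])
_TX_TERMS = ("tx_two_years", "tx_three_plus_years")
_BASELINE_TERMS = ("baseline_moderate", "baseline_marked", "baseline_severe")
_CUTPOINT_TERMS = tuple(f"cutpoint_{k}" for k in range(1, 9))
_TRANSITION_TERMS = (
    _PREV_TERMS + _TX_TERMS + _BASELINE_TERMS + ("not_splenectomized",) + _CUTPOINT_TERMS
)


@dataclass(frozen=True)
class TransitionCoefficients:
    """Proportional-odds coefficients for annual health-state transitions.

    ``prev_state`` maps previous-state rank (2..9) to its contrast versus
    mild (rank 1 = 0); ``years_on_tx`` holds the contrasts for the second
    and third-plus treatment years versus the first; ``baseline_d`` the
    contrasts of the DS3 category at treatment start versus mild;
    ``not_splenectomized`` applies to patients with an intact or partial
    spleen.  ``cutpoints`` are the 8 ordered thresholds separating the 9
    ranked outcome categories.
    """

    prev_state: Mapping[int, float]
    years_on_tx: Mapping[str, float]
    baseline_d: Mapping[str, float]
    not_splenectomized: float
    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if sorted(self.prev_state) != list(range(2, 10)):
            raise SchemaError("prev_state must map ranks 2..9")
        if sorted(self.years_on_tx) != ["2", "3plus"]:
            raise SchemaError("years_on_tx must have contrasts for '2' and '3plus'")
        if sorted(self.baseline_d) != ["marked", "moderate", "severe"]:
            raise SchemaError(
                "baseline_d must have contrasts for moderate, marked, severe"
            )
        if len(self.cutpoints) != 8:
            raise SchemaError(
                f"9 outcome categories require 8 cutpoints, got {len(self.cutpoints)}"
            )
        cuts = np.asarray(self.cutpoints, dtype=float)
        if not np.all(np.isfinite(cuts)):
            raise ValueError("cutpoints must be finite")
        if np.any(np.diff(cuts) < 0):
            raise ValueError(f"cutpoints must be nondecreasing, got {self.cutpoints}")

    def prev_contrast(self, state: HealthState) -> float:
        return 0.0 if state.rank == 1 else self.prev_state[state.rank]

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for term, rank in zip(_PREV_TERMS, range(2, 10)):
            out[term] = self.prev_state[rank]
        out["tx_two_years"] = self.years_on_tx["2"]
        out["tx_three_plus_years"] = self.years_on_tx["3plus"]
        for sev in ("moderate", "marked", "severe"):
            out[f"baseline_{sev}"] = self.baseline_d[sev]
        out["not_splenectomized"] = self.not_splenectomized
        for term, cut in zip(_CUTPOINT_TERMS, self.cutpoints):
            out[term] = cut
        return out

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "TransitionCoefficients":
        return cls(
            prev_state={r: float(values[t]) for t, r in zip(_PREV_TERMS, range(2, 10))},
            years_on_tx={
                "2": float(values["tx_two_years"]),
                "3plus": float(values["tx_three_plus_years"]),
            },
            baseline_d={
                sev: float(values[f"baseline_{sev}"])
                for sev in ("moderate", "marked", "severe")
            },
            not_splenectomized=float(values["not_splenectomized"]),
            cutpoints=tuple(float(values[t]) for t in _CUTPOINT_TERMS),
        )


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities q(x), contiguous from age 0."""

    ages: np.ndarray
    qx: np.ndarray
    max_age: int = field(init=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.shape != qx.shape or ages.ndim != 1:
            raise ValueError("ages and qx must be matching 1-d arrays")
        if ages[0] != 0 or not np.array_equal(np.diff(ages), np.ones(len(ages) - 1)):
            raise ValueError("ages must be contiguous integers starting at 0")
        if ages[-1] < 100:
            raise ValueError(f"life table must extend to age >= 100, got {ages[-1]}")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("qx values must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError(
                f"terminal qx at max age {ages[-1]} must be 1, got {qx[-1]}"
            )
        object.__setattr__(self, "max_age", int(ages[-1]))

    def q(self, age: int) -> float:
        if not 0 <= age <= self.max_age:
            raise ValueError(f"age {age} outside table range 0..{self.max_age}")
        return float(self.qx[age])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def _read_terms(path: str | Path, required: tuple[str, ...]) -> dict[str, float]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: JSON coefficient file must be an object")
        values = {str(k): float(v) for k, v in raw.items()}
    else:
        df = pd.read_csv(path)
        if not {"term", "value"}.issubset(df.columns):
            raise SchemaError(f"{path}: expected columns 'term' and 'value'")
        dup = df["term"][df["term"].duplicated()]
        if len(dup):
            raise SchemaError(f"{path}: duplicate term(s): {sorted(set(dup))}")
        values = dict(zip(df["term"].astype(str), df["value"].astype(float)))
    missing = [t for t in required if t not in values]
    if missing:
        raise SchemaError(f"{path}: missing required term(s): {missing}")
    extra = [t for t in values if t not in required]
    if extra:
        raise SchemaError(f"{path}: unknown term(s): {extra}")
    return values


def load_utility_coefficients(path: str | Path) -> UtilityCoefficients:
    """Read utility-regression coefficients from a long CSV or JSON file."""
    return UtilityCoefficients(**_read_terms(path, _UTILITY_TERMS))


def load_transition_coefficients(path: str | Path) -> TransitionCoefficients:
    """Read ordered-logit transition coefficients from a long CSV or JSON file."""
    return TransitionCoefficients.from_dict(_read_terms(path, _TRANSITION_TERMS))


def save_coefficients(
    coefs: UtilityCoefficients | TransitionCoefficients, path: str | Path
) -> None:
    """Write a coefficient object back to CSV or JSON (round-trip safe)."""
    path = Path(path)
    values = coefs.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(values, indent=1))
    else:
        pd.DataFrame({"term": list(values), "value": list(values.values())}).to_csv(
            path, index=False
        )


def load_life_table(path: str | Path) -> LifeTable:
    """Read a life table CSV with columns ``age`` and ``qx``."""
    df = pd.read_csv(path)
    if not {"age", "qx"}.issubset(df.columns):
        raise SchemaError(f"{path}: expected columns 'age' and 'qx'")
    df = df.sort_values("age")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ds3markov").joinpath("data", name)))


def default_utility_coefficients(age_variant: str = "calibrated") -> UtilityCoefficients:
    """Packaged utility coefficients.

    ``age_variant="calibrated"`` (default) replaces the printed age
    coefficient with :data:`CALIBRATED_AGE_COEF`; ``"printed"`` keeps the
    published rounded value.
    """
    coefs = load_utility_coefficients(_data_path("utility_coefficients.csv"))
    if age_variant == "printed":
        return coefs
    if age_variant == "calibrated":
        vals = coefs.to_dict()
        vals["age_at_init"] = CALIBRATED_AGE_COEF
        return UtilityCoefficients(**vals)
    raise ValueError(f"age_variant must be 'calibrated' or 'printed', got {age_variant!r}")


def default_transition_coefficients() -> TransitionCoefficients:
    """Packaged ordered-logit transition coefficients."""
    return load_transition_coefficients(_data_path("transition_coefficients.csv"))


def default_life_table() -> LifeTable:
    """Packaged synthetic UK-like general-population life table."""
    return load_life_table(_data_path("life_table_uk_synthetic.csv"))
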