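"""The nine-state DS3 health-state space for treated Gaucher disease type 1.

Health states combine the total-DS3 severity category (mild, moderate,
marked, severe) with bone-disease status: bone pain (BP, distinguished only
within the mild band) or severe skeletal complications (SSC: lytic lesions,
avascular necrosis, or fracture).  The rank order 1..9 is the ordinal
outcome used by the transition regression; death is handled separately as
an absorbing state (index ``DEAD``), never as an ordinal category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator


class Severity(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    MARKED = "marked"
    SEVERE = "severe"


class Bone(str, Enum):
    NONE = "none"
    BP = "BP"  # bone pain without severe skeletal complications
    SSC = "SSC"  # severe skeletal complications


@dataclass(frozen=True, order=True)
class HealthState:
    """One of the nine ranked alive health states.

    Attributes
    ----------
    rank
        Ordinal rank 1 (best: mild, no bone symptoms) .. 9 (worst:
        severe with SSC).
    severity
        Total-DS3 severity band.
    bone
        Bone-disease status; BP occurs only in the mild band, the other
        bands distinguish only the presence/absence of SSC.
    """

    rank: int
    severity: Severity = Severity.MILD
    bone: Bone = Bone.NONE

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= 9:
            raise ValueError(f"rank must be in 1..9, got {self.rank}")
        expected = _TAXONOMY[self.rank - 1]
        if (self.severity, self.bone) != expected:
            raise ValueError(
                f"rank {self.rank} must be {expected[0].value}/{expected[1].value}, "
                f"got {self.severity.value}/{self.bone.value}"
            )

    @property
    def has_bp(self) -> bool:
        return self.bone is Bone.BP

    @property
    def has_ssc(self) -> bool:
        return self.bone is Bone.SSC

    @property
    def label(self) -> str:
        if self.bone is Bone.NONE:
            return self.severity.value
        suffix = "BP" if self.bone is Bone.BP else "SSC"
        return f"{self.severity.value}+{suffix}"

    @classmethod
    def from_rank(cls, rank: int) -> "HealthState":
        sev, bone = _TAXONOMY[rank - 1]
        return cls(rank, sev, bone)

    @classmethod
    def from_label(cls, label: str) -> "HealthState":
        try:
            return _BY_LABEL[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown health state label: {label!r}") from None


# rank -> (severity, bone); BP only in the mild band, per the state taxonomy
_TAXONOMY = (
    (Severity.MILD, Bone.NONE),
    (Severity.MILD, Bone.BP),
    (Severity.MILD, Bone.SSC),
    (Severity.MODERATE, Bone.NONE),
    (Severity.MODERATE, Bone.SSC),
    (Severity.MARKED, Bone.NONE),
    (Severity.MARKED, Bone.SSC),
    (Severity.SEVERE, Bone.NONE),
    (Severity.SEVERE, Bone.SSC),
)

STATES: tuple[HealthState, ...] = tuple(
    HealthState(i + 1, sev, bone) for i, (sev, bone) in enumerate(_TAXONOMY)
)

#: Index of the absorbing death state in cohort traces (alive ranks occupy 1..9).
DEAD = 10

STATE_LABELS: tuple[str, ...] = tuple(s.label for s in STATES)

_BY_LABEL = {s.label.lower(): s for s in STATES}
_BY_LABEL.update({s.label.lower().replace("+", " with "): s for s in STATES})
_BY_LABEL["mild with bp"] = STATES[1]


def iter_states() -> Iterator[HealthState]:
    return iter(STATES)
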