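"""Domain types for rapid eye-health survey data.

The vocabulary mirrors field practice: visual acuity is recorded as the best
Snellen threshold passed (a seven-level ordinal scale from 6/12 down to no
perception of light), each eye carries a lens-status finding and a main cause
of vision impairment, and each participant carries demographics, enrolment
status and two eye examinations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence


class VAGrade(enum.IntEnum):
    """Ordinal visual-acuity category: the best threshold the eye passed.

    The integer value is the rank: 0 is best (acuity 6/12 or better), 6 is
    worst (no perception of light). ``a > b`` therefore reads "a is worse
    than b".
    """

    V6_12 = 0
    V6_18 = 1
    V6_60 = 2
    V3_60 = 3
    V1_60 = 4
    PL = 5    # light perception only
    NPL = 6   # no perception of light

    @property
    def rank(self) -> int:
        return int(self)

    def worse_than(self, other: "VAGrade") -> bool:
        return self.rank > other.rank

    def at_least(self, other: "VAGrade") -> bool:
        """True if this acuity is as good as or better than ``other``."""
        return self.rank <= other.rank

    @property
    def token(self) -> str:
        return _VA_TOKENS[self]

    @classmethod
    def from_token(cls, token: str) -> "VAGrade":
        try:
            return _VA_FROM_TOKEN[token.strip()]
        except KeyError:
            raise ValueError(f"unknown visual-acuity token: {token!r}") from None


_VA_TOKENS = {
    VAGrade.V6_12: "6/12",
    VAGrade.V6_18: "6/18",
    VAGrade.V6_60: "6/60",
    VAGrade.V3_60: "3/60",
    VAGrade.V1_60: "1/60",
    VAGrade.PL: "PL",
    VAGrade.NPL: "NPL",
}
_VA_FROM_TOKEN = {v: k for k, v in _VA_TOKENS.items()}


class LensStatus(str, enum.Enum):
    """One of the seven lens findings recorded for every examined eye."""

    NORMAL = "NORMAL"
    OBVIOUS_OPACITY = "OBVIOUS_OPACITY"
    APHAKIA = "APHAKIA"
    PSEUDOPHAKIA_NO_PCO = "PSEUDOPHAKIA_NO_PCO"
    PSEUDOPHAKIA_PCO = "PSEUDOPHAKIA_PCO"
    NO_VIEW = "NO_VIEW"
    NOT_EXAMINED = "NOT_EXAMINED"

    @property
    def operated(self) -> bool:
        """True for eyes with a history of cataract surgery."""
        return self in _OPERATED_STATUSES


_OPERATED_STATUSES = frozenset(
    {LensStatus.APHAKIA, LensStatus.PSEUDOPHAKIA_NO_PCO, LensStatus.PSEUDOPHAKIA_PCO}
)


class Cause(str, enum.Enum):
    """Eye conditions that may be assigned as a cause of vision impairment."""

    REFRACTIVE_ERROR = "REFRACTIVE_ERROR"
    CATARACT_UNTREATED = "CATARACT_UNTREATED"
    CATARACT_SURGICAL_COMPLICATIONS = "CATARACT_SURGICAL_COMPLICATIONS"
    TRACHOMA_CORNEAL_OPACITY = "TRACHOMA_CORNEAL_OPACITY"
    OTHER_CORNEAL_OPACITY = "OTHER_CORNEAL_OPACITY"
    PHTHISIS = "PHTHISIS"
    ONCHOCERCIASIS = "ONCHOCERCIASIS"
    GLAUCOMA = "GLAUCOMA"
    DIABETIC_RETINOPATHY = "DIABETIC_RETINOPATHY"
    ARMD = "ARMD"
    OTHER_POSTERIOR_SEGMENT = "OTHER_POSTERIOR_SEGMENT"
    OTHER_GLOBE_CNS = "OTHER_GLOBE_CNS"
    NOT_EXAMINED_UNDETERMINED = "NOT_EXAMINED_UNDETERMINED"
    # optional additions for settings where they are common
    PTERYGIUM = "PTERYGIUM"
    MYOPIC_MACULAR_DEGENERATION = "MYOPIC_MACULAR_DEGENERATION"
    ANTERIOR_UVEITIS = "ANTERIOR_UVEITIS"
    OTHER_NONCATARACT_SURGICAL_COMPLICATIONS = "OTHER_NONCATARACT_SURGICAL_COMPLICATIONS"


#: Default ordering of causes, most easily treatable or preventable first.
#: The principal cause of vision impairment in a person is the cause highest
#: up this list among the two eyes' main causes.
DEFAULT_CAUSE_ORDER: tuple[Cause, ...] = (
    Cause.REFRACTIVE_ERROR,
    Cause.CATARACT_UNTREATED,
    Cause.CATARACT_SURGICAL_COMPLICATIONS,
    Cause.TRACHOMA_CORNEAL_OPACITY,
    Cause.OTHER_CORNEAL_OPACITY,
    Cause.PHTHISIS,
    Cause.ONCHOCERCIASIS,
    Cause.GLAUCOMA,
    Cause.DIABETIC_RETINOPATHY,
    Cause.ARMD,
    Cause.OTHER_POSTERIOR_SEGMENT,
    Cause.OTHER_GLOBE_CNS,
    Cause.NOT_EXAMINED_UNDETERMINED,
)


class CauseRanking:
    """An ordered list of causes, most avoidable first.

    Surveys may remove conditions that are not endemic in their setting and
    add locally common ones; the ranking is data, not code. Refractive error
    and untreated cataract must always be present.
    """

    def __init__(self, order: Sequence[Cause] = DEFAULT_CAUSE_ORDER):
        order = tuple(order)
        if len(set(order)) != len(order):
            raise ValueError("cause ranking contains duplicates")
        if Cause.REFRACTIVE_ERROR not in order or Cause.CATARACT_UNTREATED not in order:
            raise ValueError(
                "cause ranking must contain refractive error and untreated cataract"
            )
        self._order = order
        self._rank = {c: i for i, c in enumerate(order)}

    @property
    def order(self) -> tuple[Cause, ...]:
        return self._order

    def rank(self, cause: Cause) -> int:
        try:
            return self._rank[cause]
        except KeyError:
            raise ValueError(f"cause {cause.value} is not in the active ranking") from None

    def __contains__(self, cause: Cause) -> bool:
        return cause in self._rank

    def remove(self, cause: Cause) -> "CauseRanking":
        """New ranking without ``cause`` (e.g. trachoma in non-endemic settings)."""
        if cause in (Cause.REFRACTIVE_ERROR, Cause.CATARACT_UNTREATED):
            raise ValueError(f"{cause.value} cannot be removed from the ranking")
        return CauseRanking(tuple(c for c in self._order if c is not cause))

    def insert(self, cause: Cause, position: int) -> "CauseRanking":
        """New ranking with ``cause`` inserted at ``position``."""
        if cause in self._rank:
            raise ValueError(f"{cause.value} already in ranking")
        order = list(self._order)
        order.insert(position, cause)
        return CauseRanking(tuple(order))

    def __repr__(self) -> str:  # pragma: no cover
        return f"CauseRanking({[c.value for c in self._order]})"


class ExamStatus(str, enum.Enum):
    EXAMINED = "examined"
    UNAVAILABLE = "unavailable"
    REFUSED = "refused"


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class SpectacleAge(str, enum.Enum):
    """Age of the participant's current distance spectacles."""

    LT2Y = "lt2y"
    Y2TO5 = "y2to5"
    GT5Y = "gt5y"


@dataclass
class EyeExam:
    """Acuity, lens and cause findings for one eye.

    ``presenting_va`` and ``pinhole_va`` are derived fields: presenting acuity
    is the corrected acuity for spectacle wearers and the uncorrected acuity
    otherwise, and the pinhole value is only measured when presenting acuity
    is worse than 6/12 (defaulting to the presenting value at PL/NPL).
    """

    uncorrected_va: Optional[VAGrade] = None
    corrected_va: Optional[VAGrade] = None
    presenting_va: Optional[VAGrade] = None
    pinhole_va: Optional[VAGrade] = None
    lens_status: Optional[LensStatus] = None
    main_cause: Optional[Cause] = None
    examiner_candidate_causes: frozenset[Cause] = frozenset()


@dataclass
class ParticipantRecord:
    participant_id: str
    cluster_id: str
    age: int
    gender: Gender
    resident_flag: bool = True
    exam_status: ExamStatus = ExamStatus.EXAMINED
    wears_distance_correction: bool = False
    spectacle_age: Optional[SpectacleAge] = None
    right_eye: Optional[EyeExam] = None
    left_eye: Optional[EyeExam] = None
    principal_cause: Optional[Cause] = None
    barriers: Optional[frozenset[str]] = None
    surgery_followup: Optional[str] = None

    @property
    def examined(self) -> bool:
        return self.exam_status is ExamStatus.EXAMINED

    def eyes(self) -> tuple[EyeExam, ...]:
        return tuple(e for e in (self.right_eye, self.left_eye) if e is not None)

    def better_eye_presenting(self) -> Optional[VAGrade]:
        """Presenting acuity in the better eye, or None if not examined."""
        grades = [e.presenting_va for e in self.eyes() if e.presenting_va is not None]
        return min(grades) if grades else None

    def better_eye_uncorrected(self) -> Optional[VAGrade]:
        grades = [e.uncorrected_va for e in self.eyes() if e.uncorrected_va is not None]
        return min(grades) if grades else None

    def better_eye_pinhole(self) -> Optional[VAGrade]:
        """Pinhole acuity in the better eye; falls back to presenting where
        the pinhole test was not indicated (presenting 6/12)."""
        grades = []
        for e in self.eyes():
            if e.pinhole_va is not None:
                grades.append(e.pinhole_va)
            elif e.presenting_va is not None:
                grades.append(e.presenting_va)
        return min(grades) if grades else None


@dataclass
class SurveyMetadata:
    """The survey-level record shared with the central data repository."""

    year: int
    location_name: str
    pi_name: str = ""
    trainer_name: str = ""
    sample_size: int = 0
    response_rate: Optional[float] = None
    dr_module: bool = False
    disability_module: bool = False
    completion_date: Optional[date] = None
    embargo_end: Optional[date] = None
    clusters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.response_rate is not None and not (0.0 <= self.response_rate <= 1.0):
            raise ValueError("response_rate must lie in [0, 1]")
        if self.sample_size < 0:
            raise ValueError("sample_size must be non-negative")


@dataclass
class ValidationFlag:
    """A protocol-violation flag attached to a participant record."""

    participant_id: str
    rule_code: str
    message: str

    def __hash__(self) -> int:
        return hash((self.participant_id, self.rule_code))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ValidationFlag):
            return NotImplemented
        return (self.participant_id, self.rule_code) == (
            other.participant_id,
            other.rule_code,
        )


@dataclass
class Dataset:
    """A parsed participant-level survey dataset."""

    records: list[ParticipantRecord] = field(default_factory=list)
    metadata: Optional[SurveyMetadata] = None
    violations: list[ValidationFlag] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def examined(self) -> Iterable[ParticipantRecord]:
        return (r for r in self.records if r.examined)

    def cluster_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.cluster_id, None)
        return list(seen)
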