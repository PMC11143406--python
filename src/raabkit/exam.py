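"""Standardized examination decision algorithms.

These are the deterministic rules that turn raw per-eye measurements into the
derived fields every downstream indicator depends on: presenting acuity,
pinhole gating, vision-impairment categories, main and principal causes,
follow-up question routing, and the inter-observer agreement statistic used
to certify examination teams during training.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .types import (
    Cause,
    CauseRanking,
    Dataset,
    EyeExam,
    LensStatus,
    ParticipantRecord,
    VAGrade,
)

#: Pass threshold for the training-week inter-observer variation exercise.
KAPPA_PASS_THRESHOLD = 0.6


class ImpairmentCategory(enum.IntEnum):
    """Vision-impairment category from presenting acuity in the better eye."""

    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    BLIND = 4


class PinholeAction(enum.Enum):
    TEST = "test"
    DEFAULT_TO_PRESENTING = "default_to_presenting"
    NOT_TESTED = "not_tested"


class ProtocolError(ValueError):
    """A measurement combination the examination protocol cannot produce."""


def compose_presenting_va(
    uncorrected: VAGrade,
    corrected: Optional[VAGrade],
    wears_correction: bool,
) -> VAGrade:
    """Presenting acuity: corrected if the participant habitually wears
    distance correction, uncorrected otherwise."""
    if wears_correction:
        if corrected is None:
            raise ProtocolError(
                "participant wears distance correction but corrected acuity is missing"
            )
        return corrected
    return uncorrected


def pinhole_requirement(presenting: VAGrade) -> PinholeAction:
    """Whether the pinhole test is presented for an eye.

    Pinhole acuity is tested in any eye with presenting acuity worse than
    6/12 but better than light perception; at PL/NPL the pinhole value
    defaults to the presenting value and the test is skipped.
    """
    if presenting is VAGrade.V6_12:
        return PinholeAction.NOT_TESTED
    if presenting in (VAGrade.PL, VAGrade.NPL):
        return PinholeAction.DEFAULT_TO_PRESENTING
    return PinholeAction.TEST


_CATEGORY_BY_GRADE = {
    VAGrade.V6_12: ImpairmentCategory.NORMAL,
    VAGrade.V6_18: ImpairmentCategory.MILD,
    VAGrade.V6_60: ImpairmentCategory.MODERATE,
    VAGrade.V3_60: ImpairmentCategory.SEVERE,
    VAGrade.V1_60: ImpairmentCategory.BLIND,
    VAGrade.PL: ImpairmentCategory.BLIND,
    VAGrade.NPL: ImpairmentCategory.BLIND,
}


def classify_impairment(better_eye_presenting: VAGrade) -> ImpairmentCategory:
    """Map better-eye presenting acuity to the impairment category.

    Normal ≥6/12; mild <6/12 to ≥6/18; moderate <6/18 to ≥6/60; severe <6/60
    to ≥3/60; blind <3/60 (1/60, light perception and no light perception all
    count as blindness).
    """
    return _CATEGORY_BY_GRADE[better_eye_presenting]


def assign_main_cause_eye(exam: EyeExam, ranking: CauseRanking) -> Optional[Cause]:
    """Main cause of vision impairment for one eye.

    An eye presenting 6/12 is normal and gets no cause, even if disease is
    present. An eye that improves to 6/12 with pinhole is assigned refractive
    error regardless of any other disease the examiner observed. Otherwise
    the examiner-selected candidate stands (checked against the active
    ranking).
    """
    presenting = exam.presenting_va
    if presenting is None:
        raise ProtocolError("presenting acuity must be derived before cause assignment")
    if presenting is VAGrade.V6_12:
        return None
    pinhole = exam.pinhole_va
    if pinhole is None:
        raise ProtocolError(
            "pinhole acuity required for an eye presenting worse than 6/12"
        )
    if pinhole is VAGrade.V6_12:
        return Cause.REFRACTIVE_ERROR
    candidates = exam.examiner_candidate_causes
    if not candidates:
        return Cause.NOT_EXAMINED_UNDETERMINED
    for c in candidates:
        if c not in ranking:
            raise ValueError(f"examiner cause {c.value} is not in the active ranking")
    if len(candidates) == 1:
        return next(iter(candidates))
    # The examiner records a single main cause in the field; when the
    # simulator emits several latent candidates, the condition judged more
    # responsible for vision loss is approximated by the worse-ranked one
    # (cause hierarchy is only applied across eyes, not within one eye).
    return max(candidates, key=ranking.rank)


def assign_principal_cause(
    right: Optional[Cause],
    left: Optional[Cause],
    person_category: ImpairmentCategory,
    ranking: CauseRanking,
) -> Optional[Cause]:
    """Principal cause of vision impairment in the person.

    When the two eyes carry different main causes, the cause higher up the
    ranking — more readily treatable or preventable — wins, so avoidable
    causes are prioritised. A person with normal vision has no principal
    cause.
    """
    if person_category is ImpairmentCategory.NORMAL:
        return None
    causes = [c for c in (right, left) if c is not None]
    if not causes:
        return None
    return min(causes, key=ranking.rank)


@dataclass(frozen=True)
class FollowupRoute:
    """Which follow-up question blocks a participant is routed to."""

    surgical_outcome_questions: bool = False
    barrier_questions: bool = False

    @property
    def none(self) -> bool:
        return not (self.surgical_outcome_questions or self.barrier_questions)


def followup_route(record: ParticipantRecord) -> FollowupRoute:
    """Cataract follow-up routing.

    Surgical-outcome questions are asked of anyone with a history of cataract
    surgery (an aphakic or pseudophakic eye). Barrier questions are asked of
    anyone with an eye with obvious lens opacity and pinhole acuity worse
    than 6/12 — why have they not had cataract surgery?
    """
    surgical = any(
        e.lens_status is not None and e.lens_status.operated for e in record.eyes()
    )
    barrier = False
    for e in record.eyes():
        if e.lens_status is not LensStatus.OBVIOUS_OPACITY:
            continue
        pin = e.pinhole_va if e.pinhole_va is not None else e.presenting_va
        if pin is not None and pin.worse_than(VAGrade.V6_12):
            barrier = True
            break
    return FollowupRoute(surgical_outcome_questions=surgical, barrier_questions=barrier)


def cohen_kappa(
    ratings_a: Sequence, ratings_b: Sequence
) -> tuple[float, bool]:
    """Cohen's kappa for two raters over categorical ratings.

    kappa = (p_o − p_e) / (1 − p_e), with chance agreement p_e from the
    product of the raters' marginal distributions. Returns the statistic and
    whether it reaches the 0.6 acceptable-agreement threshold used in the
    training-week inter-observer exercise.
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors must have equal length")
    n = len(ratings_a)
    if n < 2:
        raise ValueError("need at least two paired ratings")
    categories = set(ratings_a) | set(ratings_b)
    if len(categories) < 2:
        if tuple(ratings_a) == tuple(ratings_b):
            warnings.warn(
                "both raters constant and identical; kappa defined as 1",
                stacklevel=2,
            )
            return 1.0, True
        raise ValueError("need at least two categories across both raters")
    p_o = sum(a == b for a, b in zip(ratings_a, ratings_b)) / n
    marg_a = Counter(ratings_a)
    marg_b = Counter(ratings_b)
    p_e = sum(marg_a[c] * marg_b[c] for c in categories) / (n * n)
    if p_e == 1.0:
        warnings.warn("degenerate marginals; kappa defined as 1", stacklevel=2)
        return 1.0, True
    kappa = (p_o - p_e) / (1.0 - p_e)
    return kappa, kappa >= KAPPA_PASS_THRESHOLD


def derive_eye(exam: EyeExam, wears_correction: bool, ranking: CauseRanking) -> EyeExam:
    """Fill the derived fields of one eye exam: presenting acuity, the
    pinhole default, and the main cause."""
    if exam.uncorrected_va is None:
        raise ProtocolError("uncorrected acuity missing on an examined eye")
    presenting = compose_presenting_va(
        exam.uncorrected_va, exam.corrected_va, wears_correction
    )
    action = pinhole_requirement(presenting)
    pinhole = exam.pinhole_va
    if action is PinholeAction.NOT_TESTED:
        pinhole = None
    elif action is PinholeAction.DEFAULT_TO_PRESENTING:
        pinhole = presenting
    elif pinhole is None:
        raise ProtocolError(
            "pinhole acuity not recorded for an eye presenting worse than 6/12"
        )
    out = replace(exam, presenting_va=presenting, pinhole_va=pinhole)
    out.main_cause = assign_main_cause_eye(out, ranking)
    return out


def derive_record(
    record: ParticipantRecord, ranking: Optional[CauseRanking] = None
) -> ParticipantRecord:
    """Fill all derived fields of an examined participant record.

    Returns a new record with per-eye presenting/pinhole/main-cause fields
    and the person-level principal cause populated. Unexamined records are
    returned unchanged.
    """
    if not record.examined:
        return record
    ranking = ranking or CauseRanking()
    right = derive_eye(record.right_eye, record.wears_distance_correction, ranking)
    left = derive_eye(record.left_eye, record.wears_distance_correction, ranking)
    better = min(right.presenting_va, left.presenting_va)
    category = classify_impairment(better)
    principal = assign_principal_cause(
        right.main_cause, left.main_cause, category, ranking
    )
    return replace(
        record, right_eye=right, left_eye=left, principal_cause=principal
    )


def derive_dataset(ds: Dataset, ranking: Optional[CauseRanking] = None) -> Dataset:
    """Apply :func:`derive_record` to every record of a dataset."""
    return Dataset(
        records=[derive_record(r, ranking) for r in ds.records],
        metadata=ds.metadata,
        violations=list(ds.violations),
    )
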