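"""Protocol-violation validation of participant datasets.

Validation never throws on content: every rule produces flags, the caller
decides what to do with them. The rule codes form a documented closed set.
"""

from __future__ import annotations

from collections import Counter

from .types import Dataset, ExamStatus, LensStatus, ParticipantRecord, VAGrade, ValidationFlag

#: Closed set of protocol-violation rule codes.
RULE_CODES = (
    "DUPLICATE_ID",
    "UNDERAGE",
    "PINHOLE_NOT_INDICATED",
    "CORRECTED_WITHOUT_SPECTACLES",
    "TOO_MANY_BARRIERS",
    "BARRIERS_NOT_ROUTED",
    "EXAM_FIELDS_ON_UNEXAMINED",
    "PARSE_ERROR",
)

MAX_BARRIERS = 2  # examiners choose up to two of the six barrier options


def _effective_presenting(eye, wears: bool):
    """Presenting acuity, composed from raw fields when not yet derived."""
    if eye.presenting_va is not None:
        return eye.presenting_va
    if wears and eye.corrected_va is not None:
        return eye.corrected_va
    return eye.uncorrected_va


def _barrier_routed(record: ParticipantRecord) -> bool:
    for e in record.eyes():
        if e.lens_status is not LensStatus.OBVIOUS_OPACITY:
            continue
        pin = e.pinhole_va if e.pinhole_va is not None else e.presenting_va
        if pin is not None and pin.worse_than(VAGrade.V6_12):
            return True
    return False


def validate_dataset(ds: Dataset) -> list[ValidationFlag]:
    """Apply every protocol rule to every record; returns a deterministic,
    order-independent flag list (one flag per record per rule)."""
    flags: list[ValidationFlag] = []

    id_counts = Counter(r.participant_id for r in ds.records)
    for pid, n in sorted(id_counts.items()):
        if n > 1:
            flags.append(
                ValidationFlag(pid, "DUPLICATE_ID", f"participant id appears {n} times")
            )

    for r in ds.records:
        if r.age < 50:
            flags.append(
                ValidationFlag(r.participant_id, "UNDERAGE", f"age {r.age} below 50")
            )
        if r.exam_status is not ExamStatus.EXAMINED:
            if r.eyes():
                flags.append(
                    ValidationFlag(
                        r.participant_id,
                        "EXAM_FIELDS_ON_UNEXAMINED",
                        f"eye examination recorded for {r.exam_status.value} participant",
                    )
                )
            continue
        for side, eye in (("right", r.right_eye), ("left", r.left_eye)):
            if eye is None:
                continue
            presenting = _effective_presenting(eye, r.wears_distance_correction)
            if presenting is VAGrade.V6_12 and eye.pinhole_va is not None:
                flags.append(
                    ValidationFlag(
                        r.participant_id,
                        "PINHOLE_NOT_INDICATED",
                        f"{side} eye: pinhole recorded at presenting 6/12",
                    )
                )
            if eye.corrected_va is not None and not r.wears_distance_correction:
                flags.append(
                    ValidationFlag(
                        r.participant_id,
                        "CORRECTED_WITHOUT_SPECTACLES",
                        f"{side} eye: corrected acuity without spectacle wear",
                    )
                )
        if r.barriers is not None:
            if len(r.barriers) > MAX_BARRIERS:
                flags.append(
                    ValidationFlag(
                        r.participant_id,
                        "TOO_MANY_BARRIERS",
                        f"{len(r.barriers)} barrier options selected (max {MAX_BARRIERS})",
                    )
                )
            if not _barrier_routed(r):
                flags.append(
                    ValidationFlag(
                        r.participant_id,
                        "BARRIERS_NOT_ROUTED",
                        "barrier answers present without obvious lens opacity "
                        "and pinhole acuity worse than 6/12",
                    )
                )

    # duplicates across records may insert the same (pid, rule) twice; keep
    # the flag list a set, deterministically ordered
    unique = sorted(set(flags), key=lambda f: (f.participant_id, f.rule_code))
    return unique
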