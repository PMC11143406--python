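import numpy as np
import pytest
from hypothesis import settings

from raabkit import (
    Cause,
    CauseRanking,
    Dataset,
    ExamStatus,
    EyeExam,
    Gender,
    LensStatus,
    ParticipantRecord,
    VAGrade,
    derive_record,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ranking():
    return CauseRanking()


def make_record(
    pid="P1",
    cluster="C1",
    age=65,
    gender=Gender.FEMALE,
    ucva=VAGrade.V6_12,
    corrected=None,
    wears=False,
    pinhole=None,
    lens=LensStatus.NORMAL,
    causes=frozenset(),
    exam_status=ExamStatus.EXAMINED,
    derive=True,
    **kwargs,
):
    """Build a symmetric-eyed participant record, optionally derived."""
    if exam_status is not ExamStatus.EXAMINED:
        return ParticipantRecord(
            participant_id=pid, cluster_id=cluster, age=age, gender=gender,
            exam_status=exam_status,
        )

    def eye():
        return EyeExam(
            uncorrected_va=ucva,
            corrected_va=corrected,
            pinhole_va=pinhole,
            lens_status=lens,
            examiner_candidate_causes=causes,
        )

    rec = ParticipantRecord(
        participant_id=pid,
        cluster_id=cluster,
        age=age,
        gender=gender,
        wears_distance_correction=wears,
        right_eye=eye(),
        left_eye=eye(),
        **kwargs,
    )
    return derive_record(rec) if derive else rec


@pytest.fixture
def make_participant():
    return make_record


@pytest.fixture
def tiny_clean_dataset():
    """A protocol-conformant 6-record dataset spanning 3 clusters."""
    records = [
        make_record(pid=f"P{i}", cluster=f"C{i % 3}", age=50 + 5 * i)
        for i in range(6)
    ]
    return Dataset(records=records)
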