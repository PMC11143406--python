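"""Reading and writing the participant-level CSV dialect and auxiliary tables.

The on-disk participant format is one row per participant with per-eye
columns suffixed ``_re`` / ``_le``, acuity grades serialised as the Snellen
tokens ``6/12 6/18 6/60 3/60 1/60 PL NPL``, UTF-8, comma-separated. Missing
optional fields are empty strings, never sentinel numbers. The exact column
names are configurable through a dialect mapping because deployed survey
platforms use their own variable schemas.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .types import (
    Cause,
    Dataset,
    ExamStatus,
    EyeExam,
    Gender,
    LensStatus,
    ParticipantRecord,
    SpectacleAge,
    SurveyMetadata,
    VAGrade,
    ValidationFlag,
)
from .design import SamplingFrame

_EYE_FIELDS = (
    "uncorrected_va",
    "corrected_va",
    "presenting_va",
    "pinhole_va",
    "lens_status",
    "main_cause",
)

_PERSON_FIELDS = (
    "participant_id",
    "cluster_id",
    "age",
    "gender",
    "resident",
    "exam_status",
    "wears_distance_correction",
    "spectacle_age",
)

_TAIL_FIELDS = ("principal_cause", "barriers", "surgery_followup")

#: Canonical column order of the dialect.
CANONICAL_COLUMNS: tuple[str, ...] = (
    _PERSON_FIELDS
    + tuple(f"{f}_re" for f in _EYE_FIELDS)
    + tuple(f"{f}_le" for f in _EYE_FIELDS)
    + _TAIL_FIELDS
)


@dataclass
class CsvDialect:
    """Column-name mapping for the participant CSV format.

    ``columns`` maps canonical field names to on-disk header names; the
    default is the identity mapping.
    """

    columns: dict[str, str] = field(default_factory=dict)
    delimiter: str = ","

    def header(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


class DatasetFormatError(ValueError):
    """The file does not match the documented participant dialect."""


class RowParseError(ValueError):
    """A data row could not be parsed; carries the 1-based row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


def _parse_optional(token: str, parser):
    token = token.strip()
    return None if token == "" else parser(token)


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise ValueError(f"not a boolean: {token!r}")


def _parse_eye(row: dict[str, str], suffix: str, dialect: CsvDialect) -> Optional[EyeExam]:
    vals = {f: row.get(dialect.header(f"{f}_{suffix}"), "").strip() for f in _EYE_FIELDS}
    if all(v == "" for v in vals.values()):
        return None
    return EyeExam(
        uncorrected_va=_parse_optional(vals["uncorrected_va"], VAGrade.from_token),
        corrected_va=_parse_optional(vals["corrected_va"], VAGrade.from_token),
        presenting_va=_parse_optional(vals["presenting_va"], VAGrade.from_token),
        pinhole_va=_parse_optional(vals["pinhole_va"], VAGrade.from_token),
        lens_status=_parse_optional(vals["lens_status"], LensStatus),
        main_cause=_parse_optional(vals["main_cause"], Cause),
    )


def _parse_row(row: dict[str, str], dialect: CsvDialect) -> ParticipantRecord:
    def get(name: str) -> str:
        return row.get(dialect.header(name), "").strip()

    age_token = get("age")
    try:
        age = int(age_token)
    except ValueError:
        raise ValueError(f"age is not an integer: {age_token!r}") from None
    barriers_token = get("barriers")
    barriers = (
        frozenset(b for b in barriers_token.split(";") if b) if barriers_token else None
    )
    return ParticipantRecord(
        participant_id=get("participant_id"),
        cluster_id=get("cluster_id"),
        age=age,
        gender=Gender(get("gender")),
        resident_flag=_parse_bool(get("resident") or "true"),
        exam_status=ExamStatus(get("exam_status") or "examined"),
        wears_distance_correction=_parse_bool(get("wears_distance_correction") or "false"),
        spectacle_age=_parse_optional(get("spectacle_age"), SpectacleAge),
        right_eye=_parse_eye(row, "re", dialect),
        left_eye=_parse_eye(row, "le", dialect),
        principal_cause=_parse_optional(get("principal_cause"), Cause),
        barriers=barriers,
        surgery_followup=get("surgery_followup") or None,
    )


def read_dataset(
    path: Union[str, Path, _io.TextIOBase],
    dialect: Optional[CsvDialect] = None,
    strict: bool = True,
) -> Dataset:
    """Read a participant-level dataset in the documented CSV dialect.

    With ``strict=True`` (default) any unparseable row raises
    :class:`RowParseError` naming the row. With ``strict=False`` bad rows
    are reported as ``PARSE_ERROR`` validation flags on the returned
    dataset — never silently dropped.
    """
    dialect = dialect or CsvDialect()
    if isinstance(path, (str, Path)):
        fh = open(path, "r", encoding="utf-8", newline="")
        close = True
    else:
        fh, close = path, False
    try:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        headers = reader.fieldnames or []
        mandatory = [dialect.header(c) for c in _PERSON_FIELDS]
        missing = [h for h in mandatory if h not in headers]
        if missing:
            raise DatasetFormatError(f"missing mandatory columns: {missing}")
        records: list[ParticipantRecord] = []
        flags: list[ValidationFlag] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row, dialect))
            except ValueError as exc:
                if strict:
                    raise RowParseError(i, str(exc)) from exc
                flags.append(
                    ValidationFlag(
                        participant_id=row.get(dialect.header("participant_id"), ""),
                        rule_code="PARSE_ERROR",
                        message=f"row {i}: {exc}",
                    )
                )
    finally:
        if close:
            fh.close()
    return Dataset(records=records, violations=flags)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, VAGrade):
        return value.token
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (Cause, LensStatus, Gender, ExamStatus, SpectacleAge)):
        return value.value
    return str(value)


def _eye_cells(eye: Optional[EyeExam]) -> list[str]:
    if eye is None:
        return [""] * len(_EYE_FIELDS)
    return [_fmt(getattr(eye, f)) for f in _EYE_FIELDS]


def write_dataset(
    ds: Dataset,
    path: Union[str, Path, _io.TextIOBase],
    dialect: Optional[CsvDialect] = None,
) -> None:
    """Write a dataset in the documented CSV dialect (round-trips with
    :func:`read_dataset` on canonical files)."""
    dialect = dialect or CsvDialect()
    if isinstance(path, (str, Path)):
        fh = open(path, "w", encoding="utf-8", newline="")
        close = True
    else:
        fh, close = path, False
    try:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow([dialect.header(c) for c in CANONICAL_COLUMNS])
        for r in ds.records:
            barriers = ";".join(sorted(r.barriers)) if r.barriers else ""
            row = [
                r.participant_id,
                r.cluster_id,
                str(r.age),
                _fmt(r.gender),
                _fmt(r.resident_flag),
                _fmt(r.exam_status),
                _fmt(r.wears_distance_correction),
                _fmt(r.spectacle_age),
                *_eye_cells(r.right_eye),
                *_eye_cells(r.left_eye),
                _fmt(r.principal_cause),
                barriers,
                _fmt(r.surgery_followup),
            ]
            writer.writerow(row)
    finally:
        if close:
            fh.close()


def read_frame(path: Union[str, Path], dialect: Optional[dict] = None) -> SamplingFrame:
    """Read a sampling frame: a delimited table with columns
    ``psu_id, population``."""
    cols = {"psu_id": "psu_id", "population": "population"}
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"frame is missing columns: {missing}")
    return SamplingFrame(
        psus=[
            (str(row[cols["psu_id"]]), int(row[cols["population"]]))
            for _, row in df.iterrows()
        ]
    )


def read_census(path: Union[str, Path]) -> "CensusStructure":
    """Read census age-gender counts: columns ``age_group, gender, count``
    with age groups 50-59, 60-69, 70-79, 80+."""
    from .estimation import AGE_GROUPS, CensusStructure

    df = pd.read_csv(path)
    for c in ("age_group", "gender", "count"):
        if c not in df.columns:
            raise DatasetFormatError(f"census table is missing column {c!r}")
    counts: dict[tuple[str, Gender], float] = {}
    for _, row in df.iterrows():
        ag = str(row["age_group"]).strip()
        if ag not in AGE_GROUPS:
            raise DatasetFormatError(
                f"unknown age group {ag!r}; expected one of {AGE_GROUPS}"
            )
        counts[(ag, Gender(str(row["gender"]).strip()))] = float(row["count"])
    return CensusStructure(counts=counts)
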