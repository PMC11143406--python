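"""Automated survey report and the survey metadata record.

The report consolidates the priority outputs — response rate, crude and
age-gender-weighted prevalence by category and gender, causes, cataract and
refractive-error coverage, surgical outcomes, barriers and validation flags
— into a machine-readable structure plus a deterministic markdown rendering.
Indicators that cannot be computed on a given dataset are rendered as
explicit "not computable" cells, never omitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from typing import Any, Optional

from .estimation import (
    CensusStructure,
    EstimationError,
    IndicatorResult,
    cataract_coverage,
    estimate_prevalence,
    refractive_coverage,
    response_rate,
    surgical_outcomes,
    tabulate_barriers,
)
from .exam import ImpairmentCategory
from .types import Dataset, SurveyMetadata
from .validate import validate_dataset

NOT_COMPUTABLE = "not computable"

EMBARGO_MONTHS = 18


def _pct(x: Optional[float]) -> str:
    return NOT_COMPUTABLE if x is None else f"{100.0 * x:.1f}%"


def _indicator_dict(res: IndicatorResult) -> dict[str, Any]:
    return {
        "crude": res.crude,
        "weighted": res.weighted,
        "se": res.se,
        "ci95": list(res.ci95),
        "ci95_weighted": list(res.ci95_weighted),
        "n": res.n,
        "n_cases": res.n_cases,
        "by_gender": {g: _indicator_dict(r) for g, r in res.by_gender.items()},
        "notes": res.notes,
    }


@dataclass
class ReportDocument:
    """Machine-readable report content plus its markdown rendering."""

    sections: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.sections, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        s = self.sections
        lines = ["# Survey report", ""]
        meta = s.get("metadata", {})
        if meta:
            lines += [
                f"**Location:** {meta.get('location_name', '')}   "
                f"**Year:** {meta.get('year', '')}",
                "",
            ]
        lines += [
            "## Design and response",
            "",
            f"- Participants enrolled: {s['design']['enrolled']}",
            f"- Participants examined: {s['design']['examined']}",
            f"- Clusters: {s['design']['n_clusters']}",
            f"- Response rate: {_pct(s['design']['response_rate'])}",
            "",
            "## Vision impairment prevalence",
            "",
            "Prevalence of each category from presenting acuity in the better",
            "eye; weighted values are post-stratified to census age-gender counts.",
            "",
            "| Category | Crude | Weighted | 95% CI (weighted) | Cases / N |",
            "|---|---|---|---|---|",
        ]
        for cat, d in s["prevalence"].items():
            if d == NOT_COMPUTABLE:
                lines.append(f"| {cat} | {NOT_COMPUTABLE} | | | |")
                continue
            lo, hi = d["ci95_weighted"]
            lines.append(
                f"| {cat} | {_pct(d['crude'])} | {_pct(d['weighted'])} | "
                f"{_pct(lo)}–{_pct(hi)} | {d['n_cases']} / {d['n']} |"
            )
        lines += ["", "### By gender", ""]
        for cat, d in s["prevalence"].items():
            if d == NOT_COMPUTABLE or not d["by_gender"]:
                continue
            for g, gd in d["by_gender"].items():
                lines.append(
                    f"- {cat}, {g}: crude {_pct(gd['crude'])}, "
                    f"weighted {_pct(gd['weighted'])}"
                )
        lines += [
            "",
            "## Cataract surgical coverage",
            "",
            "CSC: operated persons over operated plus bilaterally operable;",
            "eCSC restricts the numerator to good presenting-vision outcomes.",
            "",
            f"- CSC (persons): {_pct(s['cataract']['csc_person'])}",
            f"- eCSC (persons): {_pct(s['cataract']['ecsc_person'])}",
            f"- CSC (eyes): {_pct(s['cataract']['csc_eye'])}",
            f"- eCSC (eyes): {_pct(s['cataract']['ecsc_eye'])}",
            "",
            "## Refractive error coverage",
            "",
            "Need marked by pinhole improvement to 6/12; effective coverage",
            "requires presenting acuity of 6/12 with the worn correction.",
            "",
            f"- REC: {_pct(s['refraction']['rec'])}",
            f"- eREC: {_pct(s['refraction']['erec'])}",
            "",
            "## Cataract surgical outcomes (operated eyes)",
            "",
        ]
        if s["surgical_outcomes"] == NOT_COMPUTABLE:
            lines.append(NOT_COMPUTABLE)
        else:
            for k, v in s["surgical_outcomes"].items():
                lines.append(f"- {k}: {_pct(v)}")
        lines += ["", "## Barriers to cataract surgery", ""]
        if s["barriers"] == NOT_COMPUTABLE:
            lines.append(NOT_COMPUTABLE)
        else:
            for k, v in s["barriers"].items():
                lines.append(f"- {k}: {v:.1f}%")
        lines += ["", "## Validation flags", ""]
        if s["validation_flags"]:
            for f_ in s["validation_flags"]:
                lines.append(
                    f"- {f_['participant_id']}: {f_['rule_code']} — {f_['message']}"
                )
        else:
            lines.append("No protocol violations flagged.")
        lines.append("")
        return "\n".join(lines)


def generate_report(
    ds: Dataset, census: CensusStructure, cfg: Optional[dict] = None
) -> ReportDocument:
    """Run the full analysis on a dataset and assemble the report.

    Read-only on the dataset; deterministic given identical inputs.
    """
    sections: dict[str, Any] = {}
    meta = ds.metadata
    sections["metadata"] = export_metadata(ds) if meta is not None else {}

    enrolled = len(ds.records)
    examined = sum(1 for r in ds.records if r.examined)
    sections["design"] = {
        "enrolled": enrolled,
        "examined": examined,
        "n_clusters": len(ds.cluster_ids()),
        "response_rate": response_rate(ds) if enrolled else None,
    }

    prevalence: dict[str, Any] = {}
    for cat in ImpairmentCategory:
        if cat is ImpairmentCategory.NORMAL:
            continue
        try:
            prevalence[cat.name.lower()] = _indicator_dict(
                estimate_prevalence(ds, cat, census)
            )
        except EstimationError:
            prevalence[cat.name.lower()] = NOT_COMPUTABLE
    sections["prevalence"] = prevalence

    cat_res = cataract_coverage(ds)
    sections["cataract"] = {
        "csc_person": cat_res.csc_person,
        "ecsc_person": cat_res.ecsc_person,
        "csc_eye": cat_res.csc_eye,
        "ecsc_eye": cat_res.ecsc_eye,
        "components_person": {
            "met": cat_res.person_components.met,
            "undermet": cat_res.person_components.undermet,
            "unmet": cat_res.person_components.unmet,
        },
    }

    ref = refractive_coverage(ds)
    sections["refraction"] = {
        "rec": ref.rec,
        "erec": ref.erec,
        "components": {
            "met": ref.components.met,
            "undermet": ref.components.undermet,
            "unmet": ref.components.unmet,
        },
    }

    so = surgical_outcomes(ds)
    sections["surgical_outcomes"] = so if so else NOT_COMPUTABLE

    barriers, excluded = tabulate_barriers(ds)
    sections["barriers"] = barriers if barriers else NOT_COMPUTABLE
    sections["barriers_excluded"] = excluded

    flags = validate_dataset(ds)
    sections["validation_flags"] = [
        {"participant_id": f.participant_id, "rule_code": f.rule_code, "message": f.message}
        for f in flags
    ]
    return ReportDocument(sections=sections)


def _add_months(d: date, months: int) -> date:
    month = d.month - 1 + months
    year = d.year + month // 12
    month = month % 12 + 1
    day = min(d.day, [31, 29 if year % 4 == 0 and (year % 100 != 0 or year % 400 == 0) else 28,
                      31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1])
    return date(year, month, day)


def export_metadata(ds: Dataset) -> dict[str, Any]:
    """Survey metadata record for the central repository.

    Auto-fills the response rate from the dataset when absent and the
    embargo end as completion date plus 18 months when unset.
    """
    meta = ds.metadata
    if meta is None:
        raise ValueError("dataset has no survey metadata")
    missing = [f for f in ("year", "location_name") if not getattr(meta, f)]
    if missing:
        raise ValueError(f"mandatory metadata fields missing: {missing}")
    rate = meta.response_rate
    if rate is None and ds.records:
        rate = response_rate(ds)
    completion = meta.completion_date or date(meta.year, 12, 31)
    embargo = meta.embargo_end or _add_months(completion, EMBARGO_MONTHS)
    return {
        "year": meta.year,
        "location_name": meta.location_name,
        "pi_name": meta.pi_name,
        "trainer_name": meta.trainer_name,
        "sample_size": meta.sample_size or len(ds.records),
        "response_rate": rate,
        "dr_module": meta.dr_module,
        "disability_module": meta.disability_module,
        "completion_date": completion.isoformat(),
        "embargo_end": embargo.isoformat(),
    }
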