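"""Indicator estimation for two-stage cluster eye-health surveys.

Covers the survey's priority outputs: vision-impairment prevalence with
design-based standard errors (the cluster-ratio variance estimator), census
post-stratification over the eight 10-year-age-by-gender strata, cataract
surgical coverage (CSC) and its "effective" variant restricted to good
presenting-vision outcomes (eCSC), refractive error coverage (REC/eREC) from
the pinhole-improvement definition of refractive need, cataract surgical
outcomes, barrier tabulation and response rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exam import ImpairmentCategory, classify_impairment, followup_route
from .types import Cause, Dataset, Gender, LensStatus, ParticipantRecord, VAGrade
from .validate import MAX_BARRIERS

Z_95 = 1.96

AGE_GROUPS: tuple[str, ...] = ("50-59", "60-69", "70-79", "80+")


def age_group_of(age: int) -> str:
    if age < 50:
        raise ValueError("post-stratification strata start at age 50")
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    if age < 80:
        return "70-79"
    return "80+"


Stratum = tuple[str, Gender]

ALL_STRATA: tuple[Stratum, ...] = tuple(
    (ag, g) for g in (Gender.MALE, Gender.FEMALE) for ag in AGE_GROUPS
)


@dataclass
class CensusStructure:
    """Known population counts for the 8 age-gender strata (50-59, 60-69,
    70-79, 80+ by male/female)."""

    counts: dict[Stratum, float]

    def __post_init__(self) -> None:
        for s in self.counts:
            if s[0] not in AGE_GROUPS:
                raise ValueError(f"unknown age group {s[0]!r}")
            if self.counts[s] < 0:
                raise ValueError("census counts must be non-negative")
        if sum(self.counts.values()) <= 0:
            raise ValueError("census total must be positive")

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def restricted(self, gender: Gender) -> "CensusStructure":
        return CensusStructure(
            {s: c for s, c in self.counts.items() if s[1] is gender}
        )


@dataclass(frozen=True)
class ClusterTally:
    """Per-cluster case and examined counts for variance estimation."""

    cluster_id: str
    n_examined: int
    n_cases: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_cases <= self.n_examined:
            raise ValueError("need 0 <= cases <= examined within a cluster")


class EstimationError(ValueError):
    pass


def bennett_se(tallies: Sequence[ClusterTally]) -> tuple[float, float]:
    """Crude proportion and its cluster-ratio standard error.

    For c clusters with cases a_i and examined n_i, p = Σa_i/Σn_i and

        se = sqrt( Σ(a_i − p·n_i)² / (c(c−1)) ) / n̄,   n̄ = Σn_i / c.

    This is the standard ratio-estimator variance for cluster samples of
    unequal size; it requires at least two clusters.
    """
    c = len(tallies)
    if c < 2:
        raise EstimationError("cluster-ratio variance requires at least 2 clusters")
    a = np.array([t.n_cases for t in tallies], dtype=float)
    n = np.array([t.n_examined for t in tallies], dtype=float)
    if n.sum() <= 0:
        raise EstimationError("no examined participants")
    p = a.sum() / n.sum()
    nbar = n.sum() / c
    se = math.sqrt(float(np.sum((a - p * n) ** 2)) / (c * (c - 1))) / nbar
    return float(p), float(se)


def _collapse_strata(
    sample_counts: dict[Stratum, int], census: CensusStructure
) -> tuple[dict[Stratum, Stratum], list[str]]:
    """Map each census stratum to the stratum whose sample it is pooled with.

    A stratum with census population but no sampled participants is collapsed
    into the adjacent younger age stratum of the same gender (the youngest
    collapses upward), so post-stratification never divides by zero. Returns
    the mapping and human-readable notes.
    """
    mapping: dict[Stratum, Stratum] = {}
    notes: list[str] = []
    strata = [s for s in ALL_STRATA if census.counts.get(s, 0) > 0]
    if not any(sample_counts.get(s, 0) > 0 for s in strata):
        raise EstimationError("no sampled participants in any census stratum")
    for s in strata:
        if sample_counts.get(s, 0) > 0:
            mapping[s] = s
            continue
        ag, gender = s
        idx = AGE_GROUPS.index(ag)
        target = None
        for j in list(range(idx - 1, -1, -1)) + list(range(idx + 1, len(AGE_GROUPS))):
            cand = (AGE_GROUPS[j], gender)
            if sample_counts.get(cand, 0) > 0:
                target = cand
                break
        if target is None:  # no sampled stratum for this gender at all
            for j in range(len(AGE_GROUPS)):
                cand = (AGE_GROUPS[j], Gender.MALE if gender is Gender.FEMALE else Gender.FEMALE)
                if sample_counts.get(cand, 0) > 0:
                    target = cand
                    break
        mapping[s] = target
        notes.append(
            f"stratum {ag}/{gender.value} unsampled; collapsed into "
            f"{target[0]}/{target[1].value}"
        )
    return mapping, notes


def poststrat_weights(
    sample_counts: dict[Stratum, int], census: CensusStructure
) -> tuple[dict[Stratum, float], list[str]]:
    """Post-stratification weights w_h = (N_h/N) / (n_h/n).

    A participant in stratum h is up- or down-weighted so that the weighted
    sample age-gender distribution matches the census. Unsampled strata with
    census population are collapsed into an adjacent stratum (their census
    mass is carried by the collapse target); the notes record any collapses.
    """
    n_total = sum(sample_counts.values())
    if n_total <= 0:
        raise EstimationError("sample is empty")
    mapping, notes = _collapse_strata(sample_counts, census)
    # census mass per collapse target
    census_mass: dict[Stratum, float] = {}
    for s, target in mapping.items():
        census_mass[target] = census_mass.get(target, 0.0) + census.counts.get(s, 0.0)
    big_n = census.total()
    weights: dict[Stratum, float] = {}
    for target, mass in census_mass.items():
        n_h = sample_counts[target]
        weights[target] = (mass / big_n) / (n_h / n_total)
    return weights, notes


Predicate = Union[ImpairmentCategory, Callable[[ParticipantRecord], bool]]


def _as_predicate(category: Predicate) -> Callable[[ParticipantRecord], bool]:
    if isinstance(category, ImpairmentCategory):
        def pred(r: ParticipantRecord, _cat=category) -> bool:
            better = r.better_eye_presenting()
            return better is not None and classify_impairment(better) is _cat

        return pred
    return category


@dataclass
class IndicatorResult:
    """A prevalence-type indicator with design-based uncertainty."""

    crude: float
    weighted: float
    se: float                       # cluster-ratio SE of the crude estimate
    se_weighted: float              # delete-one-cluster jackknife SE
    ci95: tuple[float, float]       # crude-scale Wald interval
    ci95_weighted: tuple[float, float]
    n: int
    n_cases: int
    by_gender: dict[str, "IndicatorResult"] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _wald_ci(p: float, se: float) -> tuple[float, float]:
    return (max(0.0, p - Z_95 * se), min(1.0, p + Z_95 * se))


def _weighted_estimate(
    strata: Sequence[Stratum], cases: Sequence[bool], census: CensusStructure
) -> float:
    counts: dict[Stratum, int] = {}
    case_counts: dict[Stratum, int] = {}
    for s, is_case in zip(strata, cases):
        counts[s] = counts.get(s, 0) + 1
        if is_case:
            case_counts[s] = case_counts.get(s, 0) + 1
    mapping, _ = _collapse_strata(counts, census)
    census_mass: dict[Stratum, float] = {}
    for s, target in mapping.items():
        census_mass[target] = census_mass.get(target, 0.0) + census.counts.get(s, 0.0)
    big_n = sum(census_mass.values())
    est = 0.0
    for target, mass in census_mass.items():
        p_h = case_counts.get(target, 0) / counts[target]
        est += (mass / big_n) * p_h
    return est


def jackknife_weighted_se(
    clusters: Sequence[str],
    strata: Sequence[Stratum],
    cases: Sequence[bool],
    census: CensusStructure,
) -> float:
    """Delete-one-cluster jackknife SE of the post-stratified estimate.

    The cluster-ratio formula applies to crude ratios only; for the weighted
    estimate each cluster is deleted in turn, the post-stratified estimate
    recomputed, and se = sqrt((c−1)/c · Σ(θ_(j) − θ̄)²).
    """
    clusters = np.asarray(clusters)
    strata_arr = list(strata)
    cases_arr = np.asarray(cases, dtype=bool)
    uniq = pd.unique(clusters)
    c = len(uniq)
    if c < 2:
        raise EstimationError("jackknife requires at least 2 clusters")
    thetas = []
    for cl in uniq:
        keep = clusters != cl
        thetas.append(
            _weighted_estimate(
                [s for s, k in zip(strata_arr, keep) if k],
                cases_arr[keep],
                census,
            )
        )
    thetas = np.array(thetas)
    return float(math.sqrt((c - 1) / c * float(np.sum((thetas - thetas.mean()) ** 2))))


def cluster_tallies(
    ds: Dataset, predicate: Callable[[ParticipantRecord], bool]
) -> list[ClusterTally]:
    """Per-cluster (examined, cases) tallies for a case predicate."""
    per: dict[str, list[int]] = {}
    for r in ds.examined():
        ex, ca = per.setdefault(r.cluster_id, [0, 0])
        per[r.cluster_id][0] = ex + 1
        per[r.cluster_id][1] = ca + (1 if predicate(r) else 0)
    return [
        ClusterTally(cid, n_examined=v[0], n_cases=v[1]) for cid, v in per.items()
    ]


def estimate_prevalence(
    ds: Dataset,
    category: Predicate,
    census: CensusStructure,
    disaggregate: bool = True,
) -> IndicatorResult:
    """Crude and age-gender-post-stratified prevalence with 95% CIs.

    The crude estimate uses the cluster-ratio SE; the weighted estimate
    post-stratifies stratum prevalences to the census age-gender counts and
    takes its SE from a delete-one-cluster jackknife. Output is always also
    disaggregated by gender (each gender post-stratified within its own four
    age strata).
    """
    pred = _as_predicate(category)
    examined = [r for r in ds.examined()]
    if not examined:
        raise EstimationError("dataset contains no examined participants")
    tallies = cluster_tallies(ds, pred)
    p, se = bennett_se(tallies)

    strata = [(age_group_of(r.age), r.gender) for r in examined]
    cases = [pred(r) for r in examined]
    clusters = [r.cluster_id for r in examined]
    weighted = _weighted_estimate(strata, cases, census)
    se_w = jackknife_weighted_se(clusters, strata, cases, census)
    counts: dict[Stratum, int] = {}
    for s in strata:
        counts[s] = counts.get(s, 0) + 1
    _, notes = _collapse_strata(counts, census)

    by_gender: dict[str, IndicatorResult] = {}
    if disaggregate:
        for g in (Gender.MALE, Gender.FEMALE):
            sub = Dataset(records=[r for r in examined if r.gender is g])
            if not sub.records:
                continue
            try:
                by_gender[g.value] = estimate_prevalence(
                    sub, pred, census.restricted(g), disaggregate=False
                )
            except EstimationError:
                pass  # fewer than 2 clusters with this gender

    return IndicatorResult(
        crude=p,
        weighted=weighted,
        se=se,
        se_weighted=se_w,
        ci95=_wald_ci(p, se),
        ci95_weighted=_wald_ci(weighted, se_w),
        n=len(examined),
        n_cases=int(sum(cases)),
        by_gender=by_gender,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Coverage indicators


@dataclass(frozen=True)
class CoverageComponents:
    """Counts behind a coverage ratio; the denominator is their sum."""

    met: int          # operated (cataract) / corrected with good outcome (refraction)
    undermet: int     # operated but poor outcome / corrected but still impaired
    unmet: int        # operable, unoperated / uncorrected need

    @property
    def denominator(self) -> int:
        return self.met + self.undermet + self.unmet


@dataclass
class CataractCoverageResult:
    csc_person: Optional[float]
    ecsc_person: Optional[float]
    person_components: CoverageComponents
    csc_eye: Optional[float]
    ecsc_eye: Optional[float]
    eye_components: CoverageComponents


def _eye_operable(eye, operable_threshold: VAGrade) -> bool:
    return (
        eye is not None
        and eye.lens_status is LensStatus.OBVIOUS_OPACITY
        and eye.presenting_va is not None
        and eye.presenting_va.worse_than(operable_threshold)
        and eye.main_cause is Cause.CATARACT_UNTREATED
    )


def cataract_coverage(
    ds: Dataset,
    outcome_threshold: VAGrade = VAGrade.V6_12,
    operable_threshold: VAGrade = VAGrade.V6_12,
) -> CataractCoverageResult:
    """Cataract surgical coverage and effective coverage, person and eye level.

    Person level: with x = bilaterally operated persons, y = unilaterally
    operated persons and z = bilaterally operable persons (both eyes with
    obvious opacity, cataract as main cause and presenting acuity worse than
    ``operable_threshold``), CSC = (x+y)/(x+y+z). eCSC restricts the
    numerator to operated persons with a good outcome — presenting acuity at
    least ``outcome_threshold`` in at least one operated eye — so
    eCSC ≤ CSC always. Eye-level analogues count eyes. Empty denominators
    yield None (not computable).
    """
    x = y = z = 0
    good_person = 0
    op_eyes = operable_eyes = good_eyes = 0
    for r in ds.examined():
        eyes = r.eyes()
        operated = [e for e in eyes if e.lens_status is not None and e.lens_status.operated]
        operable = [e for e in eyes if _eye_operable(e, operable_threshold)]
        op_eyes += len(operated)
        operable_eyes += len(operable)
        good_eyes += sum(
            1
            for e in operated
            if e.presenting_va is not None and e.presenting_va.at_least(outcome_threshold)
        )
        if len(operated) >= 2:
            x += 1
        elif len(operated) == 1:
            y += 1
        elif len(operable) >= 2:
            z += 1
        if operated and any(
            e.presenting_va is not None and e.presenting_va.at_least(outcome_threshold)
            for e in operated
        ):
            good_person += 1

    person_comp = CoverageComponents(
        met=good_person, undermet=(x + y) - good_person, unmet=z
    )
    eye_comp = CoverageComponents(
        met=good_eyes, undermet=op_eyes - good_eyes, unmet=operable_eyes
    )
    denom_p = person_comp.denominator
    denom_e = eye_comp.denominator
    return CataractCoverageResult(
        csc_person=(x + y) / denom_p if denom_p else None,
        ecsc_person=good_person / denom_p if denom_p else None,
        person_components=person_comp,
        csc_eye=op_eyes / denom_e if denom_e else None,
        ecsc_eye=good_eyes / denom_e if denom_e else None,
        eye_components=eye_comp,
    )


@dataclass
class RefractiveCoverageResult:
    rec: Optional[float]
    erec: Optional[float]
    components: CoverageComponents


def refractive_coverage(ds: Dataset) -> RefractiveCoverageResult:
    """Refractive error coverage (REC) and effective coverage (eREC).

    Better-eye, person-level basis. Refractive need is marked by pinhole
    improvement (refraction is not performed in the rapid protocol):

    - met: wears distance correction, uncorrected acuity worse than 6/12,
      presenting acuity 6/12 — the correction restores normal vision;
    - undermet: wears correction but presenting acuity is still worse than
      6/12 while pinhole reaches 6/12 — inadequate correction;
    - unmet: no correction, presenting worse than 6/12, pinhole 6/12.

    eREC = met / (met+undermet+unmet); REC = (met+undermet) / (same).
    """
    met = undermet = unmet = 0
    for r in ds.examined():
        ucva = r.better_eye_uncorrected()
        pres = r.better_eye_presenting()
        pin = r.better_eye_pinhole()
        if pres is None or ucva is None:
            continue
        if r.wears_distance_correction:
            if ucva.worse_than(VAGrade.V6_12) and pres is VAGrade.V6_12:
                met += 1
            elif pres.worse_than(VAGrade.V6_12) and pin is VAGrade.V6_12:
                undermet += 1
        else:
            if pres.worse_than(VAGrade.V6_12) and pin is VAGrade.V6_12:
                unmet += 1
    comp = CoverageComponents(met=met, undermet=undermet, unmet=unmet)
    d = comp.denominator
    return RefractiveCoverageResult(
        rec=(met + undermet) / d if d else None,
        erec=met / d if d else None,
        components=comp,
    )


def surgical_outcomes(ds: Dataset) -> dict[str, float]:
    """Distribution of presenting-vision outcomes over all operated eyes.

    good: ≥6/12; borderline: worse than 6/12 but ≥6/60; poor: worse than
    6/60. Returns proportions summing to 1, or an empty dict when the sample
    contains no operated eyes.
    """
    counts = {"good": 0, "borderline": 0, "poor": 0}
    for r in ds.examined():
        for e in r.eyes():
            if e.lens_status is None or not e.lens_status.operated:
                continue
            va = e.presenting_va
            if va is None:
                continue
            if va.at_least(VAGrade.V6_12):
                counts["good"] += 1
            elif va.at_least(VAGrade.V6_60):
                counts["borderline"] += 1
            else:
                counts["poor"] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in counts.items()}


def tabulate_barriers(ds: Dataset) -> tuple[dict[str, float], list[str]]:
    """Per-option percentages of barriers to cataract surgery.

    The denominator is persons asked the barrier questions (routed and with
    recorded answers). Up to two options per person, so columns can sum past
    100%. Persons with more than two recorded options are excluded and
    returned in the second element.
    """
    asked = 0
    counts: dict[str, int] = {}
    excluded: list[str] = []
    for r in ds.examined():
        if r.barriers is None:
            continue
        if not followup_route(r).barrier_questions:
            continue
        if len(r.barriers) > MAX_BARRIERS:
            excluded.append(r.participant_id)
            continue
        asked += 1
        for b in r.barriers:
            counts[b] = counts.get(b, 0) + 1
    if asked == 0:
        return {}, excluded
    return {b: 100.0 * c / asked for b, c in sorted(counts.items())}, excluded


def response_rate(ds: Dataset) -> float:
    """Examined participants over all enrolled (examined + unavailable +
    refused)."""
    enrolled = len(ds.records)
    if enrolled == 0:
        raise EstimationError("no enrolled participants")
    examined = sum(1 for r in ds.records if r.examined)
    return examined / enrolled


def table3_summary(
    counts: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Row percentages for a per-region available/unavailable table.

    ``counts`` maps region name to (available, unavailable). Returns a frame
    with per-region and Total rows, each with N and % for both columns.
    """
    if not counts:
        raise EstimationError("empty table")
    if all(a == 0 and u == 0 for a, u in counts.values()):
        raise EstimationError("all-zero table")
    rows = []
    tot_a = tot_u = 0
    for region, (a, u) in counts.items():
        total = a + u
        rows.append(
            {
                "region": region,
                "available_n": a,
                "available_pct": 100.0 * a / total if total else float("nan"),
                "unavailable_n": u,
                "unavailable_pct": 100.0 * u / total if total else float("nan"),
                "total_n": total,
            }
        )
        tot_a += a
        tot_u += u
    grand = tot_a + tot_u
    rows.append(
        {
            "region": "Total",
            "available_n": tot_a,
            "available_pct": 100.0 * tot_a / grand,
            "unavailable_n": tot_u,
            "unavailable_pct": 100.0 * tot_u / grand,
            "total_n": grand,
        }
    )
    return pd.DataFrame(rows).set_index("region")
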