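import math
from dataclasses import replace

import numpy as np
import pytest

from raabkit import (
    Cause,
    CensusStructure,
    ClusterTally,
    Dataset,
    Gender,
    ImpairmentCategory,
    LensStatus,
    VAGrade,
    bennett_se,
    cataract_coverage,
    estimate_prevalence,
    poststrat_weights,
    refractive_coverage,
    response_rate,
    surgical_outcomes,
    table3_summary,
    tabulate_barriers,
)
from raabkit.estimation import AGE_GROUPS, EstimationError

from conftest import make_record


def jackknife_ratio_se(a, n):
    """Independent delete-one-cluster jackknife for the ratio p = sum(a)/sum(n)."""
    a, n = np.asarray(a, float), np.asarray(n, float)
    c = len(a)
    thetas = np.array([
        (a.sum() - a[j]) / (n.sum() - n[j]) for j in range(c)
    ])
    return math.sqrt((c - 1) / c * np.sum((thetas - thetas.mean()) ** 2))


def uniform_census(count=100.0):
    return CensusStructure(
        counts={(ag, g): count for ag in AGE_GROUPS for g in (Gender.MALE, Gender.FEMALE)}
    )


class TestBennettSe:
    def test_identical_clusters_zero_variance(self):
        tallies = [ClusterTally("a", 50, 5), ClusterTally("b", 50, 5)]
        p, se = bennett_se(tallies)
        assert p == pytest.approx(0.10)
        assert se == 0.0

    def test_hand_evaluated_example(self):
        tallies = [ClusterTally(c, 50, a) for c, a in zip("abc", (2, 4, 6))]
        p, se = bennett_se(tallies)
        assert p == pytest.approx(0.08)
        assert se == pytest.approx(0.023094, abs=1e-6)

    def test_single_cluster_rejected(self):
        with pytest.raises(EstimationError):
            bennett_se([ClusterTally("a", 50, 5)])

    def test_close_to_jackknife_on_many_equal_clusters(self, rng):
        n = np.full(30, 50)
        a = rng.binomial(50, 0.08, size=30)
        tallies = [ClusterTally(str(i), 50, int(x)) for i, x in enumerate(a)]
        _, se = bennett_se(tallies)
        se_jk = jackknife_ratio_se(a, n)
        assert se == pytest.approx(se_jk, rel=0.15)


class TestPoststratWeights:
    def test_identity_when_sample_matches_census(self):
        census = uniform_census(1000.0)
        sample = {s: 25 for s in census.counts}
        weights, notes = poststrat_weights(sample, census)
        assert notes == []
        for w in weights.values():
            assert w == pytest.approx(1.0)

    def test_two_stratum_hand_example(self):
        # census 50/50, sample 40/60 -> weights 1.25 and 0.8333
        census = CensusStructure(counts={
            ("50-59", Gender.MALE): 500, ("60-69", Gender.MALE): 500,
        })
        sample = {("50-59", Gender.MALE): 40, ("60-69", Gender.MALE): 60}
        weights, _ = poststrat_weights(sample, census)
        assert weights[("50-59", Gender.MALE)] == pytest.approx(1.25)
        assert weights[("60-69", Gender.MALE)] == pytest.approx(0.83333, abs=1e-4)

    def test_empty_stratum_collapses_into_adjacent(self):
        census = CensusStructure(counts={
            ("50-59", Gender.MALE): 400, ("60-69", Gender.MALE): 300,
            ("70-79", Gender.MALE): 200, ("80+", Gender.MALE): 100,
        })
        sample = {("50-59", Gender.MALE): 50, ("60-69", Gender.MALE): 30,
                  ("70-79", Gender.MALE): 20}  # 80+ unsampled
        weights, notes = poststrat_weights(sample, census)
        assert len(notes) == 1 and "80+" in notes[0]
        # 70-79 carries census mass of both 70-79 and 80+
        assert weights[("70-79", Gender.MALE)] == pytest.approx(
            (300 / 1000) / (20 / 100)
        )

    def test_all_empty_rejected(self):
        with pytest.raises(EstimationError):
            poststrat_weights({}, uniform_census())


def dataset_from_tallies(a, n):
    """Materialize records matching per-cluster (cases, examined) tallies,
    cases blind, spread evenly over age-gender strata."""
    records = []
    i = 0
    for cid, (cases, examined) in enumerate(zip(a, n)):
        for j in range(examined):
            blind = j < cases
            records.append(make_record(
                pid=f"P{i}", cluster=f"C{cid}",
                age=50 + (i % 4) * 10, gender=Gender.MALE if i % 2 else Gender.FEMALE,
                ucva=VAGrade.NPL if blind else VAGrade.V6_12,
            ))
            i += 1
    return Dataset(records=records)


class TestEstimatePrevalence:
    def test_crude_ci_from_hand_example(self):
        ds = dataset_from_tallies([2, 4, 6], [50, 50, 50])
        res = estimate_prevalence(ds, ImpairmentCategory.BLIND, uniform_census())
        assert res.crude == pytest.approx(0.08)
        assert res.ci95[0] == pytest.approx(0.0347, abs=1e-3)
        assert res.ci95[1] == pytest.approx(0.1253, abs=1e-3)

    def test_zero_cases_degenerate(self):
        ds = dataset_from_tallies([0, 0], [30, 30])
        res = estimate_prevalence(ds, ImpairmentCategory.BLIND, uniform_census())
        assert res.crude == 0.0
        assert res.se == 0.0
        assert res.ci95 == (0.0, 0.0)

    def test_weighted_corrects_oversampled_high_prevalence_stratum(self):
        # Old stratum (80+) has higher prevalence and is oversampled relative
        # to the census: the weighted estimate must fall below the crude one.
        records = []
        i = 0
        for cid in range(4):
            for _ in range(20):  # 80+, 50% blind (oversampled)
                records.append(make_record(
                    pid=f"O{i}", cluster=f"C{cid}", age=85,
                    ucva=VAGrade.NPL if i % 2 else VAGrade.V6_12))
                i += 1
            for _ in range(10):  # 50-59, none blind
                records.append(make_record(
                    pid=f"Y{i}", cluster=f"C{cid}", age=55))
                i += 1
        census = CensusStructure(counts={
            ("50-59", Gender.FEMALE): 900, ("80+", Gender.FEMALE): 100,
        })
        ds = Dataset(records=records)
        res = estimate_prevalence(ds, ImpairmentCategory.BLIND, census)
        assert res.weighted < res.crude

    def test_poststratification_identity(self):
        # sample age-gender distribution equals the census -> weighted = crude
        ds = dataset_from_tallies([3, 5], [40, 40])
        counts = {}
        for r in ds.records:
            ag = AGE_GROUPS[(r.age - 50) // 10]
            counts[(ag, r.gender)] = counts.get((ag, r.gender), 0) + 1
        census = CensusStructure(counts={s: float(c) for s, c in counts.items()})
        res = estimate_prevalence(ds, ImpairmentCategory.BLIND, census)
        assert res.weighted == pytest.approx(res.crude, abs=1e-12)

    def test_gender_disaggregation_aggregates_back(self):
        ds = dataset_from_tallies([2, 4, 6], [50, 50, 50])
        res = estimate_prevalence(ds, ImpairmentCategory.BLIND, uniform_census())
        shares, combined = 0.0, 0.0
        for g, sub in res.by_gender.items():
            combined += sub.crude * sub.n
            shares += sub.n
        assert combined / shares == pytest.approx(res.crude, abs=1e-12)

    def test_unexamined_only_rejected(self):
        from raabkit import ExamStatus
        ds = Dataset(records=[make_record(exam_status=ExamStatus.UNAVAILABLE)])
        with pytest.raises(EstimationError):
            estimate_prevalence(ds, ImpairmentCategory.BLIND, uniform_census())


def operated_person(pid, outcome_va, bilateral=True, cluster="C1"):
    rec = make_record(
        pid=pid, cluster=cluster, ucva=outcome_va,
        pinhole=outcome_va if outcome_va.worse_than(VAGrade.V6_12) else None,
        lens=LensStatus.PSEUDOPHAKIA_NO_PCO,
        causes=frozenset({Cause.CATARACT_SURGICAL_COMPLICATIONS})
        if outcome_va.worse_than(VAGrade.V6_12) else frozenset(),
    )
    if not bilateral:
        normal = make_record(pid=pid).right_eye
        rec = replace(rec, left_eye=normal)
    return rec


def operable_person(pid, va=VAGrade.V3_60, cluster="C1"):
    return make_record(
        pid=pid, cluster=cluster, ucva=va, pinhole=va,
        lens=LensStatus.OBVIOUS_OPACITY,
        causes=frozenset({Cause.CATARACT_UNTREATED}),
    )


class TestCataractCoverage:
    def test_hand_counted_fixture(self):
        ds = Dataset(records=[
            operated_person("A", VAGrade.V6_12),
            operated_person("B", VAGrade.V6_60),
            operable_person("C"),
        ])
        res = cataract_coverage(ds)
        assert res.csc_person == pytest.approx(2 / 3)
        assert res.ecsc_person == pytest.approx(1 / 3)

    def test_empty_denominator_not_computable(self):
        ds = Dataset(records=[make_record(pid="N1")])
        res = cataract_coverage(ds)
        assert res.csc_person is None and res.ecsc_person is None

    def test_saturation_all_operated_good(self):
        ds = Dataset(records=[operated_person(f"P{i}", VAGrade.V6_12) for i in range(3)])
        res = cataract_coverage(ds)
        assert res.csc_person == 1.0 and res.ecsc_person == 1.0

    def test_eye_level_counts(self):
        ds = Dataset(records=[
            operated_person("A", VAGrade.V6_12),        # 2 operated eyes, good
            operable_person("C"),                        # 2 operable eyes
        ])
        res = cataract_coverage(ds)
        assert res.csc_eye == pytest.approx(0.5)
        assert res.ecsc_eye == pytest.approx(0.5)

    def test_effective_never_exceeds_plain(self):
        ds = Dataset(records=[
            operated_person("A", VAGrade.V6_12),
            operated_person("B", VAGrade.V3_60),
            operated_person("D", VAGrade.V6_60, bilateral=False),
            operable_person("C"),
        ])
        res = cataract_coverage(ds)
        assert res.ecsc_person <= res.csc_person
        assert res.ecsc_eye <= res.csc_eye

    def test_operable_threshold_configurable(self):
        ds = Dataset(records=[
            operated_person("A", VAGrade.V6_12),
            operable_person("C", va=VAGrade.V6_60),
        ])
        strict = cataract_coverage(ds, operable_threshold=VAGrade.V6_60)
        default = cataract_coverage(ds)
        assert default.csc_person == pytest.approx(0.5)
        assert strict.csc_person == 1.0  # 6/60 eye not operable at the 6/60 cut


def met_person(pid):
    return make_record(pid=pid, ucva=VAGrade.V6_18, corrected=VAGrade.V6_12, wears=True)


def undermet_person(pid):
    return make_record(pid=pid, ucva=VAGrade.V6_60, corrected=VAGrade.V6_18,
                       wears=True, pinhole=VAGrade.V6_12)


def unmet_person(pid):
    return make_record(pid=pid, ucva=VAGrade.V6_18, pinhole=VAGrade.V6_12)


class TestRefractiveCoverage:
    def test_hand_counted_fixture(self):
        ds = Dataset(records=[
            met_person("M"), undermet_person("U"), unmet_person("X"),
            make_record(pid="N1"), make_record(pid="N2"),
        ])
        res = refractive_coverage(ds)
        assert res.erec == pytest.approx(1 / 3)
        assert res.rec == pytest.approx(2 / 3)
        assert res.components.denominator == 3

    def test_no_need_not_computable(self):
        ds = Dataset(records=[make_record(pid="N1"), make_record(pid="N2")])
        res = refractive_coverage(ds)
        assert res.erec is None and res.rec is None

    def test_saturation_all_met(self):
        ds = Dataset(records=[met_person(f"M{i}") for i in range(4)])
        res = refractive_coverage(ds)
        assert res.erec == 1.0 and res.rec == 1.0


class TestSurgicalOutcomes:
    def test_hand_counted_thirds(self):
        ds = Dataset(records=[
            operated_person("A", VAGrade.V6_12, bilateral=False),
            operated_person("B", VAGrade.V6_60, bilateral=False),
            operated_person("C", VAGrade.V3_60, bilateral=False),
        ])
        out = surgical_outcomes(ds)
        assert out == pytest.approx({"good": 1 / 3, "borderline": 1 / 3, "poor": 1 / 3})

    def test_all_good(self):
        ds = Dataset(records=[operated_person("A", VAGrade.V6_12)])
        assert surgical_outcomes(ds)["good"] == 1.0

    def test_no_operated_eyes_empty(self):
        assert surgical_outcomes(Dataset(records=[make_record()])) == {}


class TestBarriers:
    def test_multi_response_percentages(self):
        p1 = replace(operable_person("P1"), barriers=frozenset({"cost"}))
        p2 = replace(operable_person("P2"), barriers=frozenset({"cost", "distance"}))
        table, excluded = tabulate_barriers(Dataset(records=[p1, p2]))
        assert table["cost"] == pytest.approx(100.0)
        assert table["distance"] == pytest.approx(50.0)
        assert excluded == []

    def test_nobody_routed_empty(self):
        table, _ = tabulate_barriers(Dataset(records=[make_record()]))
        assert table == {}

    def test_three_answers_excluded(self):
        p = replace(operable_person("P1"), barriers=frozenset({"a", "b", "c"}))
        table, excluded = tabulate_barriers(Dataset(records=[p]))
        assert excluded == ["P1"]
        assert table == {}


class TestResponseRate:
    def test_direct_ratio(self):
        from raabkit import ExamStatus
        records = [make_record(pid=f"P{i}") for i in range(97)]
        records += [make_record(pid=f"U{i}", exam_status=ExamStatus.UNAVAILABLE)
                    for i in range(3)]
        assert response_rate(Dataset(records=records)) == pytest.approx(0.97)

    def test_all_examined(self, tiny_clean_dataset):
        assert response_rate(tiny_clean_dataset) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(EstimationError):
            response_rate(Dataset())


class TestRegionSummaryTable:
    # open-access data availability per world region: (available, unavailable)
    PRINTED = {
        "Central Europe, Eastern Europe & Central Asia": (6, 2),
        "High Income": (4, 0),
        "Latin America & Caribbean": (17, 4),
        "North Africa & Middle East": (8, 18),
        "Southeast Asia, East Asia & Oceania": (67, 62),
        "South Asia": (27, 79),
        "Sub Saharan Africa": (35, 46),
    }

    def test_total_row(self):
        df = table3_summary(self.PRINTED)
        assert df.loc["Total", "available_n"] == 164
        assert round(df.loc["Total", "available_pct"], 1) == 43.7

    def test_region_row(self):
        df = table3_summary(self.PRINTED)
        assert round(df.loc["Latin America & Caribbean", "available_pct"], 1) == 81.0

    def test_single_region_even_split(self):
        df = table3_summary({"R": (1, 1)})
        assert df.loc["R", "available_pct"] == pytest.approx(50.0)

    def test_all_zero_rejected(self):
        with pytest.raises(EstimationError):
            table3_summary({"R": (0, 0)})
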