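import warnings

import pytest

from raabkit import (
    Cause,
    CauseRanking,
    EyeExam,
    ImpairmentCategory,
    LensStatus,
    PinholeAction,
    VAGrade,
    assign_main_cause_eye,
    assign_principal_cause,
    classify_impairment,
    cohen_kappa,
    compose_presenting_va,
    followup_route,
    pinhole_requirement,
)
from raabkit.exam import ProtocolError

from conftest import make_record


class TestPresentingVA:
    def test_non_wearer_uses_uncorrected(self):
        assert compose_presenting_va(VAGrade.V6_18, None, False) is VAGrade.V6_18

    def test_wearer_uses_corrected(self):
        assert compose_presenting_va(VAGrade.V6_60, VAGrade.V6_12, True) is VAGrade.V6_12

    def test_wearer_without_corrected_is_protocol_error(self):
        with pytest.raises(ProtocolError):
            compose_presenting_va(VAGrade.V6_12, None, True)


class TestPinholeGating:
    @pytest.mark.parametrize(
        "presenting,action",
        [
            (VAGrade.V6_12, PinholeAction.NOT_TESTED),
            (VAGrade.V6_18, PinholeAction.TEST),
            (VAGrade.V6_60, PinholeAction.TEST),
            (VAGrade.V3_60, PinholeAction.TEST),
            (VAGrade.V1_60, PinholeAction.TEST),
            (VAGrade.PL, PinholeAction.DEFAULT_TO_PRESENTING),
            (VAGrade.NPL, PinholeAction.DEFAULT_TO_PRESENTING),
        ],
    )
    def test_gate(self, presenting, action):
        assert pinhole_requirement(presenting) is action


class TestImpairmentCategories:
    @pytest.mark.parametrize(
        "grade,category",
        [
            (VAGrade.V6_12, ImpairmentCategory.NORMAL),
            (VAGrade.V6_18, ImpairmentCategory.MILD),
            (VAGrade.V6_60, ImpairmentCategory.MODERATE),
            (VAGrade.V3_60, ImpairmentCategory.SEVERE),
            (VAGrade.V1_60, ImpairmentCategory.BLIND),
            (VAGrade.PL, ImpairmentCategory.BLIND),
            (VAGrade.NPL, ImpairmentCategory.BLIND),
        ],
    )
    def test_mapping_total(self, grade, category):
        assert classify_impairment(grade) is category

    def test_order_preserving(self):
        cats = [classify_impairment(g) for g in VAGrade]
        assert cats == sorted(cats)


class TestCauseAssignment:
    def test_normal_eye_gets_no_cause(self, ranking):
        eye = EyeExam(presenting_va=VAGrade.V6_12,
                      examiner_candidate_causes=frozenset({Cause.CATARACT_UNTREATED}))
        assert assign_main_cause_eye(eye, ranking) is None

    def test_pinhole_improvement_overrides_examiner(self, ranking):
        eye = EyeExam(
            presenting_va=VAGrade.V6_18,
            pinhole_va=VAGrade.V6_12,
            examiner_candidate_causes=frozenset({Cause.CATARACT_UNTREATED}),
        )
        assert assign_main_cause_eye(eye, ranking) is Cause.REFRACTIVE_ERROR

    def test_examiner_judgment_stands_without_improvement(self, ranking):
        eye = EyeExam(
            presenting_va=VAGrade.V3_60,
            pinhole_va=VAGrade.V3_60,
            examiner_candidate_causes=frozenset({Cause.GLAUCOMA}),
        )
        assert assign_main_cause_eye(eye, ranking) is Cause.GLAUCOMA

    def test_candidate_outside_ranking_rejected(self):
        trimmed = CauseRanking().remove(Cause.ONCHOCERCIASIS)
        eye = EyeExam(
            presenting_va=VAGrade.V6_60,
            pinhole_va=VAGrade.V6_60,
            examiner_candidate_causes=frozenset({Cause.ONCHOCERCIASIS}),
        )
        with pytest.raises(ValueError, match="not in the active ranking"):
            assign_main_cause_eye(eye, trimmed)

    def test_principal_prefers_more_treatable(self, ranking):
        got = assign_principal_cause(
            Cause.GLAUCOMA, Cause.CATARACT_UNTREATED,
            ImpairmentCategory.MODERATE, ranking,
        )
        assert got is Cause.CATARACT_UNTREATED

    def test_principal_identical_causes(self, ranking):
        got = assign_principal_cause(
            Cause.CATARACT_UNTREATED, Cause.CATARACT_UNTREATED,
            ImpairmentCategory.BLIND, ranking,
        )
        assert got is Cause.CATARACT_UNTREATED

    def test_principal_none_for_normal_person(self, ranking):
        assert assign_principal_cause(
            None, Cause.CATARACT_UNTREATED, ImpairmentCategory.NORMAL, ranking
        ) is None

    def test_principal_single_sighted_eye_cause(self, ranking):
        got = assign_principal_cause(
            None, Cause.ARMD, ImpairmentCategory.MILD, ranking
        )
        assert got is Cause.ARMD


class TestFollowupRouting:
    def test_opacity_with_impaired_pinhole_routes_to_barriers(self):
        rec = make_record(ucva=VAGrade.V6_60, pinhole=VAGrade.V6_60,
                          lens=LensStatus.OBVIOUS_OPACITY,
                          causes=frozenset({Cause.CATARACT_UNTREATED}))
        route = followup_route(rec)
        assert route.barrier_questions and not route.surgical_outcome_questions

    def test_pseudophakia_routes_to_surgical_questions(self):
        rec = make_record(ucva=VAGrade.V6_18, pinhole=VAGrade.V6_18,
                          lens=LensStatus.PSEUDOPHAKIA_NO_PCO,
                          causes=frozenset({Cause.CATARACT_SURGICAL_COMPLICATIONS}))
        route = followup_route(rec)
        assert route.surgical_outcome_questions and not route.barrier_questions

    def test_normal_participant_routes_nowhere(self):
        rec = make_record()
        assert followup_route(rec).none

    def test_opacity_with_pinhole_improvement_not_barrier_routed(self):
        # pinhole reaches 6/12, so the impairment is refractive, not cataract
        rec = make_record(ucva=VAGrade.V6_60, pinhole=VAGrade.V6_12,
                          lens=LensStatus.OBVIOUS_OPACITY)
        assert not followup_route(rec).barrier_questions


class TestCohenKappa:
    def test_perfect_agreement(self):
        a = ["VA1", "VA2"] * 10
        kappa, passed = cohen_kappa(a, list(a))
        assert kappa == pytest.approx(1.0)
        assert passed

    def test_hand_computed_contingency_table(self):
        # 20 (A,A), 20 (B,B), 5 (A,B), 5 (B,A): p0=0.8, pe=0.5, kappa=0.6
        a = ["A"] * 20 + ["B"] * 20 + ["A"] * 5 + ["B"] * 5
        b = ["A"] * 20 + ["B"] * 20 + ["B"] * 5 + ["A"] * 5
        kappa, passed = cohen_kappa(a, b)
        assert kappa == pytest.approx(0.6)
        assert passed

    def test_independence_gives_zero(self):
        # joint equals product of marginals exactly
        a = ["A", "A", "B", "B"]
        b = ["A", "B", "A", "B"]
        kappa, passed = cohen_kappa(a, b)
        assert kappa == pytest.approx(0.0)
        assert not passed

    def test_matches_sklearn_on_random_ratings(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(10):
            a = rng.choice(list("XYZ"), size=40)
            b = rng.choice(list("XYZ"), size=40)
            kappa, _ = cohen_kappa(list(a), list(b))
            assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_constant_identical_raters_warn(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            kappa, passed = cohen_kappa(["A"] * 5, ["A"] * 5)
        assert kappa == 1.0 and passed and len(w) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["A", "B"], ["A"])
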