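"""The examination decision rules on single eyes and persons.

Shows presenting-acuity composition, pinhole gating, the refractive-error
override, and the avoidability-ranked principal cause.
"""

from raabkit import (
    Cause,
    CauseRanking,
    EyeExam,
    ImpairmentCategory,
    VAGrade,
    assign_main_cause_eye,
    assign_principal_cause,
    classify_impairment,
    cohen_kappa,
    compose_presenting_va,
    pinhole_requirement,
)

ranking = CauseRanking()

# A spectacle wearer presents with their correction on.
presenting = compose_presenting_va(
    uncorrected=VAGrade.V6_60, corrected=VAGrade.V6_18, wears_correction=True
)
print(f"presenting acuity: {presenting.token}")
print(f"pinhole action   : {pinhole_requirement(presenting).value}")
print(f"person category  : {classify_impairment(presenting).name}")

# Pinhole improvement to 6/12 marks refractive error, overriding whatever
# the examiner recorded — even cataract.
eye = EyeExam(
    presenting_va=VAGrade.V6_18,
    pinhole_va=VAGrade.V6_12,
    examiner_candidate_causes=frozenset({Cause.CATARACT_UNTREATED}),
)
print(f"main cause with pinhole improvement: {assign_main_cause_eye(eye, ranking).value}")

# Between two eyes with different causes, the more treatable wins.
principal = assign_principal_cause(
    Cause.GLAUCOMA, Cause.CATARACT_UNTREATED, ImpairmentCategory.MODERATE, ranking
)
print(f"principal cause (glaucoma vs cataract): {principal.value}")

# Training-week inter-observer agreement, graded by Cohen's kappa (pass at 0.6).
a = ["6/12"] * 20 + ["6/60"] * 20 + ["6/12"] * 5 + ["6/60"] * 5
b = ["6/12"] * 20 + ["6/60"] * 20 + ["6/60"] * 5 + ["6/12"] * 5
kappa, passed = cohen_kappa(a, b)
print(f"kappa = {kappa:.2f}, acceptable agreement: {passed}")
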