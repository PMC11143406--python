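"""Synthetic-population generator and field-work simulator.

The generator emulates the statistical structure the survey analysis
assumes: clustered populations of census-enumeration-area size with a
configurable age-gender structure among people 50 and older, blindness with
between-cluster heterogeneity (beta-binomial, intracluster correlation
mapped from the target design effect), cataract surgical histories with an
outcome mix, unoperated operable cataract, refractive-error need with a
met/undermet/unmet split, and an availability (non-response) model with a
mop-up revisit.

The field-work simulator then runs the actual two-stage design against a
generated population: PPS selection of PSUs, sketch-map segmentation, a
random-corner door-to-door walk enrolling exactly one cluster of eligible
people (spilling into the nearest neighbouring unit when a segment runs
out), availability and mop-up draws, and emission of a participant dataset
in the same form the readers and estimators consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Optional, Sequence

import numpy as np

from .design import SamplingFrame, SurveyDesign, plan_segmentation, select_psus_pps
from .estimation import AGE_GROUPS, CensusStructure, Stratum
from .exam import derive_record
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
)

# latent person states
S_NORMAL, S_BLIND_CAT, S_BLIND_OTHER, S_OPERATED, S_OPERABLE = 0, 1, 2, 3, 4
S_RE_MET, S_RE_UNDERMET, S_RE_UNMET = 5, 6, 7

#: Default barrier-to-surgery response options (six, as presented to
#: examiners); the engine only enforces the choose-up-to-two rule.
DEFAULT_BARRIER_OPTIONS = (
    "cost",
    "distance",
    "no_escort",
    "fear",
    "no_felt_need",
    "service_unavailable",
)


def icc_for_deff(deff: float, cluster_size: int) -> float:
    """Intracluster correlation implied by a design effect at a cluster size,
    via DEFF = 1 + (m−1)·ICC."""
    return (deff - 1.0) / (cluster_size - 1)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic population and field-work model.

    Prevalences are fractions of the population aged 50+. The default
    availability model examines 90% at the first visit and recovers half of
    the remainder at the mop-up revisit, for an expected response rate of
    0.95.
    """

    n_psus: int = 120
    psu_mean_population: float = 1000.0   # all ages
    psu_population_cv: float = 0.25
    proportion_50plus: float = 0.20
    #: stratum shares among people 50+, (age_group, gender) -> fraction
    age_gender_structure: dict[Stratum, float] = field(default_factory=lambda: {
        (ag, g): share / 2.0
        for ag, share in zip(AGE_GROUPS, (0.45, 0.30, 0.17, 0.08))
        for g in (Gender.MALE, Gender.FEMALE)
    })
    blindness_prevalence: float = 0.02
    #: relative risk of blindness by age group (normalised internally so the
    #: overall prevalence stays exactly blindness_prevalence)
    blindness_age_rr: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    cluster_icc: float = icc_for_deff(1.5, 50)
    blind_cataract_fraction: float = 0.6
    blind_va_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # 1/60, PL, NPL
    operated_prevalence: float = 0.05
    operated_bilateral_fraction: float = 0.5
    outcome_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)  # good/borderline/poor
    operable_prevalence: float = 0.04
    re_need_prevalence: float = 0.15
    re_mix: tuple[float, float, float] = (0.4, 0.2, 0.4)  # met/undermet/unmet
    normal_wearer_fraction: float = 0.05
    institutionalized_fraction: float = 0.01
    household_mean_eligible: float = 1.6
    availability: float = 0.9
    mopup_recovery: float = 0.5
    refusal: float = 0.0
    #: optional availability multipliers by age group (older people are more
    #: often at home); None = constant availability
    availability_age_mult: Optional[tuple[float, ...]] = None
    barrier_options: tuple[str, ...] = DEFAULT_BARRIER_OPTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.blindness_prevalence,
            self.operated_prevalence,
            self.operable_prevalence,
            self.re_need_prevalence,
            self.availability,
            self.mopup_recovery,
            self.refusal,
            self.blind_cataract_fraction,
            self.institutionalized_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if not 0.0 <= self.cluster_icc < 1.0:
            raise ConfigError("cluster_icc must lie in [0, 1)")
        total_share = sum(self.age_gender_structure.values())
        if abs(total_share - 1.0) > 1e-9:
            raise ConfigError("age-gender stratum shares must sum to 1")
        fixed = (
            self.operated_prevalence
            + self.operable_prevalence
            + self.re_need_prevalence
        )
        if fixed + self.blindness_prevalence * max(self.blindness_age_rr) * 2 >= 1.0:
            raise ConfigError("state prevalences are infeasible (sum too close to 1)")
        for mix in (self.outcome_mix, self.re_mix, self.blind_va_mix):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigError("mixture fractions must sum to 1")

    def age_rr_normalised(self) -> np.ndarray:
        """Age relative risks scaled so the population-average risk is 1."""
        shares = np.array(
            [sum(v for (ag, _g), v in self.age_gender_structure.items() if ag == a)
             for a in AGE_GROUPS]
        )
        rr = np.asarray(self.blindness_age_rr, dtype=float)
        return rr / float(np.sum(shares * rr))


@dataclass
class PsuPopulation:
    """One synthetic primary sampling unit.

    Person-level attributes are parallel column arrays; households are
    contiguous runs of persons identified by ``household`` ids, emulating the
    door-to-door walk order of the sketch map.
    """

    psu_id: str
    all_age_population: int
    age: np.ndarray            # int
    gender: np.ndarray         # 0 male, 1 female
    household: np.ndarray      # int household index, sorted
    institutionalized: np.ndarray  # bool
    state: np.ndarray          # latent state code
    aux1: np.ndarray           # state-specific latent detail
    aux2: np.ndarray

    @property
    def n_persons(self) -> int:
        return len(self.age)


@dataclass
class Population:
    """A full synthetic multi-PSU population plus its generating config."""

    psus: list[PsuPopulation]
    cfg: SimConfig

    def frame(self) -> SamplingFrame:
        return SamplingFrame(
            psus=[(p.psu_id, p.all_age_population) for p in self.psus]
        )

    def census(self) -> CensusStructure:
        """True age-gender counts of the eligible (non-institutional)
        population 50+, as a census table for post-stratification."""
        counts: dict[Stratum, float] = {s: 0.0 for s in _all_strata()}
        for p in self.psus:
            ok = ~p.institutionalized
            for i, ag in enumerate(AGE_GROUPS):
                lo, hi = _AGE_BOUNDS[i]
                in_ag = ok & (p.age >= lo) & (p.age < hi)
                counts[(ag, Gender.MALE)] += int(np.sum(in_ag & (p.gender == 0)))
                counts[(ag, Gender.FEMALE)] += int(np.sum(in_ag & (p.gender == 1)))
        return CensusStructure(counts=counts)

    def realized_prevalence(self, states: Sequence[int]) -> float:
        """Fraction of eligible persons in any of the given latent states."""
        num = tot = 0
        for p in self.psus:
            ok = ~p.institutionalized
            num += int(np.sum(ok & np.isin(p.state, states)))
            tot += int(np.sum(ok))
        return num / tot


_AGE_BOUNDS = ((50, 60), (60, 70), (70, 80), (80, 95))


def _all_strata() -> tuple[Stratum, ...]:
    return tuple((ag, g) for g in (Gender.MALE, Gender.FEMALE) for ag in AGE_GROUPS)


def generate_population(cfg: SimConfig, seed: Optional[int] = None) -> Population:
    """Generate a synthetic population per the config; reproducible under
    the seed (defaults to ``cfg.seed``).

    Blindness has between-PSU variation: each PSU draws a base risk from a
    beta distribution with mean ``blindness_prevalence`` and intracluster
    correlation ``cluster_icc``; a person's blindness probability is that
    base risk times their (normalised) age relative risk. All other latent
    states are assigned with constant probability, so their population
    prevalences equal the configured values in expectation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    strata = list(cfg.age_gender_structure)
    shares = np.array([cfg.age_gender_structure[s] for s in strata])
    rr = cfg.age_rr_normalised()
    rr_by_stratum = np.array([rr[AGE_GROUPS.index(s[0])] for s in strata])

    p_b = cfg.blindness_prevalence
    icc = cfg.cluster_icc
    if icc > 0 and 0 < p_b < 1:
        a = p_b * (1.0 / icc - 1.0)
        b = (1.0 - p_b) * (1.0 / icc - 1.0)
    else:
        a = b = None

    # cumulative intervals anchored at the top of [0,1] for the fixed-rate
    # states, so their marginals are exact regardless of the PSU blind risk
    hi_op = 1.0
    lo_op = hi_op - cfg.operated_prevalence
    lo_opc = lo_op - cfg.operable_prevalence
    re_m, re_u, re_n = (cfg.re_need_prevalence * f for f in cfg.re_mix)
    lo_rem = lo_opc - re_m
    lo_reu = lo_rem - re_u
    lo_ren = lo_reu - re_n

    psus: list[PsuPopulation] = []
    for k in range(cfg.n_psus):
        cv = cfg.psu_population_cv
        if cv > 0:
            shape = 1.0 / cv**2
            pop_all = int(max(150, rng.gamma(shape, cfg.psu_mean_population / shape)))
        else:
            pop_all = int(cfg.psu_mean_population)
        n = max(1, round(pop_all * cfg.proportion_50plus))

        stratum_idx = rng.choice(len(strata), size=n, p=shares)
        ag_idx = np.array([AGE_GROUPS.index(strata[i][0]) for i in stratum_idx])
        lo = np.array([_AGE_BOUNDS[i][0] for i in ag_idx])
        hi = np.array([_AGE_BOUNDS[i][1] for i in ag_idx])
        age = lo + (rng.random(n) * (hi - lo)).astype(int)
        gender = np.array(
            [0 if strata[i][1] is Gender.MALE else 1 for i in stratum_idx]
        )

        base = float(rng.beta(a, b)) if a is not None else p_b
        p_blind = np.minimum(base * rr_by_stratum[stratum_idx], lo_ren)

        u = rng.random(n)
        state = np.zeros(n, dtype=np.int8)
        state[u < p_blind] = S_BLIND_CAT
        blind = state == S_BLIND_CAT
        other = blind & (rng.random(n) >= cfg.blind_cataract_fraction)
        state[other] = S_BLIND_OTHER
        state[(u >= lo_op)] = S_OPERATED
        state[(u >= lo_opc) & (u < lo_op)] = S_OPERABLE
        state[(u >= lo_rem) & (u < lo_opc)] = S_RE_MET
        state[(u >= lo_reu) & (u < lo_rem)] = S_RE_UNDERMET
        state[(u >= lo_ren) & (u < lo_reu)] = S_RE_UNMET

        aux1 = np.zeros(n, dtype=np.int8)
        aux2 = np.zeros(n, dtype=np.int8)
        is_blind = np.isin(state, (S_BLIND_CAT, S_BLIND_OTHER))
        aux1[is_blind] = rng.choice(3, size=int(is_blind.sum()), p=cfg.blind_va_mix)
        operated = state == S_OPERATED
        n_op = int(operated.sum())
        aux1[operated] = (
            rng.random(n_op) < cfg.operated_bilateral_fraction
        ).astype(np.int8)
        o1 = rng.choice(3, size=n_op, p=cfg.outcome_mix)
        o2 = rng.choice(3, size=n_op, p=cfg.outcome_mix)
        aux2[operated] = o1 * 3 + o2
        wearer = np.isin(state, (S_RE_MET, S_RE_UNDERMET))
        aux2[wearer] = rng.choice(3, size=int(wearer.sum()))  # spectacle age
        normal = state == S_NORMAL
        aux1[normal] = (
            rng.random(int(normal.sum())) < cfg.normal_wearer_fraction
        ).astype(np.int8)

        institutionalized = rng.random(n) < cfg.institutionalized_fraction

        # households: contiguous runs with Poisson(mean)>=1 eligible members
        sizes = []
        total = 0
        while total < n:
            s = max(1, int(rng.poisson(cfg.household_mean_eligible)))
            sizes.append(min(s, n - total))
            total += sizes[-1]
        household = np.repeat(np.arange(len(sizes)), sizes)

        psus.append(
            PsuPopulation(
                psu_id=f"PSU{k + 1:04d}",
                all_age_population=pop_all,
                age=age,
                gender=gender,
                household=household,
                institutionalized=institutionalized,
                state=state,
                aux1=aux1,
                aux2=aux2,
            )
        )
    return Population(psus=psus, cfg=cfg)


class SimulationError(RuntimeError):
    pass


_OUTCOME_VA = {0: VAGrade.V6_12, 1: VAGrade.V6_60, 2: VAGrade.V3_60}
_BLIND_VA = {0: VAGrade.V1_60, 1: VAGrade.PL, 2: VAGrade.NPL}
_SPEC_AGE = {0: SpectacleAge.LT2Y, 1: SpectacleAge.Y2TO5, 2: SpectacleAge.GT5Y}


def _operated_eye(outcome: int) -> EyeExam:
    va = _OUTCOME_VA[outcome]
    if outcome == 0:
        return EyeExam(
            uncorrected_va=va, lens_status=LensStatus.PSEUDOPHAKIA_NO_PCO
        )
    return EyeExam(
        uncorrected_va=va,
        pinhole_va=va,
        lens_status=LensStatus.PSEUDOPHAKIA_PCO,
        examiner_candidate_causes=frozenset({Cause.CATARACT_SURGICAL_COMPLICATIONS}),
    )


def _normal_eye(wears: bool) -> EyeExam:
    return EyeExam(
        uncorrected_va=VAGrade.V6_12,
        corrected_va=VAGrade.V6_12 if wears else None,
        lens_status=LensStatus.NORMAL,
    )


def _person_exam(state: int, aux1: int, aux2: int) -> tuple[EyeExam, EyeExam, bool, Optional[SpectacleAge], Optional[str]]:
    """Latent state -> (right eye, left eye, wears correction, spectacle age,
    surgery-followup answer)."""
    if state == S_NORMAL:
        wears = bool(aux1)
        eye = _normal_eye(wears)
        return eye, _dc_replace(eye), wears, _SPEC_AGE[0] if wears else None, None
    if state in (S_BLIND_CAT, S_BLIND_OTHER):
        va = _BLIND_VA[aux1]
        if state == S_BLIND_CAT:
            lens, cause = LensStatus.OBVIOUS_OPACITY, Cause.CATARACT_UNTREATED
        else:
            lens, cause = LensStatus.NORMAL, Cause.GLAUCOMA
        def eye() -> EyeExam:
            return EyeExam(
                uncorrected_va=va,
                pinhole_va=va if va is VAGrade.V1_60 else None,  # PL/NPL default
                lens_status=lens,
                examiner_candidate_causes=frozenset({cause}),
            )
        return eye(), eye(), False, None, None
    if state == S_OPERATED:
        bilateral = bool(aux1)
        o1, o2 = divmod(aux2, 3)
        right = _operated_eye(o1)
        left = _operated_eye(o2) if bilateral else _normal_eye(False)
        followup = (
            "surgical_complications" if (o1 != 0 or (bilateral and o2 != 0)) else None
        )
        return right, left, False, None, followup
    if state == S_OPERABLE:
        def eye() -> EyeExam:
            return EyeExam(
                uncorrected_va=VAGrade.V6_60,
                pinhole_va=VAGrade.V6_60,
                lens_status=LensStatus.OBVIOUS_OPACITY,
                examiner_candidate_causes=frozenset({Cause.CATARACT_UNTREATED}),
            )
        return eye(), eye(), False, None, None
    if state == S_RE_MET:
        def eye() -> EyeExam:
            return EyeExam(
                uncorrected_va=VAGrade.V6_18,
                corrected_va=VAGrade.V6_12,
                lens_status=LensStatus.NORMAL,
            )
        return eye(), eye(), True, _SPEC_AGE[aux2], None
    if state == S_RE_UNDERMET:
        def eye() -> EyeExam:
            return EyeExam(
                uncorrected_va=VAGrade.V6_60,
                corrected_va=VAGrade.V6_18,
                pinhole_va=VAGrade.V6_12,
                lens_status=LensStatus.NORMAL,
            )
        return eye(), eye(), True, _SPEC_AGE[aux2], None
    if state == S_RE_UNMET:
        def eye() -> EyeExam:
            return EyeExam(
                uncorrected_va=VAGrade.V6_18,
                pinhole_va=VAGrade.V6_12,
                lens_status=LensStatus.NORMAL,
            )
        return eye(), eye(), False, None, None
    raise ValueError(f"unknown latent state {state}")


def _availability_prob(cfg: SimConfig, age: int) -> float:
    if cfg.availability_age_mult is None:
        return cfg.availability
    ag = min((age - 50) // 10, 3)
    return min(1.0, cfg.availability * cfg.availability_age_mult[ag])


def _segment_bounds(household: np.ndarray, n_segments: int) -> np.ndarray:
    """Assign each person to one of n population-equal contiguous segments,
    never splitting a household across segments."""
    n = len(household)
    raw = np.minimum((np.arange(n) * n_segments) // n, n_segments - 1)
    # a household lies entirely in the segment of its first member
    first_idx = np.r_[0, np.flatnonzero(household[1:] != household[:-1]) + 1]
    seg_of_household = raw[first_idx]
    return seg_of_household[np.searchsorted(household[first_idx], household)]


def simulate_survey(
    pop: Population,
    design: SurveyDesign,
    n_clusters: int,
    seed: int,
    metadata_year: int = 2024,
) -> Dataset:
    """Simulate one complete survey of a generated population.

    Selects PSUs with PPS, segments each, starts the walk at a random corner
    (a random rotation of the household order), enrols exactly
    ``design.cluster_size`` eligible persons per cluster — spilling into the
    rest of the PSU and then the next population unit when a segment holds
    too few — applies the availability/mop-up model, and emits a derived
    participant dataset. Deterministic for a fixed (population, seed).
    """
    cfg = pop.cfg
    rng = np.random.default_rng(seed)
    frame = pop.frame()
    psu_by_id = {p.psu_id: i for i, p in enumerate(pop.psus)}
    selected = select_psus_pps(frame, n_clusters, rng)
    used: dict[int, np.ndarray] = {}

    records: list[ParticipantRecord] = []
    cluster_ids: list[str] = []
    for k, psu_id in enumerate(selected):
        cluster_id = f"C{k + 1:03d}"
        cluster_ids.append(cluster_id)
        start_idx = psu_by_id[psu_id]
        plan = plan_segmentation(
            pop.psus[start_idx].all_age_population,
            cfg.proportion_50plus,
            design.cluster_size,
            rng,
        )
        enrolled = 0
        # candidate pools: chosen segment, rest of the PSU, then subsequent
        # population units in frame order ("nearest population unit")
        pool_specs: list[tuple[int, Optional[int]]] = [(start_idx, plan.chosen_segment)]
        pool_specs.append((start_idx, None))
        for step in range(1, len(pop.psus)):
            pool_specs.append(((start_idx + step) % len(pop.psus), None))

        for psu_idx, segment in pool_specs:
            if enrolled >= design.cluster_size:
                break
            psu = pop.psus[psu_idx]
            mask = used.setdefault(psu_idx, np.zeros(psu.n_persons, dtype=bool))
            if segment is not None and plan.n_segments > 1:
                seg = _segment_bounds(psu.household, plan.n_segments)
                candidates = np.flatnonzero(
                    (seg == segment) & ~mask & ~psu.institutionalized
                )
            else:
                candidates = np.flatnonzero(~mask & ~psu.institutionalized)
            if candidates.size == 0:
                continue
            # random corner: rotate the household walk order
            households = psu.household[candidates]
            uniq_h = np.unique(households)
            offset = int(rng.integers(0, len(uniq_h)))
            order = np.argsort(
                (np.searchsorted(uniq_h, households) - offset) % len(uniq_h),
                kind="stable",
            )
            for i in candidates[order]:
                if enrolled >= design.cluster_size:
                    break
                mask[i] = True
                enrolled += 1
                records.append(
                    _enrol_person(pop, psu, int(i), cluster_id, rng)
                )
        if enrolled < design.cluster_size:
            raise SimulationError(
                f"population exhausted: cluster {cluster_id} enrolled "
                f"{enrolled}/{design.cluster_size}"
            )

    n_examined = sum(1 for r in records if r.examined)
    metadata = SurveyMetadata(
        year=metadata_year,
        location_name="synthetic",
        sample_size=len(records),
        response_rate=n_examined / len(records) if records else None,
        clusters=tuple(cluster_ids),
    )
    return Dataset(records=records, metadata=metadata)


def _enrol_person(
    pop: Population,
    psu: PsuPopulation,
    i: int,
    cluster_id: str,
    rng: np.random.Generator,
) -> ParticipantRecord:
    cfg = pop.cfg
    age = int(psu.age[i])
    gender = Gender.MALE if psu.gender[i] == 0 else Gender.FEMALE
    pid = f"{psu.psu_id}-{i:05d}-{cluster_id}"

    available = rng.random() < _availability_prob(cfg, age)
    if not available:
        available = rng.random() < cfg.mopup_recovery  # mop-up revisit
    if not available:
        return ParticipantRecord(
            participant_id=pid,
            cluster_id=cluster_id,
            age=age,
            gender=gender,
            exam_status=ExamStatus.UNAVAILABLE,
        )
    if cfg.refusal > 0 and rng.random() < cfg.refusal:
        return ParticipantRecord(
            participant_id=pid,
            cluster_id=cluster_id,
            age=age,
            gender=gender,
            exam_status=ExamStatus.REFUSED,
        )

    state = int(psu.state[i])
    right, left, wears, spec_age, followup = _person_exam(
        state, int(psu.aux1[i]), int(psu.aux2[i])
    )
    record = ParticipantRecord(
        participant_id=pid,
        cluster_id=cluster_id,
        age=age,
        gender=gender,
        exam_status=ExamStatus.EXAMINED,
        wears_distance_correction=wears,
        spectacle_age=spec_age,
        right_eye=right,
        left_eye=left,
        surgery_followup=followup,
    )
    record = derive_record(record)
    # barrier answers for anyone with obvious opacity and impaired pinhole
    from .exam import followup_route

    if followup_route(record).barrier_questions:
        n_answers = 1 + int(rng.random() < 0.5)
        picks = rng.choice(len(cfg.barrier_options), size=n_answers, replace=False)
        record.barriers = frozenset(cfg.barrier_options[j] for j in picks)
    return record


def coverage_experiment(
    cfg: SimConfig,
    design: SurveyDesign,
    n_reps: int,
    seed: int,
    n_clusters: int = 40,
) -> dict[str, float]:
    """Replicate the survey many times against one population and measure
    confidence-interval calibration.

    For each replicate a fresh survey is simulated, blindness prevalence is
    estimated with the cluster-ratio SE and a Wald 95% interval, and
    containment of the configured true prevalence is recorded. Also reports
    the mean bias of the crude estimator and the observed design effect
    (mean cluster-variance over the binomial variance at the same size).
    """
    from .estimation import bennett_se, cluster_tallies
    from .exam import ImpairmentCategory, classify_impairment

    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    pop = generate_population(cfg, seed=seed)
    truth = cfg.blindness_prevalence

    def is_blind(r: ParticipantRecord) -> bool:
        better = r.better_eye_presenting()
        return better is not None and classify_impairment(better) is ImpairmentCategory.BLIND

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_reps + 1)[1:] % (2**31)
    covered = 0
    estimates = []
    variances = []
    n_examined = []
    for rep in range(n_reps):
        ds = simulate_survey(pop, design, n_clusters, seed=int(child_seeds[rep]))
        tallies = cluster_tallies(ds, is_blind)
        p, se = bennett_se(tallies)
        lo, hi = max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se)
        if lo <= truth <= hi:
            covered += 1
        estimates.append(p)
        variances.append(se**2)
        n_examined.append(sum(t.n_examined for t in tallies))
    p_bar = float(np.mean(estimates))
    n_bar = float(np.mean(n_examined))
    srs_var = p_bar * (1.0 - p_bar) / n_bar
    return {
        "coverage_pct": 100.0 * covered / n_reps,
        "mean_bias": p_bar - truth,
        "mean_estimate": p_bar,
        "observed_deff": float(np.mean(variances)) / srs_var if srs_var > 0 else float("nan"),
        "n_reps": float(n_reps),
    }
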