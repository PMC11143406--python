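# Methods

This note records the statistical model behind `raabkit`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical choices a maintainer would want written down.

## Survey model

The target population is adults aged 50 and older resident in a survey
area. Sampling is two-stage: census enumeration areas (primary sampling
units, PSUs) are selected with systematic probability-proportional-to-size
on their all-age populations, and within each selected PSU one
population-equal segment is enrolled door-to-door until the cluster size is
reached. Since segment count scales with PSU size, the two stages cancel
and each eligible person has (approximately) the same inclusion
probability; the suite verifies this empirically on uneven frames.

Sample size uses the standard normal-approximation formula
`n = Z²·P(1−P)/h² · DEFF/(1−d)`. Two readings of the precision parameter
are supported because they genuinely coexist in field practice:
`precision_mode="relative"` (default) takes the confidence half-width as
`D·P` — a 20% relative precision on a 2% prevalence is a ±0.4 pp
half-width — while `"absolute"` uses `D` itself, which is the literal
closed form. The 10–30% menu restriction applies to relative precision
only; absolute half-widths accept any value in (0, 1). The design effect
is a lookup by cluster size (35/40 → 1.4, 50 → 1.5, 60 → 1.6), derived
from historical surveys, overridable via `SurveyDesign(deff=...)`.

Segmentation arithmetic: segment size = `round(cluster_size /
proportion_50plus)` all-age persons; a PSU smaller than two target
segments is surveyed whole. The widely quoted "below 500 people, no
segmentation" threshold is the special case of segment size 250.

PPS selection is systematic (cumulative sizes, random start, fixed
interval). Multiple hits are allowed and award a PSU several clusters, so
a PSU spanning k sampling intervals is selected at least k times with
certainty and no separate certainty-selection step is needed.

## Examination decision rules

Acuity grades form a seven-level ordinal scale (6/12 best → NPL worst);
all comparisons are rank-based. Presenting acuity = corrected if the
participant habitually wears distance correction, else uncorrected.
Pinhole is tested only when presenting is worse than 6/12 and better than
light perception; at PL/NPL the pinhole value defaults to presenting.
Impairment categories from better-eye presenting acuity: normal ≥ 6/12;
mild < 6/12 and ≥ 6/18; moderate < 6/18 and ≥ 6/60; severe < 6/60 and
≥ 3/60; blind < 3/60.

Cause assignment is deliberately mechanical where the protocol is
mechanical: a 6/12 eye gets no cause; pinhole improvement to 6/12 forces
refractive error over any examiner-recorded condition; otherwise the
examiner's candidate stands. When the simulator supplies several latent
candidates for one eye, the worse-ranked condition is kept as the
examiner's single main cause — the avoidability hierarchy is defined
across eyes, not within one eye. The person-level principal cause is the
better-ranked (more treatable/preventable) of the two eyes' causes; the
ranking is data (default thirteen conditions, refractive error first),
with removal/insertion hooks for non-endemic or locally common conditions.

Cohen's kappa for training-week inter-observer grading uses the standard
marginal-product chance correction with a pass threshold of 0.6. The
degenerate both-raters-constant-and-identical case is defined as κ = 1
with a warning rather than an error, since in practice it means a
too-easy exercise, not disagreement.

## Estimation

Crude prevalences are cluster-ratio estimates `p = Σaᵢ/Σnᵢ` with
`se = sqrt(Σ(aᵢ − p·nᵢ)²/(c(c−1)))/n̄`; this requires at least two
clusters and is exactly zero when clusters are identical. Confidence
intervals are Wald (`±1.96·se`) truncated to [0, 1]; a transform-based
interval was deliberately not made the default because the plain form is
what field reports print. The suite cross-checks the SE against an
independent delete-one-cluster jackknife (15% relative tolerance on
30-cluster replicates) and against the hand example aᵢ=(2,4,6),
nᵢ=(50,50,50) → se ≈ 0.023094.

Post-stratification reweights the eight strata {50–59, 60–69, 70–79,
≥80} × {male, female} to census counts: `w_h = (N_h/N)/(n_h/n)`. An
unsampled stratum with census population is collapsed into the adjacent
younger age stratum of the same gender (the youngest collapses upward;
a gender with no sample at all falls back to the other gender), which
keeps weights finite and is reported in the output notes. The weighted
estimate's SE uses the delete-one-cluster jackknife because the
cluster-ratio formula applies only to crude ratios. Gender disaggregation
is always produced, each gender post-stratified within its own four age
strata.

Coverage indicators: person-level CSC = (x+y)/(x+y+z) with x bilaterally
operated, y unilaterally operated and z bilaterally operable persons
("operable": obvious lens opacity, cataract as main cause, presenting
worse than a configurable threshold, default 6/12). eCSC keeps operated
persons with presenting ≥ 6/12 in at least one operated eye, so
eCSC ≤ CSC structurally. Eye-level analogues count eyes. Refractive need
is marked by pinhole improvement to 6/12 (refraction is not performed in
a rapid protocol): met = wearer with uncorrected worse than 6/12 restored
to 6/12 presenting; undermet = wearer still below 6/12 presenting but
pinhole-correctable; unmet = non-wearer, pinhole-correctable. Both
thresholds ("operable", "good outcome") are parameters, not constants,
because published operationalizations vary. Empty denominators yield
`None` ("not computable"), never zero.

## Simulator

The generator emulates exactly the structure the estimators assume, which
is its purpose and its limitation. Latent person states are: blind (from
cataract with probability 0.6, else posterior-segment disease), operated
cataract, operable cataract, refractive-error need (met/undermet/unmet),
or normal. Blindness risk varies between PSUs via a beta-distributed base
risk with mean 2% and intracluster correlation mapped from the target
design effect (ICC = (DEFF−1)/(m−1); 1.5 at m = 50 → ICC ≈ 0.0102), and
rises with age through relative risks (0.5, 1, 2, 4 by decade) normalised
so the overall prevalence stays exactly the configured value. All other
states use constant probabilities anchored to disjoint sub-intervals of a
single uniform draw, so their marginal prevalences are exact and the
analytic expectations used in parameter-recovery tests follow directly
from the config (e.g. expected CSC = p_op/(p_op + p_opc + 0.6·p_blind)).

Default rates — blindness 2%, operated cataract 5% (half bilateral;
per-eye outcomes 60% good / 25% borderline / 15% poor), operable cataract
4%, refractive-error need 15% (40% met / 20% undermet / 40% unmet),
availability 0.9 with mop-up recovery 0.5 (expected response rate 0.95),
1% institutionalized — are typical of published surveys in low- and
middle-income settings and are fixed as the package's study conditions.
Age structure among 50+ defaults to 45/30/17/8% by decade, split evenly
by gender.

Households are contiguous runs of eligible persons with Poisson-distributed
sizes (mean 1.6, truncated at 1); the "random corner" start of the
door-to-door walk is a random rotation of the household order — geometry
is not modelled because under exchangeable households it has no
statistical effect. A segment that runs out of eligible people spills into
the rest of the PSU and then the next unit in frame order, emulating
"continue in the nearest population unit". Persons are stored as per-PSU
column arrays and materialised into participant records only on enrolment,
which keeps a 500-replicate experiment cheap.

What the simulator does **not** emulate: spatial clustering within
segments, migration, measurement error in acuity testing, examiner
misclassification of causes, correlated availability within households,
and multimorbidity (one latent state per person). Passing tests therefore
demonstrate that the pipeline is internally consistent and statistically
calibrated under the design's own assumptions — not that field data meet
those assumptions.

## Confidence-interval calibration

`coverage_experiment` generates one population, replicates the whole
survey (selection, walk, non-response, estimation) and scores Wald-interval
containment of the true 2% prevalence. The population pool is set to 400
PSUs in the shipped experiment so that the single realized population's
prevalence sits within ~0.07 pp of nominal and replicates measure the
estimator, not one population draw. Observed coverage is 93–94%: the
cluster-ratio SE is empirically unbiased (checked against the replicate
SD), and the shortfall from 95% is the known anti-conservatism of a
symmetric Wald interval for a skewed small-proportion estimate (~40 cases
per survey). The observed design effect lands slightly below the 1.5 used
in the ICC mapping because age-driven risk variation adds within-cluster
heterogeneity.

## Numerical and interface choices

- Acuity tokens `6/12 … 1/60, PL, NPL`; missing optional CSV fields are
  empty strings, never sentinel numbers; round-trip on canonical files is
  byte-identical.
- Validation never raises on content — every protocol violation becomes a
  flag from a closed rule set; flags deduplicate as (participant, rule)
  pairs and are deterministically ordered.
- All randomness flows through `numpy.random.Generator` objects or integer
  seeds; replicate seeds are spawned from a root `SeedSequence` and kept
  below 2³¹.
- Reports render as markdown plus a JSON twin with identical numeric
  content; not-computable indicators are rendered explicitly. Percentages
  print to one decimal.
- The CLI (`raab`) is a thin wrapper: every verb is one library call plus
  file I/O.

## Known limitations

- The participant CSV dialect is a documented stand-in: deployed survey
  platforms use their own variable schemas, hence the configurable
  column-name mapping.
- Wald intervals undercover slightly at low prevalence (see above); a
  transform-based interval would trade that for asymmetry and is left as
  future configuration.
- The barrier-options list and cause ranking ship as editable defaults;
  surveys are expected to localise both.
- Eye-level refractive-error coverage is not produced (person-level,
  better-eye basis only), matching how the indicator is reported in
  practice.
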