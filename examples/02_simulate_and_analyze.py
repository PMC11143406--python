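"""Simulate a full survey and estimate the priority indicators.

Generates a synthetic population (2% blindness with between-cluster
heterogeneity, cataract surgical histories, refractive-error need), runs a
40-cluster survey of 50 participants each, and estimates blindness
prevalence, cataract surgical coverage and refractive error coverage.
"""

from raabkit import (
    ImpairmentCategory,
    SurveyDesign,
    cataract_coverage,
    estimate_prevalence,
    refractive_coverage,
    response_rate,
)
from raabkit.simulate import SimConfig, generate_population, simulate_survey

cfg = SimConfig(n_psus=120)
pop = generate_population(cfg, seed=1)
design = SurveyDesign(prevalence=cfg.blindness_prevalence, cluster_size=50)
ds = simulate_survey(pop, design, n_clusters=40, seed=2)

print(f"enrolled {len(ds.records)}, response rate {response_rate(ds):.3f}")

res = estimate_prevalence(ds, ImpairmentCategory.BLIND, pop.census())
lo, hi = res.ci95
print(f"blindness: crude {100 * res.crude:.2f}% "
      f"(95% CI {100 * lo:.2f}-{100 * hi:.2f}%), "
      f"age-gender weighted {100 * res.weighted:.2f}%")
# The weighted value post-stratifies to the population's true age-gender
# counts; the CI uses the cluster-ratio SE, not the binomial one.

cat = cataract_coverage(ds)
print(f"CSC  (persons): {100 * cat.csc_person:.1f}%  "
      f"eCSC (persons): {100 * cat.ecsc_person:.1f}%")
ref = refractive_coverage(ds)
print(f"REC: {100 * ref.rec:.1f}%  eREC: {100 * ref.erec:.1f}%  "
      f"(need n={ref.components.denominator})")
# eCSC/eREC demand a good presenting-vision outcome on top of having been
# treated, so they are always <= CSC/REC; the gap is the quality gap.
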