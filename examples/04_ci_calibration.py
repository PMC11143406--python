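"""Check confidence-interval calibration by replicated simulation.

If the survey were repeated many times in the same population, about 95 of
every 100 computed intervals should contain the true prevalence. This runs
a reduced replicate count for speed; the acceptance script runs 500.
"""

from raabkit import SurveyDesign
from raabkit.simulate import SimConfig, coverage_experiment

cfg = SimConfig(n_psus=400)  # ICC default maps from DEFF 1.5 at cluster size 50
design = SurveyDesign(prevalence=0.02, cluster_size=50)

out = coverage_experiment(cfg, design, n_reps=200, seed=1, n_clusters=40)
print(f"replicates          : {out['n_reps']:.0f}")
print(f"95%-CI coverage     : {out['coverage_pct']:.1f}%")
print(f"mean estimate       : {100 * out['mean_estimate']:.2f}% (truth 2.00%)")
print(f"mean bias           : {out['mean_bias']:+.5f}")
print(f"observed design effect: {out['observed_deff']:.2f}")
# Coverage lands a little under 95%: the symmetric Wald interval is slightly
# anti-conservative for a 2% prevalence estimated from ~40 cases.
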