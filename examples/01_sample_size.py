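"""Plan a survey: sample size and segmentation arithmetic.

A survey anticipating 2% blindness among people 50+, wanting 20% relative
precision at 95% confidence, expecting 10% non-response and using clusters
of 50 (design effect 1.5).
"""

import numpy as np

from raabkit import SurveyDesign, compute_sample_size, plan_segmentation

design = SurveyDesign(
    prevalence=0.02, precision=0.20, nonresponse=0.10, cluster_size=50
)
res = compute_sample_size(design)
print(f"raw sample size     : {res.n_raw:.1f}")
print(f"clusters of {design.cluster_size}      : {res.n_clusters}")
print(f"recruited persons   : {res.n_individuals}")
print(f"design effect used  : {res.deff_used}")
# The raw size is rounded up to whole clusters: one field team completes one
# cluster per day, so the recruited size is clusters x cluster size.

plan = plan_segmentation(
    psu_population=1000, proportion_50plus=0.20, cluster_size=50,
    rng=np.random.default_rng(1),
)
print(f"\nsegment size (all ages): {plan.segment_size}")
print(f"segments in a PSU of 1000: {plan.n_segments}, chosen: {plan.chosen_segment}")
# With 20% of people aged 50+, a segment of 250 people of all ages yields
# one cluster of 50 eligible adults; a PSU of 1000 gives four segments.
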