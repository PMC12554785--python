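"""Seed-based structural covariance and its group difference.

Uses the left pallidum as seed and tests, per target parcel, whether the
seed-target covariance slope differs between patients and controls
(seed x group interaction).  The generator plants a control slope of 0.8
to the left precentral gyrus that is absent in patients, so PreCG.L should
show a negative interaction z.
"""

from morphnet.scn import covariance_group_difference, seed_covariance
from morphnet.synthetic import GroundTruth, gen_gmv_parcels, gen_subject_table

truth = GroundTruth.paper_like(seed=1)
subjects = gen_subject_table(61, 61, seed=1)
gmv = gen_gmv_parcels(subjects, truth)

within = seed_covariance(gmv, "PAL.L", subjects, group="control")
print("control-group covariance of PAL.L with PreCG.L: "
      f"slope {within.loc['PreCG.L', 'slope']:.3f}, "
      f"r {within.loc['PreCG.L', 'r']:.3f}")

diff = covariance_group_difference(gmv, "PAL.L", subjects)
print("\nseed x group interaction (negative z = patient covariance lower):")
print(diff.round(4).to_string())
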