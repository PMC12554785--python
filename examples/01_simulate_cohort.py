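"""Generate a synthetic patient/control cohort with planted structure.

Builds the default study conditions (61 tremor-dominant patients, 61
controls) with planted precuneus/fusiform atrophy, a group-dependent
pallidum-precentral covariance slope and a pallidum -> precuneus ->
temporal causal chain, then prints what was planted.
"""

from morphnet.synthetic import GroundTruth, gen_gmv_parcels, gen_subject_table

truth = GroundTruth.paper_like(seed=1)
subjects = gen_subject_table(61, 61, seed=1)
gmv = gen_gmv_parcels(subjects, truth)

print(f"cohort: {len(subjects)} subjects "
      f"({(subjects['group'] == 'patient').sum()} patients)")
print(f"patient disease duration: mean {subjects['duration'].mean():.2f} y, "
      f"sd {subjects['duration'].std():.2f} y")
print(f"GMV matrix: {gmv.shape[0]} subjects x {gmv.shape[1]} parcels")
print("planted atrophy (sd units):", truth.atrophy_effects)
print("planted causal chain:", truth.causal_edges)
# The atrophy map and the causal chain are what the morphometry and
# pseudotime-causality stages are expected to recover from these data.
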