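"""Three-step predictor reduction on a synthetic study, plus the power check.

Step 1 keeps driver-gene alterations, step 2 drops low-variance ones
(threshold 0.05 x 0.95 = 0.0475), step 3 collapses redundancy clusters at
|r| >= 0.95 to their first member.
"""

from pharmforest import min_frequency_for_power, power_of_frequency, reduce_predictors
from pharmforest.synthetic import demo_config, driver_gene_set, make_study

study, truth = make_study(demo_config(), seed=0)
res = reduce_predictors(study.alterations, driver_gene_set(truth))

print(f"alterations in:      {study.alterations.n_alterations}")
print(f"after driver filter: {res.step1_kept}")
print(f"variance-excluded:   {res.step2_excluded}  (threshold {res.variance_threshold})")
print(f"clusters found:      {res.clusters.n_clusters}  "
      f"({(res.clusters.sizes == 1).sum()} singletons, cut height {res.distance_threshold})")
print(f"predictors entering the forests: {res.retained.n_alterations}")

# why 0.05 is a defensible minimum frequency at the screens' average n:
n = 523
print(f"\nt-test power at frequency 0.05, n={n}, d=0.5: {power_of_frequency(0.05, n):.3f}")
print(f"smallest frequency reaching power 0.80:      {min_frequency_for_power(0.80, n):.3f}")
# Prints ~0.70 and 0.065: alterations rarer than ~6.5% are underpowered even
# before the forest sees them, which motivates the variance filter.
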