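"""Reduction due to drought (RDD) and soil-moisture conversion.

Compares each trait's mean under normal irrigation and drought within one
season, and converts a gravimetric soil-moisture reading to volumetric.
"""

import wheatqg as w

obs = w.simulate_trial(w.example_design(200), w.example_truth(), seed=1)
table = w.rdd_table(
    w.genotype_means(obs, "N2020"), w.genotype_means(obs, "D2020")
)
print("per-trait RDD (% of the normal-condition mean):")
for trait, value in table.rdd_of_means.items():
    print(f"  {trait}: {value:.1f}%")
# Positive RDD = the trait dropped under drought; peduncle weight (PW)
# loses the most, spikelet number (NSPS) the least, matching the expected
# stress ranking of these traits.

theta_g = 20.0  # gravimetric moisture, mass %
vol = w.gravimetric_to_volumetric(theta_g, bulk_density=1.2)
print(f"gravimetric {theta_g}% x bulk density 1.2 g/cm^3 = {vol}% volumetric")
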