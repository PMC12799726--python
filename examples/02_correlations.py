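"""Phenotypic vs genotypic trait correlations under drought.

Computes entry-mean (phenotypic) and mean-cross-product (genotypic)
correlations among spike and peduncle traits in one drought environment.
"""

import wheatqg as w

obs = w.simulate_trial(w.example_design(200), w.example_truth(), seed=1)
env = "D2020"

means = w.genotype_means(obs, env)
rp = w.phenotypic_correlation(means)
G, P = w.genetic_covariance(obs, env)
rg = w.genotypic_correlation(G)

pair = ("PD", "GYPS")
print(f"environment {env}, {len(means)} genotypes")
print(f"phenotypic r({pair[0]}, {pair[1]}) = {rp.r.loc[pair]:.3f}"
      f"{w.significance_stars(rp.p.loc[pair])}")
print(f"genotypic  r({pair[0]}, {pair[1]}) = {rg.r.loc[pair]:.3f}")
# The genotypic correlation exceeds the phenotypic one: plot-level noise
# attenuates the phenotypic estimate, while the genotypic estimate removes
# the residual cross product. A positive PD-GYPS correlation means
# thicker-peduncled genotypes yield more per spike under drought.
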