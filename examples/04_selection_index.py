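"""Smith-Hazel indices and drought-tolerant genotype selection.

Builds the spike index (SI) from GYPS/GNPS/NSPS and the peduncle index
(PI) from PW/PD in each drought environment, combines them into the
standardised drought index DI, and intersects the per-year top-20 sets.
"""

import numpy as np
import wheatqg as w

obs = w.simulate_trial(w.example_design(200), w.example_truth(), seed=1)
spike, peduncle = ["GYPS", "GNPS", "NSPS"], ["PW", "PD"]

selections = {}
for year in ("2020", "2021"):
    env = f"D{year}"
    means = w.genotype_means(obs, env)
    G_s, P_s = w.genetic_covariance(obs, env, spike)
    b_s = w.smith_hazel_coefficients(P_s, G_s, np.ones(3))
    si = w.index_values(b_s, means[spike])
    G_p, P_p = w.genetic_covariance(obs, env, peduncle)
    b_p = w.smith_hazel_coefficients(P_p, G_p, np.ones(2))
    pi = w.index_values(b_p, means[peduncle])
    result = w.drought_index(si, pi, year=year)
    outcome = w.select_extremes(result.di, k=20, year=year)
    selections[year] = outcome
    print(f"{env}: b_spike = {np.round(b_s, 3)}, top genotype {outcome.top[0]} "
          f"(DI = {result.di[outcome.top[0]]:.2f})")

common = w.intersect_years({y: s.top for y, s in selections.items()})
print(f"genotypes in the top 20 of both drought seasons: {len(common.common)}")
# The index coefficients b solve P b = G w, weighting each trait by how
# heritable and how correlated with the others it is; genotypes that stay
# in the top set across both years are the stable drought-tolerance picks.
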