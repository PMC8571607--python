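"""Species-richness estimation and rarefaction for a survey design.

Simulates a samples x species incidence matrix with many rare species
(the usual shape of arthropod community surveys) and compares the
nonparametric richness estimators against the true pool size.
"""

import numpy as np

from endosym.richness import (
    AbundanceVector,
    IncidenceMatrix,
    ace,
    chao1,
    chao2,
    ice,
    jackknife,
    rarefaction,
)

rng = np.random.default_rng(8)
true_species = 120
n_samples = 20
# log-series-like abundances: a few common species, many rare ones
weights = 1 / np.arange(1, true_species + 1) ** 1.1
counts = rng.multinomial(40, weights / weights.sum(), size=n_samples)
inc = IncidenceMatrix((counts > 0).astype(int))
abund = AbundanceVector(counts.sum(axis=0))

print(f"true pool:  {true_species} species")
print(f"observed:   {abund.s_obs}")
print(f"Chao1: {chao1(abund):6.1f}   ACE: {ace(abund):6.1f}")
print(f"Chao2: {chao2(inc):6.1f}   ICE: {ice(inc):6.1f}")
print(f"Jack1: {jackknife(inc, 1):6.1f}   Jack2: {jackknife(inc, 2):6.1f}")
print("rarefaction:", [round(rarefaction(inc, t), 1)
                       for t in (1, 5, 10, 15, 20)])
# The estimators extrapolate from singletons/uniques; all should land
# between S_obs and the true pool, and the rarefaction curve's failure
# to plateau shows the survey is not yet exhaustive.
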