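"""Reproduce the bookkeeping of the packaged soil-arthropod survey.

The package ships the survey's 36 host-Wolbachia strain profiles and the
screening counts over 390 morphospecies; this script recomputes the
diversity and incidence summaries from those tables.
"""

from endosym import load_fixtures
from endosym.fixtures import load_screening_table
from endosym.mlst import diversity_summary, incidence_summary
from endosym.recomb import shared_st_screen

fx = load_fixtures()
div = diversity_summary(fx.profiles)
print(f"distinct alleles: {div.unique_alleles_total} "
      f"of {div.max_allele_slots} possible")
print(f"distinct STs:     {div.unique_st_count} among {len(fx.profiles)} "
      f"host-symbiont combinations")
print(f"STs per clade:    {div.per_supergroup_st_counts}")

scr = incidence_summary(load_screening_table())
for symbiont, pct in scr.incidence_percent.items():
    print(f"{symbiont:13s} {scr.infected_counts[symbiont]:3d}/"
          f"{scr.n_screened} infected ({pct}%)")

shared = shared_st_screen(fx.profiles, min_rank_distance="order")
print("STs shared across host orders:", [st for st, _ in shared])
# An identical five-locus strain in hosts from different orders is the
# classic signature of recent whole-strain horizontal transfer.
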