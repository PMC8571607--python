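"""Type a simulated community: alleles, sequence types, diversity.

Every distinct sequence at a locus receives the next free allele number;
a sequence type (ST) is a unique five-allele combination.  Shared STs
across hosts indicate whole-strain horizontal transfer.
"""

from endosym import SimulationConfig, simulate_transmission
from endosym.mlst import (
    AlleleCatalog,
    LocusDef,
    assign_alleles,
    assign_sts,
    diversity_summary,
)

dataset = simulate_transmission(
    SimulationConfig(n_hosts=15, h_within=0.5, seed=7)
)
cfg = dataset.config
scheme = [
    LocusDef(name, length, i)
    for i, (name, length) in enumerate(zip(cfg.locus_names, cfg.locus_lengths))
]
per_locus = {
    locus: dataset.host_locus_seqs(locus) for locus in cfg.locus_names
}
catalog = AlleleCatalog([d.name for d in scheme])
profiles = assign_sts(assign_alleles(per_locus, catalog, scheme), scheme=scheme)

div = diversity_summary(profiles, scheme)
print(f"hosts typed:        {len(profiles)}")
print(f"unique alleles:     {div.unique_alleles_total} "
      f"of {div.max_allele_slots} slots")
print(f"unique STs:         {div.unique_st_count}")
print(f"per locus:          {div.per_locus_unique_alleles}")
# unique alleles well below the slot count means hosts share alleles —
# with h_within > 0 entire strains (and so their STs) recur across hosts.
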