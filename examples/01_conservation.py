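"""Map binding sites onto alignment blocks and score their conservation.

Generates a small synthetic whole-genome alignment (46 species: a
high-retention mammal-like clade and a low-retention lower-vertebrate
clade), places 20 bp binding sites for a handful of RBPs, and computes
each site's conservation percent P = (N / 46) x 100, where N is the
number of species in the site's alignment block.
"""

import numpy as np

from rbpcons import SyntheticScenario, index_blocks, profile_rbp, species_presence_matrix
from rbpcons.synthetic import simulate_maf, simulate_sites

scenario = SyntheticScenario(
    chrom_lengths={"chr1": 100_000}, n_rbps=4, sites_per_rbp=300, seed=7
)
blocks, truth = simulate_maf(scenario)
beds, _ = simulate_sites(scenario, blocks, block_truth=truth)
index = index_blocks(blocks)

profiles = []
print(f"{len(blocks)} alignment blocks, {scenario.total_species} species\n")
for rbp, sites in beds.items():
    profile = profile_rbp(sites, index, scenario.total_species, rbp_name=rbp)
    profiles.append(profile)
    print(
        f"{rbp}: {profile.n_mapped} sites mapped, {profile.n_unmapped} unmapped "
        f"(straddle block boundaries), median P = {profile.median():.1f}%"
    )

matrix = species_presence_matrix(profiles)
mammal_cols = [c for c in matrix.columns if c.startswith("mam")]
lower_cols = [c for c in matrix.columns if c.startswith("low")]
print(
    f"\nmean per-species presence: mammal-like clade "
    f"{matrix[mammal_cols].to_numpy().mean():.1f}%, "
    f"lower-vertebrate clade {matrix[lower_cols].to_numpy().mean():.1f}%"
)
print(
    "-> the median P near 76% reflects the planted clade retention "
    "(0.9 for 36 mammal-like species, 0.2 for 9 lower vertebrates); "
    "the ~10% unmapped sites were planted across block boundaries."
)
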