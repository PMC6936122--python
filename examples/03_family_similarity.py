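"""Binding-profile similarity within an RBP family vs tree distance.

For each RBP pair, SS = 2*NBS / (N1 + N2) counts binding sites
conserved in the same percentage of species; patristic distances come
from a Newick tree. A chi-square independence test on quantile-binned
pairs asks whether closely related RBPs have more similar conservation
profiles.
"""

import io

import numpy as np

from rbpcons import index_blocks, profile_rbp, read_newick
from rbpcons.family import association_test, family_pairs
from rbpcons.synthetic import (
    SyntheticScenario,
    simulate_family_tree,
    simulate_maf,
    simulate_sites,
)

scenario = SyntheticScenario(
    chrom_lengths={"chr1": 80_000}, n_rbps=6, sites_per_rbp=200, seed=13
)
blocks, truth = simulate_maf(scenario)
beds, _ = simulate_sites(scenario, blocks, block_truth=truth)
index = index_blocks(blocks)
profiles = {
    rbp: profile_rbp(s, index, scenario.total_species, rbp)
    for rbp, s in beds.items()
}

members = list(profiles)
newick = simulate_family_tree(members, seed=3)
tree = read_newick(io.StringIO(newick))
pairs = family_pairs(profiles, tree, members=members)

print("pair            NBS   N1   N2     SS   evo_dist")
for p in pairs[:6]:
    print(
        f"{p.rbp1}-{p.rbp2}  {p.nbs:4d} {p.n1:4d} {p.n2:4d} "
        f"{p.ss:6.3f} {p.evo_dist:8.3f}"
    )

chi2, dof, pval = association_test(pairs, n_bins=2)
print(f"\nchi-square independence test: chi2 = {chi2:.2f}, dof = {dof}, p = {pval:.3f}")
print(
    "-> sites here land in blocks independently of the family tree, so "
    "SS and evolutionary distance should show no association (p > 0.05)."
)
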