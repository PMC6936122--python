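"""Compare binding-site conservation against random genomic regions.

Plants binding sites in high-retention alignment blocks (emulating
selection on functional sites) and draws random 20 bp genomic regions
as the null; the rank-sum test quantifies the separation.
"""

import numpy as np

from rbpcons import index_blocks, profile_rbp, compare_groups
from rbpcons.random_regions import AnnotationSpace, null_profile, sample_regions
from rbpcons.synthetic import CladeSpec, SyntheticScenario, simulate_maf, simulate_sites

scenario = SyntheticScenario(
    chrom_lengths={"chr1": 120_000},
    clades=[
        CladeSpec("mammal", tuple(f"mam{i:02d}" for i in range(1, 37)), 0.45),
        CladeSpec("lower_vertebrate", tuple(f"low{i:02d}" for i in range(1, 10)), 0.1),
    ],
    block_classes={"background": (0.7, 1.0), "target": (0.3, 1.8)},
    site_block_class="target",
    n_rbps=2, sites_per_rbp=400, unmappable_fraction=0.0, seed=11,
)
blocks, truth = simulate_maf(scenario)
beds, _ = simulate_sites(scenario, blocks, block_truth=truth)
index = index_blocks(blocks)

site_p = np.concatenate(
    [
        profile_rbp(s, index, scenario.total_species, r).percents()
        for r, s in beds.items()
    ]
)

space = AnnotationSpace.whole_genome(scenario.chrom_lengths)
nulls = sample_regions(space, count=800, length=20, seed=5)
null_p = profile_rbp(nulls, index, scenario.total_species, "null").percents()

_, p = compare_groups(site_p, null_p)
print(f"binding sites: median P = {np.median(site_p):.1f}% (n={site_p.size})")
print(f"random genomic regions: median P = {np.median(null_p):.1f}% (n={null_p.size})")
print(f"rank-sum p = {p:.3g}")

_, agreement = null_profile(space, 400, 20, 5, 100, index, scenario.total_species)
print(
    f"null replicate agreement: min pairwise rank-sum p = "
    f"{agreement['min_pairwise_p']:.3f} over 5 replicates"
)
print(
    "-> sites planted in boosted-retention blocks are substantially more "
    "conserved than the genomic null; replicate nulls are interchangeable."
)
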