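"""Score-weighted permutation gene-set enrichment.

Gene scores are median conservation percents of each gene's binding
sites. One gene set is planted with a +30 score shift among nine random
sets; the permutation Mann-Whitney test with the corrected p-value
max(1 - #sign/#total, 1/#total) singles it out.
"""

import numpy as np

from rbpcons.enrichment import GeneScoreTable, enrich_collection, results_to_frame
from rbpcons.synthetic import SyntheticScenario, simulate_gene_sets

rng = np.random.default_rng(0)
scores = GeneScoreTable(
    {f"GENE{i}": float(s) for i, s in enumerate(rng.normal(50, 10, 1000))}
)

scenario = SyntheticScenario(
    n_rbps=10, sites_per_rbp=1,
    planted_gene_set=("planted_set", 30.0), n_gene_sets=10, gene_set_size=30,
    seed=9,
)
sets, shifted, planted = simulate_gene_sets(scores, scenario)
results = enrich_collection(shifted, sets, n_perm=1000, seed=42)

print(results_to_frame(results).to_string(index=False))
print(
    f"\n-> the planted set ('{planted}', +30 score shift) reaches the "
    "corrected-p floor of 1/1000 = 0.001; unshifted random sets sit near 1."
)
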