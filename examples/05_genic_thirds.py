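"""Compare binding-site conservation across strand-aware gene thirds.

Each gene is cut into 5', middle and 3' segments in the direction of
transcription; sites are assigned by midpoint. Here a 3' > middle > 5'
conservation gradient is planted and recovered via pairwise rank-sum
tests.
"""

from rbpcons.genic import region_comparison, segment_gene
from rbpcons.io import GeneModel
from rbpcons.synthetic import simulate_positional_effect

minus_gene = GeneModel("G1", "G1", "chr1", 0, 300, "-")
seg = segment_gene(minus_gene)
print(
    f"'-' strand gene [0,300): 5' = [{seg.five_prime.start},{seg.five_prime.end}), "
    f"middle = [{seg.middle.start},{seg.middle.end}), "
    f"3' = [{seg.three_prime.start},{seg.three_prime.end})"
)

assignments = simulate_positional_effect(
    n_rbps=10, sites_per_region=50,
    region_means={"5prime": 40.0, "middle": 55.0, "3prime": 70.0},
    sd=5.0, seed=17,
)
medians, tests, summary = region_comparison(assignments)

print("\nmedian conservation percent by region (first 3 RBPs):")
print(medians[medians.rbp.isin(["RBP01", "RBP02", "RBP03"])].to_string(index=False))
print(
    f"\nRBPs with significantly higher 3' than 5' conservation: "
    f"{summary['n_3prime_gt_5prime']}/{summary['n_tested']}"
)
print(
    "-> the planted 30-point 3'-vs-5' gap is detected for every RBP; "
    "on '-' strand genes the 5' third sits at the higher genomic coordinates."
)
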