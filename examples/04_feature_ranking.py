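"""Rank RBP-centric features by their influence on conservation.

Builds a 60-RBP feature table (tissue-specificity, site counts,
expression levels, interaction counts, ...) whose response — median
binding-site conservation — depends on one planted feature, then runs
RReliefF and the simple site-count regression.
"""

from rbpcons.relieff import RbpFeatureTable, regress_response_on_feature, rrelieff, shuffle_robustness
from rbpcons.synthetic import SyntheticScenario, simulate_feature_table

scenario = SyntheticScenario(n_rbps=60, seed=21)
frame, planted = simulate_feature_table(scenario)
table = RbpFeatureTable(frame)

weights = rrelieff(table, k=10, m="all", sigma=20.0)
print(f"planted informative feature: {planted}\n")
print("rank  weight    feature")
for i, feat in enumerate(weights.rank, start=1):
    print(f"{i:4d}  {weights.weights[feat]: .4f}  {feat}")

slope, intercept, pval = regress_response_on_feature(table, planted)
print(f"\nOLS: response ~ {planted}: slope = {slope:.3f}, p = {pval:.3g}")

report = shuffle_robustness(table, k=10, m="all", n_shuffles=20, seed=1)
row = report.set_index("feature").loc[planted]
print(
    f"shuffling {planted}: rank {int(row.original_rank)} -> "
    f"median {row.median_shuffled_rank:.0f} of {len(weights.rank)}"
)
print(
    "-> the planted feature tops the RReliefF ranking and carries a negative "
    "regression slope (more sites, less conservation); once shuffled it is "
    "indistinguishable from the ten noise columns and falls out of the top."
)
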