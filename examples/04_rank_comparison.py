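"""Friedman/Nemenyi rank comparison of classifiers across datasets.

Takes a methods x datasets MCC table (here: published benchmark values for
four rebalancing methods on ten datasets), computes each method's mean rank
(k = best), the Friedman test of the hypothesis that all methods perform
alike, and the Nemenyi critical difference that a pair of mean ranks must
exceed to differ significantly at alpha = 0.05.
"""

import numpy as np

from kboost import pairwise_nemenyi

methods = ["K-Boosted trees", "SMOTEBoost", "RUSBoost", "SMOTE+boosted"]
mcc_table = np.array([
    [0.299, 0.454, 0.446, 0.712, 0.194, 0.380, 0.625, 0.898, 0.855, 0.280],
    [0.264, 0.432, 0.397, 0.590, 0.054, 0.317, 0.502, 0.497, 0.836, 0.232],
    [0.150, 0.446, 0.340, 0.577, 0.171, 0.152, 0.490, 0.552, 0.824, 0.270],
    [0.232, 0.425, 0.377, 0.691, 0.137, 0.232, 0.593, 0.450, 0.821, 0.195],
])

res = pairwise_nemenyi(mcc_table, alpha=0.05, method_names=methods)
for name, rank in zip(methods, res.mean_ranks):
    print(f"{name:>16s}: mean rank {rank:.3f}")
print(f"Friedman chi2 = {res.friedman_statistic:.3f}, p = {res.p_value:.2e}")
print(f"Nemenyi CD (k=4, n=10, alpha=0.05) = {res.nemenyi_cd:.3f}")
sig = res.significant_pairs()
for i in range(4):
    for j in range(i + 1, 4):
        if sig[i, j]:
            print(f"significant: {methods[i]} vs {methods[j]} "
                  f"(gap {abs(res.mean_ranks[i]-res.mean_ranks[j]):.2f} > CD)")
# a mean rank of 4.0 means best on every one of the ten datasets; pairs whose
# mean-rank gap exceeds the CD differ significantly under the Nemenyi test.
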