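"""Cluster deployments by environment and compare detections across groups.

Deployments are clustered on their mean SST, chlorophyll and daylength by
HCPC (PCA → Ward dendrogram → k-means consolidation); detection counts are
then compared across deployments, months and clusters with tie-corrected
Kruskal–Wallis tests and Nemenyi all-pairs post-hocs (the counts are far
from normal, so rank tests are the appropriate tool).
"""

import pandas as pd

import whistlegam as wg

_, _, _, records = wg.simulate_study(seed=1)
frame = wg.records_to_frame(records)

env = frame.groupby("deployment_id")[["sst", "chl", "daylength"]].mean()
pca, assign = wg.hcpc(env)
print(f"PCA: {pca.n_retained} components retained "
      f"({100 * pca.cumulative[pca.n_retained - 1]:.1f}% of variance)")
print(f"k = {assign.k} clusters, sizes: "
      f"{assign.labels.value_counts().sort_index().to_dict()}")

frame["cluster"] = frame["deployment_id"].map(assign.labels)
checks = wg.check_distributions(frame["dp10m"].to_numpy(),
                                frame["deployment_id"].to_numpy())
print(f"\nAnderson-Darling normality p = {checks['ad_p']:.2e}, "
      f"Levene p = {checks['levene_p']:.2e}  -> rank tests")

for grouping in ("deployment_id", "cluster"):
    r = wg.kruskal_nemenyi(frame["dp10m"].to_numpy(), frame[grouping].to_numpy(),
                           grouping_name=grouping)
    print(f"Kruskal-Wallis by {grouping}: Chi2 = {r.chi2:.1f} "
          f"(df = {r.df}, p = {r.p:.2e})")
print("\nNemenyi all-pairs p-values between clusters:")
r = wg.kruskal_nemenyi(frame["dp10m"].to_numpy(), frame["cluster"].to_numpy())
print(r.nemenyi_p.round(4).to_string())
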