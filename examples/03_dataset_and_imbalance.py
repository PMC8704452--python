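"""Bipartite dataset assembly and the class-imbalance problem.

Every known interacting (target, drug) pair is a positive; every other
grid pair is a negative. The sample ratio (negatives/positives) shows why
rebalancing is needed before classification.
"""

from dtipred import generate_fixture, pair_features, sample_ratio
from dtipred.reduce_balance import BalanceConfig, smote_balance

ds = generate_fixture(n_targets=8, n_drugs=12, n_positives=12, seed=7)
print(f"{len(ds.targets)} targets x {len(ds.drugs)} drugs = {ds.n_pairs} pairs; "
      f"{ds.n_positives} positives, {ds.n_negatives} negatives")
print(f"sample ratio (neg/pos): {sample_ratio(ds):.2f}")

table = pair_features(ds)
print(f"fused pair features: {table.n_features} "
      f"(80 PsePSSM + 190 DCCA + 256 fingerprint)")

balanced = smote_balance(table, BalanceConfig(perc_over=500, perc_under=120,
                                              k_neighbors=5, seed=0))
n_pos = int((balanced.labels == 1).sum())
n_neg = int((balanced.labels == 0).sum())
n_syn = int((balanced.provenance == "synthetic").sum())
print(f"after SMOTE(500,120,5): {n_pos} positives ({n_syn} synthetic) "
      f"vs {n_neg} negatives")
# perc_over=500 creates 5 interpolated positives per real one; perc_under=120
# keeps 1.2x that many negatives, giving an exactly balanced table.
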