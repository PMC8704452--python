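"""Ranked inference of candidate interactions.

Trains on every known pair of a dataset and scores a query grid, reporting
pairs whose predicted interaction probability exceeds 0.5, best first.
"""

from dtipred.dataset import build_dataset, generate_raw_fixture
from dtipred.pipeline import PipelineConfig, predict_new
from dtipred.classify_eval import ForestConfig

bundle = generate_raw_fixture(n_targets=8, n_drugs=12, n_positives=16,
                              signal_strength=5.0, seed=3)
train = build_dataset(bundle)
config = PipelineConfig(forest=ForestConfig(n_trees=100),
                        lasso_grid=(0.1, 1.0, 10.0), seed=1)

# query the training grid itself: known positives should top the ranking
result = predict_new(train, train.protein_features, train.drug_features, config)
print(f"{len(result.records)} of {result.n_query_pairs} query pairs above "
      f"cutoff 0.5 ({100 * result.fraction_above_cutoff:.1f}%)")
print("top 5 candidates:")
for r in result.records[:5]:
    known = "known" if (r.target_id, r.drug_id) in train.positives else "novel"
    print(f"  {r.drug_id} x {r.target_id}  p={r.probability:.3f}  ({known})")
# In real use the query grid is a new set of proteins (with PSSMs of length
# >= s+1) x candidate drugs, and high-probability novel pairs are the output.
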