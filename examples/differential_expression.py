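"""Two-fold differential-expression calls and directional consistency.

Each of the study's 32 conditions contributes one irradiated-vs-control
contrast (log2 fold change of arm means; |log2FC| >= 1 is a call). A gene is
directionally consistent when it is called in at least 8 of 32 conditions
with a strict majority in one direction.
"""

from radhub import SyntheticConfig, generate_collection
from radhub.diffexpr import dataset_contrasts, summarize_consistency
from radhub.preprocess import quantile_normalize

datasets, truth, _ = generate_collection(SyntheticConfig(seed=1))

contrasts = []
for ds in datasets:
    normalized = ds.with_values(quantile_normalize(ds.values))
    contrasts.extend(dataset_contrasts(normalized))
print(f"{len(contrasts)} irradiated-vs-control contrasts across "
      f"{len(datasets)} datasets")

consistency = summarize_consistency(contrasts, min_sig_fraction=0.25)
print(f"significance gate: called in >= {consistency.min_sig} of "
      f"{consistency.n_conditions} conditions")
counts = consistency.frame["status"].value_counts().to_dict()
print(f"status counts: {counts}")

planted = {g: d for g, d in truth.consistent_direction.items() if d != "none"}
hits = sum(consistency.status_of(g) == f"consistent_{d}" for g, d in planted.items())
print(f"planted directions recovered: {hits}/{len(planted)}")

up = consistency.frame[consistency.frame["status"] == "consistent_up"]
print("\nstrongest consistently upregulated genes (by number of up calls):")
print(up.sort_values("n_up", ascending=False).head(5).to_string())
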