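"""Generate the default synthetic radiation study and write it to disk.

Builds five expression datasets over a shared 1000-gene universe (five
planted 100-gene coexpression modules plus background), with 32
irradiated-vs-control conditions, planted hub genes, planted differential
expression, and a drug-target catalog, then persists everything as TSVs.
"""

import sys
from pathlib import Path

from radhub import SyntheticConfig, generate_collection, write_collection

outdir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("synthetic_study")

config = SyntheticConfig(seed=1)
datasets, truth, catalog = generate_collection(config)

print(f"{config.n_datasets} datasets over {config.n_genes} genes")
for ds in datasets:
    print(
        f"  {ds.dataset_id}: {ds.n_samples} samples, "
        f"{len(ds.condition_ids)} irradiated-vs-control conditions"
    )
print(f"planted hubs: {len(truth.hub_genes)}  (shared across all datasets)")
n_de = len({g for g, _ in truth.de_direction})
print(f"planted DE genes: {n_de}  (directional calls in 12-18 of 32 conditions)")
print(f"druggable genes: {len(truth.druggable_genes)}; catalog rows: {len(catalog)}")

manifest = write_collection(datasets, truth, catalog, outdir, config=config, overwrite=True)
print(f"written to {manifest.parent}/ (manifest: {manifest.name})")
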