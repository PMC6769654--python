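"""Generate a synthetic heterogeneous dataset and look at its structure.

Builds a planted-partition gene (PPI-like) backbone, attaches diseases and
miRNAs to gene modules, plants disease-miRNA associations between entities
sharing a module, and hides 20% of them — the recoverable signal.
"""

import numpy as np

import heterolink as hl

cfg = hl.SimConfig(seed=0)  # 200 genes / 4 modules / 20 diseases / 30 miRNAs
dataset, truth = hl.simulate(cfg)

obs = dataset.associations.matrix
print(f"genes: {dataset.n_genes}, PPI edges: {dataset.gene_net.adjacency.nnz // 2}")
print(f"diseases: {dataset.n_diseases}, miRNAs: {dataset.n_mirnas}")
print(f"true associations: {int(truth.sum())}, observed: {int(obs.sum())}, "
      f"hidden: {int((truth - obs).sum())}")

files = hl.write_dataset("scratch/example_dataset", dataset, truth)
print(f"edge lists written next to {files['manifest']}")

# hidden positives + matched true negatives form the recovery test set
pairs = hl.holdout_hidden_positives(obs, truth, seed=0)
print(f"recovery evaluation pairs: {len(pairs)} "
      f"({sum(1 for p in pairs if p[2] == 1)} hidden positives)")
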