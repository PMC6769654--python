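"""Rank novel candidate miRNAs for one disease.

After training on all observed associations, every (disease, miRNA) pair
without a known association is scored by the bilinear decoder; the top of
the list is the model's proposal for follow-up.
"""

import numpy as np

import heterolink as hl
from heterolink.evaluation import rank_candidates

dataset, truth = hl.simulate(hl.SimConfig(seed=0))
features = hl.build_features(dataset, feature_dim=128, walk_cfg=hl.WalkConfig(seed=0))
cfg = hl.TrainConfig(seed=0)
state, _ = hl.train(dataset, features, cfg)

disease = dataset.associations.disease_ids[0]
top = rank_candidates(state, dataset, features, cfg, disease, top_n=10)

obs = dataset.associations.matrix
hidden = {
    dataset.associations.mirna_ids[j]
    for j in np.nonzero((truth[0] == 1) & (obs[0] == 0))[0]
}
print(f"top-10 candidate miRNAs for {disease} (* = a planted association that was hidden):")
for rank, (mirna, prob) in enumerate(top, start=1):
    marker = " *" if mirna in hidden else ""
    print(f"  {rank:2d}. {mirna}  p={prob:.4f}{marker}")
print("starred hits are recovered hidden truth; unstarred high scorers share the")
print("disease's gene module and are plausible novel candidates")
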