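"""Train the heterogeneous GCN end-to-end and recover hidden associations.

Trains at the reference protocol (2 x 32 hidden units, Adam lr 0.001,
100 epochs, K negatives = K positives sampled by centroid distance) and
measures how well the hidden 20% of planted associations are ranked above
true negatives, against a degree-preserving label-randomisation null.
"""

import heterolink as hl

sim = hl.SimConfig(seed=0)
cfg = hl.TrainConfig(seed=0)

dataset, truth = hl.simulate(sim)
features = hl.build_features(dataset, feature_dim=128, walk_cfg=hl.WalkConfig(seed=0))

real = hl.run_recovery(sim, cfg, dataset=dataset, truth=truth, features=features)
null = hl.run_recovery(
    sim, cfg, permute_labels=True, dataset=dataset, truth=truth, features=features
)

print(f"training loss: {real.first_loss:.1f} -> {real.final_loss:.1f} "
      f"({real.n_train_positives} positive edges, 100 epochs)")
print(f"hidden-positive recovery: AUROC {real.auroc:.3f}, AUPRC {real.auprc:.3f} "
      f"over {real.n_hidden_positives} hidden positives")
print(f"degree-preserving null:   AUROC {null.auroc:.3f} (should sit near 0.5)")
print("a large real-vs-null gap shows the model exploits gene-mediated structure,")
print("not just how many associations each node has")
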