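# heterolink

Heterogeneous graph-convolutional link prediction for disease–miRNA
association discovery over a protein–protein-interaction (PPI) backbone.

## The problem

MicroRNAs regulate target genes post-transcriptionally and are implicated in
many human diseases, but experimentally confirming a disease–miRNA
association is slow and costly. Most computational predictors are built on
hand-crafted disease/miRNA similarity measures. `heterolink` instead treats
the problem as **link prediction on a heterogeneous graph**: a gene–gene
(PPI) network mediates between two bipartite attachment networks
(miRNA→target-gene and disease→associated-gene), and the task is to score
candidate edges in the disease–miRNA layer. Feature extraction and link
prediction are trained end-to-end in one pipeline.

It is intended for computational biologists who have four edge lists
(PPI, miRNA–gene, disease–gene, disease–miRNA) and want ranked candidate
associations, plus the full evaluation protocol around them.

## The model

Gene features `H⁽⁰⁾` (node2vec embeddings of the PPI graph, or one-hot) are
propagated through graph-convolution layers on the self-loop-augmented,
symmetrically normalised adjacency,

    H_gg^(l+1) = f( D̃^(-1/2) (A_gg + I) D̃^(-1/2) · H_gg^(l) · W_gg^(l) )

and each layer's gene activations are pushed across the row-normalised
bipartite incidences into miRNA and disease space,

    H_mg^(l) = f( N_mg · H_gg^(l) · W_mg^(l) ),   H_dg^(l) = f( N_dg · H_gg^(l) · W_dg^(l) )

The final embeddings are `Z_m = H_mg^(K)` and `Z_d = H_dg^(K)` (layer
averaging available). A candidate edge (d, m) is scored by a bilinear
decoder with a sigmoid,

    p(d, m) = σ( z_d · M_r · z_mᵀ )

Because confirmed negative pairs do not exist in curated databases, training
negatives are chosen by **centroid-distance sampling**: concatenated edge
features `[z_d ‖ z_m]` of the K known positives define a centroid ψ_avg and
a mean distance dis_avg; the K unknown pairs farthest beyond dis_avg become
the negatives, giving a balanced 2K-sample training set. All parameters
(per-layer `W_gg`, `W_mg`, `W_dg` and `M_r`) are optimised jointly with
summed cross-entropy plus L2 weight decay, Adam (lr 0.001, 100 epochs),
Glorot initialisation, two hidden layers of 32 units. Gradients are exact
analytic backpropagation (validated against finite differences in the test
suite).

A synthetic-data module generates fully controlled datasets: a
planted-partition gene backbone, diseases/miRNAs attached mostly to home
modules, associations planted between module-mates, and a tunable fraction
of true associations hidden — so recovery of the hidden links measures real
generalisation, with a degree-preserving label-randomisation null as
negative control.

## Worked example

```bash
python examples/03_train_and_recover.py
```

prints (exactly reproducible, seed 0):

```
training loss: 165.3 -> 25.9 (120 positive edges, 100 epochs)
hidden-positive recovery: AUROC 0.890, AUPRC 0.852 over 30 hidden positives
degree-preserving null:   AUROC 0.498 (should sit near 0.5)
```

The 20 diseases and 30 miRNAs share 4 gene modules; 30 of the 150 planted
associations were hidden before training. AUROC 0.890 means a hidden true
association outranks a random true negative 89% of the time; the
checkerboard-swap null — same degree sequences, no gene-mediated structure —
sits at chance, so the signal comes from the network, not from node
popularity. The other examples cover dataset simulation and file formats
(`01`), walk-based gene embedding (`02`), and candidate ranking for a single
disease (`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
heterolink simulate --out data/            # write the four edge-list TSVs
heterolink train --manifest data/manifest.yaml --out run/
heterolink evaluate --manifest data/manifest.yaml --mode kfold --out eval/
heterolink predict --manifest data/manifest.yaml --disease d000 --out pred/
```

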