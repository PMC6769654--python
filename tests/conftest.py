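import numpy as np
import pytest

import heterolink as hl


@pytest.fixture()
def tiny_dataset():
    """Hand-built 5-gene / 2-disease / 2-miRNA dataset with all nodes anchored."""
    gene_edges = {("g1", "g2"), ("g2", "g3"), ("g3", "g4"), ("g4", "g5"), ("g1", "g3")}
    mg = {("m1", "g1"), ("m1", "g2"), ("m2", "g4"), ("m2", "g5")}
    dg = {("d1", "g2"), ("d1", "g3"), ("d2", "g5")}
    dm = {("d1", "m1"), ("d2", "m2")}
    return hl.assemble(gene_edges, mg, dg, dm)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by training/evaluation tests."""
    cfg = hl.SimConfig(
        n_genes=60, n_modules=3, intra_module_edge_prob=0.3,
        inter_module_edge_prob=0.02, n_diseases=6, n_mirnas=9,
        genes_per_entity=5, label_noise=0.2, seed=1,
    )
    dataset, truth = hl.simulate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_sim_features(small_sim):
    _, dataset, _ = small_sim
    return hl.one_hot_features(dataset.gene_net)


@pytest.fixture()
def quick_train_cfg():
    """Short training run for protocol tests (not the reference protocol)."""
    return hl.TrainConfig(epochs=8, seed=0)


def random_toy_instance(rng: np.random.Generator, max_d: int = 10, max_m: int = 10):
    """Random association matrix + embeddings for negative-sampler oracles."""
    d = int(rng.integers(3, max_d + 1))
    m = int(rng.integers(3, max_m + 1))
    assoc = (rng.random((d, m)) < 0.3).astype(np.int8)
    if assoc.sum() == 0:
        assoc[rng.integers(d), rng.integers(m)] = 1
    fz = int(rng.integers(2, 6))
    z_d = rng.normal(size=(d, fz))
    z_m = rng.normal(size=(m, fz))
    return assoc, z_d, z_m
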