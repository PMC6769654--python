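"""Synthetic heterogeneous datasets with planted disease-miRNA associations.

The generator emulates the structure the predictor assumes: associations
between diseases and miRNAs are mediated by shared gene neighbourhoods in
the PPI backbone.  Genes are partitioned into modules and wired by a
planted-partition (stochastic block) model — dense within modules, sparse
between.  Each disease and miRNA is assigned a home module and linked to
``genes_per_entity`` genes drawn mostly from that module.  The *true*
association matrix marks disease-miRNA pairs whose module memberships
overlap by at least ``theta_ov`` (with single home modules this means the
same module).  The *observed* matrix hides a ``label_noise`` fraction of
true positives — noise only conceals associations, never fabricates them,
mirroring the premise that unknown pairs are unverified rather than
confirmed negatives.  The hidden positives are the recoverable signal an
end-to-end run is judged on.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import graph_io
from .graph_io import HeteroDataset


@dataclasses.dataclass
class SimConfig:
    """Generator settings; defaults are the reference study conditions."""

    n_genes: int = 200
    n_modules: int = 4
    intra_module_edge_prob: float = 0.2
    inter_module_edge_prob: float = 0.01
    n_diseases: int = 20
    n_mirnas: int = 30
    genes_per_entity: int = 10
    theta_ov: float = 1.0
    label_noise: float = 0.2
    seed: int = 0
    module_fidelity: float = 0.8  # prob. an entity's gene link stays in its home module

    def __post_init__(self) -> None:
        for name in ("intra_module_edge_prob", "inter_module_edge_prob", "module_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.intra_module_edge_prob <= self.inter_module_edge_prob:
            raise ValueError("intra_module_edge_prob must exceed inter_module_edge_prob")
        if self.n_modules < 2:
            raise ValueError("n_modules must be >= 2")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        if self.genes_per_entity < 1:
            raise ValueError("genes_per_entity must be >= 1")


def _entity_links(
    rng: np.random.Generator,
    home: int,
    module_genes: list[np.ndarray],
    linkable: np.ndarray,
    k: int,
    fidelity: float,
) -> np.ndarray:
    """Sample k distinct gene links, each from the home module w.p. fidelity."""
    chosen: set[int] = set()
    while len(chosen) < k:
        if rng.random() < fidelity and module_genes[home].size:
            g = int(module_genes[home][rng.integers(module_genes[home].size)])
        else:
            g = int(linkable[rng.integers(linkable.size)])
        chosen.add(g)
    return np.asarray(sorted(chosen))


def simulate(cfg: SimConfig) -> tuple[HeteroDataset, np.ndarray]:
    """Generate one dataset; returns (dataset with observed labels, truth matrix).

    The truth matrix is aligned to the returned dataset's disease/miRNA
    orderings.  Entities are re-sampled internally until every one has at
    least one gene link inside the PPI universe, so assembly never drops
    nodes and the two matrices always share their index space.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    modules = np.arange(cfg.n_genes) % cfg.n_modules
    module_genes = [np.nonzero(modules == m)[0] for m in range(cfg.n_modules)]

    # planted-partition backbone over the upper triangle
    probs = np.where(
        modules[:, None] == modules[None, :],
        cfg.intra_module_edge_prob,
        cfg.inter_module_edge_prob,
    )
    draw = rng.random((cfg.n_genes, cfg.n_genes))
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    mask = draw[iu, ju] < probs[iu, ju]
    gene_edges = {
        (genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])
    }
    if not gene_edges:
        raise ValueError("no gene edges generated; raise the edge probabilities")
    linkable = np.unique(
        np.r_[iu[mask], ju[mask]]
    )  # genes with >=1 PPI edge survive assembly
    linkable_by_module = [
        np.intersect1d(module_genes[m], linkable) for m in range(cfg.n_modules)
    ]

    # balanced (round-robin) home assignment, like the gene partition: equal
    # module occupancy keeps disease/miRNA association degrees uninformative,
    # so recovery must come from gene-mediated structure rather than margins
    diseases = [f"d{i:03d}" for i in range(cfg.n_diseases)]
    mirnas = [f"m{i:03d}" for i in range(cfg.n_mirnas)]
    d_home = np.arange(cfg.n_diseases) % cfg.n_modules
    m_home = np.arange(cfg.n_mirnas) % cfg.n_modules

    dg_edges = set()
    for i, d in enumerate(diseases):
        links = _entity_links(
            rng, int(d_home[i]), linkable_by_module, linkable,
            cfg.genes_per_entity, cfg.module_fidelity,
        )
        dg_edges.update((d, genes[g]) for g in links)
    mg_edges = set()
    for i, m in enumerate(mirnas):
        links = _entity_links(
            rng, int(m_home[i]), linkable_by_module, linkable,
            cfg.genes_per_entity, cfg.module_fidelity,
        )
        mg_edges.update((m, genes[g]) for g in links)

    # single home modules: overlap is 1 iff the homes coincide
    truth = (d_home[:, None] == m_home[None, :]).astype(np.int8)
    observed = truth.copy()
    pos_i, pos_j = np.nonzero(truth)
    n_flip = int(round(cfg.label_noise * pos_i.size))
    if n_flip:
        flip = rng.choice(pos_i.size, size=n_flip, replace=False)
        observed[pos_i[flip], pos_j[flip]] = 0
    if observed.sum() == 0:
        raise ValueError("all planted associations hidden; lower label_noise")

    dm_edges = {
        (diseases[i], mirnas[j]) for i, j in zip(*np.nonzero(observed))
    }
    dataset = graph_io.assemble(gene_edges, mg_edges, dg_edges, dm_edges)

    # reorder truth to the assembled (sorted) id orderings
    d_order = [diseases.index(x) for x in dataset.associations.disease_ids]
    m_order = [mirnas.index(x) for x in dataset.associations.mirna_ids]
    truth_aligned = truth[np.ix_(d_order, m_order)]
    return dataset, truth_aligned


def holdout_hidden_positives(
    observed: np.ndarray, truth: np.ndarray, seed: int = 0
) -> list[tuple[int, int, int]]:
    """Labelled evaluation pairs: all hidden positives + as many true negatives.

    Hidden positives are pairs with truth 1 but observed 0 (the
    noise-concealed associations); the matched negatives are sampled from
    pairs with truth 0.  Raises if there are no hidden positives.
    """
    hidden = (truth == 1) & (observed == 0)
    hp_i, hp_j = np.nonzero(hidden)
    if hp_i.size == 0:
        raise ValueError("no hidden positives (label_noise was 0?)")
    neg_i, neg_j = np.nonzero(truth == 0)
    rng = np.random.default_rng(seed)
    take = rng.choice(neg_i.size, size=min(hp_i.size, neg_i.size), replace=False)
    pairs = [(int(i), int(j), 1) for i, j in zip(hp_i, hp_j)]
    pairs += [(int(neg_i[t]), int(neg_j[t]), 0) for t in take]
    return pairs


def degree_preserving_null(
    observed: np.ndarray, truth: np.ndarray, seed: int = 0, swaps_per_edge: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-preserving label permutation: checkerboard-swap randomisation.

    The true association matrix is rewired by repeated 2x2 checkerboard
    swaps — pick two associations (i1,j1), (i2,j2) with the crossed cells
    empty and exchange them — which preserves every row and column sum
    exactly while destroying any pair-level structure.  A plain permutation
    of disease rows would *not* be a null here: the permuted labels remain
    a deterministic function of (disease identity, miRNA module) and are
    therefore still learnable.  The same number of positives as in the
    original observed matrix is then re-hidden, giving a matched
    (observed, truth) pair whose hidden positives carry no gene-mediated
    signal.
    """
    rng = np.random.default_rng(seed)
    null_truth = truth.copy()
    n_pos = int(null_truth.sum())
    if n_pos < 2:
        raise ValueError("need >= 2 positives to randomize")
    target = swaps_per_edge * n_pos
    done = tries = 0
    while done < target and tries < 200 * target:
        tries += 1
        oi, oj = np.nonzero(null_truth)
        a, b = rng.integers(oi.size), rng.integers(oi.size)
        i1, j1, i2, j2 = oi[a], oj[a], oi[b], oj[b]
        if i1 != i2 and j1 != j2 and null_truth[i1, j2] == 0 and null_truth[i2, j1] == 0:
            null_truth[i1, j1] = null_truth[i2, j2] = 0
            null_truth[i1, j2] = null_truth[i2, j1] = 1
            done += 1
    n_hidden = int(truth.sum() - observed.sum())
    pi, pj = np.nonzero(null_truth)
    null_observed = null_truth.copy()
    if n_hidden:
        flip = rng.choice(pi.size, size=min(n_hidden, pi.size), replace=False)
        null_observed[pi[flip], pj[flip]] = 0
    return null_observed, null_truth


def write_dataset(
    outdir: str | Path, dataset: HeteroDataset, truth: np.ndarray | None = None
) -> dict[str, Path]:
    """Write the four edge-list TSVs (+ optional truth TSV) and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "gene_gene": outdir / "gene_gene.tsv",
        "mirna_gene": outdir / "mirna_gene.tsv",
        "disease_gene": outdir / "disease_gene.tsv",
        "disease_mirna": outdir / "disease_mirna.tsv",
    }
    graph_io.write_edge_list(files["gene_gene"], dataset.gene_net.edge_set())
    graph_io.write_edge_list(files["mirna_gene"], dataset.mirna_gene.edge_set())
    graph_io.write_edge_list(files["disease_gene"], dataset.disease_gene.edge_set())
    graph_io.write_edge_list(files["disease_mirna"], dataset.associations.edge_set())
    if truth is not None:
        truth_path = outdir / "truth.tsv"
        pairs = {
            (dataset.associations.disease_ids[i], dataset.associations.mirna_ids[j])
            for i, j in zip(*np.nonzero(truth))
        }
        graph_io.write_edge_list(truth_path, pairs)
        files["truth"] = truth_path
    manifest = outdir / "manifest.yaml"
    with manifest.open("w", encoding="utf-8") as fh:
        for key in graph_io.MANIFEST_KEYS:
            fh.write(f"{key}: {files[key].name}\n")
    files["manifest"] = manifest
    return files
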