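"""Raw gene features: biased random-walk embeddings of the PPI graph.

The model's input features H(0) describe each gene by its position in the
PPI backbone.  Two feature sources are provided:

* **node2vec-style embeddings** — second-order biased random walks over the
  gene graph, embedded with skip-gram and negative sampling (SGNS).  A walk
  at node ``v`` arriving from ``t`` steps to a candidate ``x`` with
  unnormalised weight ``1/p`` if ``x == t`` (return), ``1`` if ``x`` is a
  common neighbour of ``t`` and ``v``, and ``1/q`` otherwise.  With
  ``p = q = 1`` this reduces to a uniform first-order walk.
* **one-hot features** — the identity matrix, a featureless baseline in
  which each gene is only distinguishable by its index.

The SGNS trainer is implemented here directly (numpy + a numba-compiled
inner loop): pairs are harvested from the walk corpus with word2vec-style
reduced windows, negatives are drawn from the unigram distribution raised
to 3/4, and updates are sequential per-pair SGD with a linearly decaying
learning rate.  Everything is seeded and single-threaded, so identical
inputs give bit-identical embeddings.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numba as nb
import numpy as np

from .graph_io import GeneNetwork


@dataclasses.dataclass
class WalkConfig:
    """Hyperparameters of the walk generator and skip-gram embedder.

    Defaults follow the node2vec reference settings: 10 walks per node,
    walk length 80, window 10, unbiased walks (p = q = 1).
    """

    num_walks_per_node: int = 10
    walk_length: int = 80
    return_param_p: float = 1.0
    inout_param_q: float = 1.0
    window: int = 10
    seed: int = 0
    epochs: int = 5
    negative: int = 5
    initial_lr: float = 0.025
    min_lr: float = 1e-4

    def __post_init__(self) -> None:
        if self.num_walks_per_node <= 0 or self.walk_length <= 0:
            raise ValueError("walk counts and lengths must be positive")
        if self.return_param_p <= 0 or self.inout_param_q <= 0:
            raise ValueError("p and q must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.epochs <= 0 or self.negative <= 0:
            raise ValueError("epochs and negative sample count must be positive")


@dataclasses.dataclass
class FeatureMatrix:
    """Dense per-node feature matrix whose row order matches a GeneNetwork."""

    node_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.node_ids):
            raise ValueError("feature matrix shape does not match node_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]


def generate_walks(graph: GeneNetwork, cfg: WalkConfig) -> list[list[str]]:
    """Generate ``num_walks_per_node`` second-order biased walks per node.

    Walks terminate early at dead ends.  Transition weights implement the
    node2vec bias (1/p return, 1 to a common neighbour, 1/q outward); for
    p = q = 1 each step is a uniform neighbour choice.
    """
    rng = np.random.default_rng(cfg.seed)
    adj = graph.adjacency.tocsr()
    n = graph.n_genes
    neighbors = [adj.indices[adj.indptr[i]: adj.indptr[i + 1]] for i in range(n)]
    neighbor_sets = [set(nb.tolist()) for nb in neighbors]
    inv_p = 1.0 / cfg.return_param_p
    inv_q = 1.0 / cfg.inout_param_q
    unbiased = cfg.return_param_p == 1.0 and cfg.inout_param_q == 1.0

    walks: list[list[str]] = []
    for _ in range(cfg.num_walks_per_node):
        for start in range(n):
            walk = [start]
            while len(walk) < cfg.walk_length:
                cur = walk[-1]
                nbrs = neighbors[cur]
                if nbrs.size == 0:
                    break
                if len(walk) == 1 or unbiased:
                    nxt = nbrs[rng.integers(nbrs.size)]
                else:
                    prev = walk[-2]
                    prev_nbrs = neighbor_sets[prev]
                    w = np.empty(nbrs.size)
                    for k, x in enumerate(nbrs):
                        if x == prev:
                            w[k] = inv_p
                        elif x in prev_nbrs:
                            w[k] = 1.0
                        else:
                            w[k] = inv_q
                    w /= w.sum()
                    nxt = nbrs[rng.choice(nbrs.size, p=w)]
                walk.append(int(nxt))
            walks.append([graph.gene_ids[i] for i in walk])
    return walks


def _harvest_pairs(
    walk_indices: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Collect (center, context) index pairs with reduced-window sampling.

    Vectorised over the concatenated corpus: for each lag 1..window a pair
    (pos, pos+lag) is emitted in both directions when both positions lie in
    the same walk and the lag is within the center's sampled window
    (word2vec convention: per-position window ~ U{1..window}).
    """
    tokens = np.concatenate([w for w in walk_indices if w.size > 0])
    walk_of = np.concatenate(
        [np.full(w.size, i, dtype=np.int64) for i, w in enumerate(walk_indices) if w.size > 0]
    )
    b = rng.integers(1, window + 1, size=tokens.size)
    centers_parts, contexts_parts = [], []
    for lag in range(1, window + 1):
        if lag >= tokens.size:
            break
        left, right = np.arange(tokens.size - lag), np.arange(lag, tokens.size)
        same = walk_of[left] == walk_of[right]
        fwd = same & (b[left] >= lag)    # left token is the center
        bwd = same & (b[right] >= lag)   # right token is the center
        centers_parts.extend((tokens[left[fwd]], tokens[right[bwd]]))
        contexts_parts.extend((tokens[right[fwd]], tokens[left[bwd]]))
    centers = np.concatenate(centers_parts) if centers_parts else np.empty(0, dtype=np.int64)
    contexts = np.concatenate(contexts_parts) if contexts_parts else np.empty(0, dtype=np.int64)
    return centers, contexts


def embed_walks(
    walks: list[list[str]],
    feature_dim: int,
    window: int = 10,
    seed: int = 0,
    node_ids: list[str] | None = None,
    epochs: int = 5,
    negative: int = 5,
    initial_lr: float = 0.025,
    min_lr: float = 1e-4,
) -> FeatureMatrix:
    """Train SGNS embeddings over a walk corpus.

    Parameters
    ----------
    walks
        Node-identifier sequences covering every node at least once.
    node_ids
        Output row order; defaults to sorted unique walk tokens.  A node
        absent from all walks is an error — it would receive an untrained
        vector.

    Returns a deterministic ``FeatureMatrix`` (single generator, single
    thread): same corpus and seed give identical matrices.
    """
    seen = {tok for walk in walks for tok in walk}
    if node_ids is None:
        node_ids = sorted(seen)
    missing = [nid for nid in node_ids if nid not in seen]
    if missing:
        raise ValueError(f"{len(missing)} node(s) absent from all walks, e.g. {missing[:3]}")

    index = {nid: i for i, nid in enumerate(node_ids)}
    V = len(node_ids)
    walk_indices = [
        np.asarray([index[t] for t in walk if t in index], dtype=np.int64)
        for walk in walks
    ]

    rng = np.random.default_rng(seed)
    # unigram^0.75 negative-sampling distribution, discretised into a table
    counts = np.zeros(V, dtype=np.float64)
    for walk in walk_indices:
        np.add.at(counts, walk, 1.0)
    noise = counts ** 0.75
    noise /= noise.sum()
    table_size = max(100_000, 10 * V)
    noise_table = rng.choice(V, size=table_size, p=noise).astype(np.int64)

    W_in = ((rng.random((V, feature_dim)) - 0.5) / feature_dim).astype(np.float64)
    W_out = np.zeros((V, feature_dim))

    centers, contexts = _harvest_pairs(walk_indices, window, rng)
    if centers.size == 0:
        raise ValueError("walk corpus yields no training pairs")
    _sgns_epochs(
        W_in, W_out, centers, contexts, noise_table,
        epochs, negative, initial_lr, min_lr,
        int(rng.integers(2 ** 31 - 1)),
    )
    return FeatureMatrix(list(node_ids), W_in)


@nb.njit(cache=False)
def _sgns_epochs(W_in, W_out, centers, contexts, noise_table, epochs, negative, initial_lr, min_lr, seed):  # pragma: no cover - exercised via embed_walks
    """Sequential skip-gram negative-sampling SGD (one update per pair)."""
    np.random.seed(seed)
    n_pairs = centers.shape[0]
    dim = W_in.shape[1]
    table_size = noise_table.shape[0]
    total = epochs * n_pairs
    done = 0
    order = np.arange(n_pairs)
    for _ in range(epochs):
        np.random.shuffle(order)
        for t in range(n_pairs):
            lr = initial_lr * (1.0 - done / total)
            if lr < min_lr:
                lr = min_lr
            c = centers[order[t]]
            grad_c = np.zeros(dim)
            for s in range(negative + 1):
                if s == 0:
                    o = contexts[order[t]]
                    target = 1.0
                else:
                    o = noise_table[np.random.randint(table_size)]
                    target = 0.0
                dot = 0.0
                for f in range(dim):
                    dot += W_in[c, f] * W_out[o, f]
                if dot >= 0.0:
                    p = 1.0 / (1.0 + np.exp(-dot))
                else:
                    e = np.exp(dot)
                    p = e / (1.0 + e)
                g = lr * (p - target)
                for f in range(dim):
                    grad_c[f] += g * W_out[o, f]
                    W_out[o, f] -= g * W_in[c, f]
            for f in range(dim):
                W_in[c, f] -= grad_c[f]
            done += 1


def node2vec_features(
    graph: GeneNetwork,
    feature_dim: int = 128,
    cfg: WalkConfig | None = None,
    standardize: bool = True,
) -> FeatureMatrix:
    """Walks + SGNS in one call, row order matching ``graph.gene_ids``.

    By default the learned embeddings are column-standardised (see
    :func:`standardize_features`) as the final step of feature
    construction; pass ``standardize=False`` for the raw vectors.
    """
    cfg = cfg or WalkConfig()
    walks = generate_walks(graph, cfg)
    feats = embed_walks(
        walks,
        feature_dim,
        window=cfg.window,
        seed=cfg.seed,
        node_ids=graph.gene_ids,
        epochs=cfg.epochs,
        negative=cfg.negative,
        initial_lr=cfg.initial_lr,
        min_lr=cfg.min_lr,
    )
    return standardize_features(feats) if standardize else feats


def one_hot_features(graph: GeneNetwork) -> FeatureMatrix:
    """Featureless baseline: the N x N identity matrix."""
    return FeatureMatrix(list(graph.gene_ids), np.eye(graph.n_genes))


def standardize_features(features: FeatureMatrix) -> FeatureMatrix:
    """Column-standardise features: zero mean, unit variance per dimension.

    Skip-gram embeddings carry a large shared mean component (all vectors
    lean along one direction); centring removes it and per-column scaling
    equalises dimensions, which conditions the downstream bilinear decoder.
    Constant columns are left at zero.
    """
    v = features.values
    mu = v.mean(axis=0)
    sd = v.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return FeatureMatrix(list(features.node_ids), (v - mu) / sd)


def normalize_features(features: FeatureMatrix, norm: str = "l1") -> FeatureMatrix:
    """Row-normalise features (L1 sum-to-one by default, L2, standardize, none).

    All-zero rows are left untouched with a warning — they carry no signal
    either way.
    """
    if norm == "none":
        return FeatureMatrix(list(features.node_ids), features.values.copy())
    if norm == "standardize":
        return standardize_features(features)
    if norm == "l1":
        norms = np.abs(features.values).sum(axis=1)
    elif norm == "l2":
        norms = np.linalg.norm(features.values, axis=1)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero feature row(s) left unnormalized")
    safe = np.where(zero, 1.0, norms)
    return FeatureMatrix(list(features.node_ids), features.values / safe[:, None])


def save_features(path: str | Path, features: FeatureMatrix) -> None:
    """Write features as TSV: node_id followed by F values per row."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for nid, row in zip(features.node_ids, features.values):
            fh.write(nid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def load_features(path: str | Path) -> FeatureMatrix:
    """Read a TSV feature table written by :func:`save_features`."""
    node_ids: list[str] = []
    rows: list[list[float]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            node_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return FeatureMatrix(node_ids, np.asarray(rows))
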