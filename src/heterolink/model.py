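"""Heterogeneous graph-convolutional forward pass and bilinear decoder.

Architecture.  Gene features H(0) are propagated through L graph-convolution
layers on the self-loop-augmented, symmetrically normalised PPI adjacency

    H_gg(l+1) = f( D^{-1/2} (A + I) D^{-1/2}  H_gg(l)  W_gg(l) )

and each layer's gene activations are pushed across the bipartite incidence
matrices into miRNA and disease space,

    H_mg(l) = f( N_mg H_gg(l) W_mg(l) ),    H_dg(l) = f( N_dg H_gg(l) W_dg(l) )

where N is the row-normalised incidence (each miRNA/disease row averages its
gene neighbours; self-loop augmentation is undefined for a non-square
incidence, and row averaging keeps the activation scale bounded regardless
of degree).  The final embeddings Z_m, Z_d are either the last layer's cross
activations (default, matching the explicit Z = H(K) rule) or the mean over
layers.  A candidate edge (d, m) is scored by the bilinear form
``g = z_d M z_m^T`` and mapped to a probability with a numerically stable
sigmoid.

The backward pass (`backward`) is exact analytic backpropagation through
this computation; it is validated against central finite differences in the
test suite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from .embedding import FeatureMatrix
from .graph_io import BipartiteNetwork, GeneNetwork, HeteroDataset

# ---------------------------------------------------------------------------
# activations

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)

def _relu_grad(pre: np.ndarray) -> np.ndarray:
    return (pre > 0).astype(pre.dtype)

def _tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)

def _tanh_grad(pre: np.ndarray) -> np.ndarray:
    t = np.tanh(pre)
    return 1.0 - t * t

def _identity(x: np.ndarray) -> np.ndarray:
    return x

def _identity_grad(pre: np.ndarray) -> np.ndarray:
    return np.ones_like(pre)

ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _relu_grad),
    "tanh": (_tanh, _tanh_grad),
    "identity": (_identity, _identity_grad),
    "linear": (_identity, _identity_grad),
}

def get_activation(name: str) -> tuple[Callable, Callable]:
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


# ---------------------------------------------------------------------------
# adjacency normalisation

@dataclasses.dataclass
class NormalizedAdjacency:
    """Symmetric D^{-1/2}(A+I)D^{-1/2} propagation matrix (eigenvalues in (-1, 1])."""

    matrix: sp.csr_matrix


def normalize_adjacency(net: GeneNetwork) -> NormalizedAdjacency:
    """Self-loop-augmented symmetric normalisation of the PPI adjacency."""
    a_tilde = (net.adjacency + sp.identity(net.n_genes, format="csr")).tocsr()
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return NormalizedAdjacency((d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr())


def normalize_bipartite(incidence: sp.spmatrix, mode: str = "row") -> sp.csr_matrix:
    """Row-normalise a bipartite incidence (``row``) or leave it raw (``none``)."""
    inc = incidence.tocsr().astype(np.float64)
    if mode == "none":
        return inc
    if mode != "row":
        raise ValueError(f"unknown bipartite normalisation {mode!r}")
    deg = np.asarray(inc.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0  # all-zero rows stay zero
    return (sp.diags(1.0 / deg) @ inc).tocsr()


# ---------------------------------------------------------------------------
# parameters

@dataclasses.dataclass
class ModelState:
    """All trainable parameters: per-layer W_gg, W_mg, W_dg and the decoder M."""

    W_gg: list[np.ndarray]
    W_mg: list[np.ndarray]
    W_dg: list[np.ndarray]
    M: np.ndarray

    def named_parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, w in enumerate(self.W_gg):
            out.append((f"W_gg.{i}", w))
        for i, w in enumerate(self.W_mg):
            out.append((f"W_mg.{i}", w))
        for i, w in enumerate(self.W_dg):
            out.append((f"W_dg.{i}", w))
        out.append(("M", self.M))
        return out

    def copy(self) -> "ModelState":
        return ModelState(
            [w.copy() for w in self.W_gg],
            [w.copy() for w in self.W_mg],
            [w.copy() for w in self.W_dg],
            self.M.copy(),
        )

    @property
    def n_layers(self) -> int:
        return len(self.W_gg)


def save_state(path: str | Path, state: ModelState, config: dict | None = None) -> None:
    """Serialise parameters to one ``.npz`` archive with a JSON manifest entry."""
    arrays: dict[str, np.ndarray] = {
        name.replace(".", "_"): w for name, w in state.named_parameters()
    }
    manifest = {
        "n_layers": state.n_layers,
        "shapes": {name: list(w.shape) for name, w in state.named_parameters()},
        "config": config or {},
    }
    arrays["__manifest__"] = np.frombuffer(
        json.dumps(manifest, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_state(path: str | Path) -> tuple[ModelState, dict]:
    """Inverse of :func:`save_state`; returns (state, manifest)."""
    with np.load(Path(path)) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        L = manifest["n_layers"]
        state = ModelState(
            [data[f"W_gg_{i}"] for i in range(L)],
            [data[f"W_mg_{i}"] for i in range(L)],
            [data[f"W_dg_{i}"] for i in range(L)],
            data["M"],
        )
    return state, manifest


# ---------------------------------------------------------------------------
# layer-level operations (contracts used by the oracle tests)

def gene_layer_forward(
    a_hat: NormalizedAdjacency | sp.spmatrix,
    h: np.ndarray | FeatureMatrix,
    w: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """One PPI graph-convolution layer: f(Â H W)."""
    mat = a_hat.matrix if isinstance(a_hat, NormalizedAdjacency) else a_hat
    hv = h.values if isinstance(h, FeatureMatrix) else h
    if mat.shape[1] != hv.shape[0] or hv.shape[1] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: Â {mat.shape}, H {hv.shape}, W {w.shape}"
        )
    f, _ = get_activation(activation)
    return f(mat @ hv @ w)


def cross_layer_forward(
    bipartite: BipartiteNetwork | sp.spmatrix,
    h_gg: np.ndarray,
    w: np.ndarray,
    activation: str = "identity",
    norm: str = "row",
) -> np.ndarray:
    """Cross-network layer: f(Norm(B) H_gg W) into miRNA or disease space."""
    inc = bipartite.incidence if isinstance(bipartite, BipartiteNetwork) else bipartite
    if inc.shape[1] != h_gg.shape[0] or h_gg.shape[1] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: B {inc.shape}, H {h_gg.shape}, W {w.shape}"
        )
    f, _ = get_activation(activation)
    return f(normalize_bipartite(inc, norm) @ h_gg @ w)


def final_embeddings(
    h_mg_layers: Sequence[np.ndarray],
    h_dg_layers: Sequence[np.ndarray],
    mode: str = "last",
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise per-layer cross activations into (Z_d, Z_m).

    ``last`` takes the final layer (Z = H(K)); ``mean`` averages layers
    element-wise, which requires equal widths.
    """
    if not h_mg_layers or not h_dg_layers:
        raise ValueError("empty layer list")
    if mode == "last":
        return h_dg_layers[-1], h_mg_layers[-1]
    if mode == "mean":
        for stack in (h_mg_layers, h_dg_layers):
            widths = {h.shape[1] for h in stack}
            if len(widths) != 1:
                raise ValueError(f"mean mode needs equal layer widths, got {widths}")
        return (
            np.mean(np.stack(h_dg_layers), axis=0),
            np.mean(np.stack(h_mg_layers), axis=0),
        )
    raise ValueError(f"unknown final-embedding mode {mode!r}")


def decode(z_d: np.ndarray, m_r: np.ndarray, z_m: np.ndarray) -> float:
    """Bilinear edge score g = z_d M z_m^T for one (disease, miRNA) pair."""
    z_d = np.asarray(z_d, dtype=np.float64)
    z_m = np.asarray(z_m, dtype=np.float64)
    if z_d.shape[-1] != m_r.shape[0] or m_r.shape[1] != z_m.shape[-1]:
        raise ValueError("decoder dimension mismatch")
    return float(z_d @ m_r @ z_m)


def decode_all(z_d: np.ndarray, m_r: np.ndarray, z_m: np.ndarray) -> np.ndarray:
    """Score every disease-miRNA pair at once: Z_d M Z_m^T (d x m)."""
    return z_d @ m_r @ z_m.T


def edge_probability(g: np.ndarray | float) -> np.ndarray | float:
    """Stable sigmoid sigma(g) = 1/(1+exp(-g)); no overflow up to |g| ~ 1e4."""
    g_arr = np.asarray(g, dtype=np.float64)
    out = np.empty_like(g_arr)
    pos = g_arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-g_arr[pos]))
    e = np.exp(g_arr[~pos])
    out[~pos] = e / (1.0 + e)
    if np.isscalar(g) or g_arr.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# full forward / backward

@dataclasses.dataclass
class ForwardCache:
    """Every intermediate needed for exact backpropagation."""

    h_gg: list[np.ndarray]        # [H(0), H(1), ..., H(L)] post-activation
    pre_gg: list[np.ndarray]      # pre-activation per gene layer
    h_mg: list[np.ndarray]        # cross activations per layer
    pre_mg: list[np.ndarray]
    h_dg: list[np.ndarray]
    pre_dg: list[np.ndarray]
    z_d: np.ndarray
    z_m: np.ndarray


@dataclasses.dataclass
class GraphOperators:
    """Pre-normalised propagation matrices shared across epochs."""

    a_hat: sp.csr_matrix
    n_mg: sp.csr_matrix
    n_dg: sp.csr_matrix

    @classmethod
    def from_dataset(cls, dataset: HeteroDataset, bipartite_norm: str = "row") -> "GraphOperators":
        return cls(
            normalize_adjacency(dataset.gene_net).matrix,
            normalize_bipartite(dataset.mirna_gene.incidence, bipartite_norm),
            normalize_bipartite(dataset.disease_gene.incidence, bipartite_norm),
        )


def forward(
    ops: GraphOperators,
    h0: np.ndarray,
    state: ModelState,
    hidden_activation: str = "relu",
    cross_activation: str = "identity",
    final_mode: str = "last",
) -> ForwardCache:
    """Run the full heterogeneous convolution stack and return all activations."""
    f_h, _ = get_activation(hidden_activation)
    f_c, _ = get_activation(cross_activation)

    h_gg = [np.asarray(h0, dtype=np.float64)]
    pre_gg, h_mg, pre_mg, h_dg, pre_dg = [], [], [], [], []
    for layer in range(state.n_layers):
        pre = ops.a_hat @ h_gg[-1] @ state.W_gg[layer]
        pre_gg.append(pre)
        h_gg.append(f_h(pre))
        pm = ops.n_mg @ h_gg[-1] @ state.W_mg[layer]
        pre_mg.append(pm)
        h_mg.append(f_c(pm))
        pd = ops.n_dg @ h_gg[-1] @ state.W_dg[layer]
        pre_dg.append(pd)
        h_dg.append(f_c(pd))

    z_d, z_m = final_embeddings(h_mg, h_dg, final_mode)
    if not np.isfinite(z_d).all() or not np.isfinite(z_m).all():
        raise FloatingPointError("non-finite activations in forward pass")
    return ForwardCache(h_gg, pre_gg, h_mg, pre_mg, h_dg, pre_dg, z_d, z_m)


def backward(
    ops: GraphOperators,
    cache: ForwardCache,
    state: ModelState,
    d_z_d: np.ndarray,
    d_z_m: np.ndarray,
    hidden_activation: str = "relu",
    cross_activation: str = "identity",
    final_mode: str = "last",
) -> dict[str, np.ndarray]:
    """Backpropagate gradients w.r.t. (Z_d, Z_m) into every parameter matrix.

    Returns a dict keyed like ``ModelState.named_parameters``.  Weight-decay
    gradients are *not* included here; the loss layer adds them.
    """
    L = state.n_layers
    _, g_h = get_activation(hidden_activation)
    _, g_c = get_activation(cross_activation)

    grads = {name: np.zeros_like(w) for name, w in state.named_parameters()}

    # distribute dZ over cross layers per synthesis mode
    d_mg = [np.zeros_like(h) for h in cache.h_mg]
    d_dg = [np.zeros_like(h) for h in cache.h_dg]
    if final_mode == "last":
        d_mg[-1] = d_z_m
        d_dg[-1] = d_z_d
    elif final_mode == "mean":
        for layer in range(L):
            d_mg[layer] = d_z_m / L
            d_dg[layer] = d_z_d / L
    else:
        raise ValueError(f"unknown final-embedding mode {final_mode!r}")

    d_h_gg = [np.zeros_like(h) for h in cache.h_gg]
    for layer in range(L):
        dq_m = d_mg[layer] * g_c(cache.pre_mg[layer])
        prop_m = ops.n_mg @ cache.h_gg[layer + 1]
        grads[f"W_mg.{layer}"] += prop_m.T @ dq_m
        d_h_gg[layer + 1] += ops.n_mg.T @ (dq_m @ state.W_mg[layer].T)

        dq_d = d_dg[layer] * g_c(cache.pre_dg[layer])
        prop_d = ops.n_dg @ cache.h_gg[layer + 1]
        grads[f"W_dg.{layer}"] += prop_d.T @ dq_d
        d_h_gg[layer + 1] += ops.n_dg.T @ (dq_d @ state.W_dg[layer].T)

    for layer in range(L - 1, -1, -1):
        dp = d_h_gg[layer + 1] * g_h(cache.pre_gg[layer])
        prop = ops.a_hat @ cache.h_gg[layer]
        grads[f"W_gg.{layer}"] += prop.T @ dp
        d_h_gg[layer] += ops.a_hat.T @ (dp @ state.W_gg[layer].T)

    return grads
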