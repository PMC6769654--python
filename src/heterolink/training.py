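"""End-to-end training: cross-entropy + L2 weight decay, Adam, Glorot init.

Feature extraction and link prediction are one pipeline: each epoch runs the
full heterogeneous convolution, pairs the K known positives with K reliable
negatives sampled by centroid distance (K = number of positives, so the
training set holds 2K samples; sampled once from the initial embeddings by
default, or refreshed per epoch), shuffles them together, and takes one
full-batch Adam step on

    L = sum_ij [ -Y_ij log p_ij - (1 - Y_ij) log(1 - p_ij) ]
        + weight_decay * sum_W ||W||^2

over all trainable matrices (per-layer W_gg, W_mg, W_dg and the decoder M).
The per-edge loss is evaluated in logit space for stability; the clipped
probability-space form is exposed as :func:`cross_entropy_loss`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import model as M
from . import negative_sampling as ns
from .embedding import FeatureMatrix, normalize_features
from .graph_io import HeteroDataset

_EPS = 1e-12


@dataclasses.dataclass
class TrainConfig:
    """Optimisation and architecture settings (defaults = reference protocol)."""

    learning_rate: float = 0.001
    epochs: int = 100
    hidden_dims: tuple[int, ...] = (32, 32)
    weight_decay: float = 5e-4
    activation: str = "relu"
    cross_activation: str = "identity"
    final_mode: str = "last"
    bipartite_norm: str = "row"
    feature_norm: str = "none"
    seed: int = 0
    neg_refresh: str = "once"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.neg_refresh not in ("once", "per-epoch"):
            raise ValueError("neg_refresh must be 'once' or 'per-epoch'")
        if self.final_mode not in ("last", "mean"):
            raise ValueError("final_mode must be 'last' or 'mean'")
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if not self.hidden_dims or any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden_dims must be non-empty positive integers")


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch training loss and validation AUROC (training AUROC if no
    validation samples were supplied)."""

    loss: list[float]
    val_auroc: list[float]


def cross_entropy_loss(label: int, probability: float, eps: float = _EPS) -> float:
    """Binary cross entropy -y log p - (1-y) log(1-p) with p clipped to [eps, 1-eps]."""
    p = min(max(float(probability), eps), 1.0 - eps)
    y = float(label)
    return float(-y * np.log(p) - (1.0 - y) * np.log1p(-p))


def _logit_bce(labels: np.ndarray, logits: np.ndarray) -> np.ndarray:
    """Stable per-sample BCE from raw scores: max(g,0) - y*g + log(1+e^-|g|)."""
    return np.maximum(logits, 0.0) - labels * logits + np.log1p(np.exp(-np.abs(logits)))


def l2_penalty(state: M.ModelState) -> float:
    """Sum of squared Frobenius norms over every trainable matrix."""
    return float(sum((w ** 2).sum() for _, w in state.named_parameters()))


def total_loss(
    labels: np.ndarray,
    logits: np.ndarray,
    state: M.ModelState | None = None,
    weight_decay: float = 0.0,
) -> float:
    """Summed cross entropy over samples plus the L2 weight-decay penalty."""
    labels = np.asarray(labels, dtype=np.float64)
    logits = np.asarray(logits, dtype=np.float64)
    loss = float(_logit_bce(labels, logits).sum())
    if weight_decay and state is not None:
        loss += weight_decay * l2_penalty(state)
    return loss


def glorot_uniform(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Uniform(-b, b) with b = sqrt(6 / (fan_in + fan_out))."""
    bound = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-bound, bound, size=shape)


def init_weights(
    feature_dim: int, hidden_dims: tuple[int, ...], seed: int
) -> M.ModelState:
    """Glorot-initialised ModelState for the given architecture."""
    rng = np.random.default_rng(seed)
    dims = (feature_dim, *hidden_dims)
    w_gg = [glorot_uniform((dims[i], dims[i + 1]), rng) for i in range(len(hidden_dims))]
    w_mg = [glorot_uniform((h, h), rng) for h in hidden_dims]
    w_dg = [glorot_uniform((h, h), rng) for h in hidden_dims]
    m_r = glorot_uniform((hidden_dims[-1], hidden_dims[-1]), rng)
    return M.ModelState(w_gg, w_mg, w_dg, m_r)


def loss_and_grads(
    ops: M.GraphOperators,
    h0: np.ndarray,
    state: M.ModelState,
    samples: list[tuple[int, int, int]],
    config: TrainConfig,
) -> tuple[float, dict[str, np.ndarray], M.ForwardCache]:
    """Forward + analytic backward over one labelled sample batch.

    Gradients cover every matrix in ``state`` including the decoder and the
    weight-decay term.
    """
    cache = M.forward(
        ops, h0, state,
        hidden_activation=config.activation,
        cross_activation=config.cross_activation,
        final_mode=config.final_mode,
    )
    d_idx = np.asarray([s[0] for s in samples])
    m_idx = np.asarray([s[1] for s in samples])
    labels = np.asarray([s[2] for s in samples], dtype=np.float64)

    zd_rows = cache.z_d[d_idx]
    zm_rows = cache.z_m[m_idx]
    logits = np.einsum("bf,fg,bg->b", zd_rows, state.M, zm_rows)
    loss = total_loss(labels, logits, state, config.weight_decay)

    delta = M.edge_probability(logits) - labels          # dL/dg per sample
    grad_m = np.einsum("b,bf,bg->fg", delta, zd_rows, zm_rows)
    d_z_d = np.zeros_like(cache.z_d)
    d_z_m = np.zeros_like(cache.z_m)
    np.add.at(d_z_d, d_idx, delta[:, None] * (zm_rows @ state.M.T))
    np.add.at(d_z_m, m_idx, delta[:, None] * (zd_rows @ state.M))

    grads = M.backward(
        ops, cache, state, d_z_d, d_z_m,
        hidden_activation=config.activation,
        cross_activation=config.cross_activation,
        final_mode=config.final_mode,
    )
    grads["M"] = grads["M"] + grad_m
    if config.weight_decay:
        for name, w in state.named_parameters():
            grads[name] = grads[name] + 2.0 * config.weight_decay * w
    return loss, grads, cache


class _Adam:
    """Textbook Adam over a dict of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            m_hat = self.m[name] / (1 - self.b1 ** self.t)
            v_hat = self.v[name] / (1 - self.b2 ** self.t)
            params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _state_params(state: M.ModelState) -> dict[str, np.ndarray]:
    return dict(state.named_parameters())


def train(
    dataset: HeteroDataset,
    features: FeatureMatrix,
    config: TrainConfig,
    val_samples: list[tuple[int, int, int]] | None = None,
    train_positives: list[tuple[int, int]] | None = None,
    exclude_pairs: set[tuple[int, int]] | None = None,
    assoc_override: np.ndarray | None = None,
    neg_callback=None,
) -> tuple[M.ModelState, TrainHistory]:
    """Optimise all parameters end-to-end; returns final state and history.

    Parameters beyond the usual triple support the cross-validation
    protocols: ``train_positives`` restricts the positive training edges,
    ``exclude_pairs`` bars edges from the negative candidate pool,
    ``assoc_override`` substitutes a masked label matrix, and
    ``neg_callback`` observes every sampled negative set (used by the
    leakage assertions).

    Raises ``RuntimeError`` on non-finite loss, with the epoch number.
    """
    # local import avoids a cycle: evaluation imports training for the CV protocols
    from .evaluation import compute_auroc

    if features.node_ids != dataset.gene_net.gene_ids:
        raise ValueError("feature rows do not match the dataset's gene order")
    h0 = normalize_features(features, config.feature_norm).values
    ops = M.GraphOperators.from_dataset(dataset, config.bipartite_norm)

    assoc = dataset.associations.matrix if assoc_override is None else assoc_override
    if train_positives is None:
        rows, cols = np.nonzero(assoc)
        positives = [(int(i), int(j)) for i, j in zip(rows, cols)]
    else:
        positives = [(int(i), int(j)) for i, j in train_positives]
    if len(positives) < 2:
        raise ValueError("need at least 2 positive associations to train")
    k = len(positives)

    state = init_weights(features.feature_dim, config.hidden_dims, config.seed)
    params = _state_params(state)
    adam = _Adam(config.learning_rate)

    negatives: list[tuple[int, int]] | None = None
    history = TrainHistory([], [])
    for epoch in range(config.epochs):
        if negatives is None or config.neg_refresh == "per-epoch":
            cache = M.forward(
                ops, h0, state,
                hidden_activation=config.activation,
                cross_activation=config.cross_activation,
                final_mode=config.final_mode,
            )
            try:
                result = ns.sample_negatives(
                    dataset.associations, cache.z_d, cache.z_m, k,
                    exclude=exclude_pairs, assoc_override=assoc,
                )
                negatives = result.negative_edges
                if neg_callback is not None:
                    neg_callback(epoch, result)
            except ns.NegativeSampleShortfall as exc:
                if negatives is not None:
                    warnings.warn(
                        f"epoch {epoch}: negative-sample shortfall, reusing previous set"
                    )
                elif getattr(exc, "available", 0) >= 1:
                    # the sampler is strict; the caller may lower K
                    warnings.warn(
                        f"epoch {epoch}: only {exc.available} candidate negatives "
                        f"beyond the mean positive distance, lowering K from {k}"
                    )
                    result = ns.sample_negatives(
                        dataset.associations, cache.z_d, cache.z_m, exc.available,
                        exclude=exclude_pairs, assoc_override=assoc,
                    )
                    negatives = result.negative_edges
                    if neg_callback is not None:
                        neg_callback(epoch, result)
                else:
                    raise
        samples = ns.shuffle_samples(positives, negatives, config.seed + epoch)
        loss, grads, cache = loss_and_grads(ops, h0, state, samples, config)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
        adam.step(params, grads)

        history.loss.append(loss)
        eval_samples = val_samples if val_samples else samples
        scores = M.decode_all(cache.z_d, state.M, cache.z_m)
        lab = np.asarray([s[2] for s in eval_samples])
        sc = np.asarray([scores[s[0], s[1]] for s in eval_samples])
        if len(np.unique(lab)) == 2:
            history.val_auroc.append(compute_auroc(lab, sc))
        else:
            history.val_auroc.append(float("nan"))

    if history.loss[-1] >= history.loss[0]:
        warnings.warn(
            f"training did not reduce the loss ({history.loss[0]:.4g} -> {history.loss[-1]:.4g})"
        )
    return state, history


def predict_probabilities(
    dataset: HeteroDataset,
    features: FeatureMatrix,
    state: M.ModelState,
    config: TrainConfig,
) -> np.ndarray:
    """Decoded association probability for every (disease, miRNA) pair."""
    h0 = normalize_features(features, config.feature_norm).values
    ops = M.GraphOperators.from_dataset(dataset, config.bipartite_norm)
    cache = M.forward(
        ops, h0, state,
        hidden_activation=config.activation,
        cross_activation=config.cross_activation,
        final_mode=config.final_mode,
    )
    return M.edge_probability(M.decode_all(cache.z_d, state.M, cache.z_m))
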