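"""Centroid-distance negative sampling over unknown disease-miRNA pairs.

Verified non-associations do not exist in the curated databases: an unknown
pair may simply be untested.  Instead of sampling unknowns uniformly, the
sampler treats the K unknown pairs whose edge features lie farthest from
the centre of mass of the known positive edges as the most reliable
negatives.  An edge (d, m) is featurised by concatenating its two endpoint
embeddings, f = [z_d || z_m]; the positive centroid psi_avg is the mean
positive edge feature and dis_avg the mean Euclidean distance of positive
features to it.  Every unknown pair whose distance to psi_avg strictly
exceeds dis_avg is a candidate, and the K most distant candidates (ties
broken lexicographically by (disease, miRNA) index) become the negatives.
With K equal to the number of positives the training set holds 2K samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .graph_io import AssociationMatrix, HeteroDataset


class NegativeSampleShortfall(ValueError):
    """Fewer than K unknown pairs lie beyond the mean positive distance."""


@dataclasses.dataclass
class EdgeSample:
    """One labelled disease-miRNA pair with its edge feature and distance."""

    disease_index: int
    mirna_index: int
    label: int
    feature: np.ndarray | None = None
    distance: float | None = None


@dataclasses.dataclass
class NegativeSampleResult:
    """K selected negatives, index-aligned with their distances (descending)."""

    centroid: np.ndarray
    mean_distance: float
    negative_edges: list[tuple[int, int]]
    negative_distances: list[float]


def edge_feature(z_d: np.ndarray, z_m: np.ndarray) -> np.ndarray:
    """Concatenated endpoint feature [z_d || z_m] of length 2*F_z."""
    z_d = np.asarray(z_d, dtype=np.float64)
    z_m = np.asarray(z_m, dtype=np.float64)
    if z_d.shape != z_m.shape:
        raise ValueError(f"endpoint dims differ: {z_d.shape} vs {z_m.shape}")
    return np.concatenate([z_d, z_m])


def positive_centroid(
    positives: list[tuple[int, int]], z_d: np.ndarray, z_m: np.ndarray
) -> tuple[np.ndarray, float]:
    """Mean positive edge feature psi_avg and mean distance dis_avg to it."""
    if not positives:
        raise ValueError("empty positive set")
    d_idx = np.asarray([p[0] for p in positives])
    m_idx = np.asarray([p[1] for p in positives])
    feats = np.concatenate([z_d[d_idx], z_m[m_idx]], axis=1)
    psi = feats.mean(axis=0)
    dis_avg = float(np.linalg.norm(feats - psi, axis=1).mean())
    return psi, dis_avg


def _pair_distances(z_d: np.ndarray, z_m: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Distance of every (d, m) pair's edge feature to psi, as a d x m array.

    With concatenated features the squared distance decomposes as
    ||z_d - psi_d||^2 + ||z_m - psi_m||^2, so it is computed from the two
    endpoint tables without materialising all pair features.
    """
    fz = z_d.shape[1]
    psi_d, psi_m = psi[:fz], psi[fz:]
    sq_d = ((z_d - psi_d) ** 2).sum(axis=1)
    sq_m = ((z_m - psi_m) ** 2).sum(axis=1)
    return np.sqrt(sq_d[:, None] + sq_m[None, :])


def sample_negatives(
    dataset: HeteroDataset | AssociationMatrix,
    z_d: np.ndarray,
    z_m: np.ndarray,
    k: int,
    exclude: set[tuple[int, int]] | None = None,
    assoc_override: np.ndarray | None = None,
) -> NegativeSampleResult:
    """Select the K unknown pairs farthest beyond the mean positive distance.

    Parameters
    ----------
    dataset
        Source of the association labels (a full dataset or the bare matrix).
    z_d, z_m
        Current disease and miRNA embeddings.
    k
        Number of negatives; the training convention is K = #positives.
    exclude
        Extra (disease, miRNA) index pairs barred from the candidate pool
        (e.g. held-out test edges during cross-validation).
    assoc_override
        Alternative binary label matrix (e.g. with held-out positives
        masked); defaults to the dataset's matrix.

    Raises
    ------
    NegativeSampleShortfall
        If fewer than K unknown pairs have distance strictly above dis_avg.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    assoc = dataset.matrix if isinstance(dataset, AssociationMatrix) else dataset.associations.matrix
    if assoc_override is not None:
        assoc = assoc_override
    positives = list(zip(*np.nonzero(assoc)))
    positives = [(int(i), int(j)) for i, j in positives]
    psi, dis_avg = positive_centroid(positives, z_d, z_m)

    dist = _pair_distances(z_d, z_m, psi)
    unknown = assoc == 0
    if exclude:
        for i, j in exclude:
            unknown[i, j] = False
    candidate_mask = unknown & (dist > dis_avg)
    cand_i, cand_j = np.nonzero(candidate_mask)
    n_cand = cand_i.size
    if n_cand < k:
        err = NegativeSampleShortfall(
            f"only {n_cand} unknown pairs beyond dis_avg={dis_avg:.6g}, need {k}"
        )
        err.available = n_cand
        raise err
    cand_d = dist[cand_i, cand_j]
    # largest distance first; ties by (disease, miRNA) ascending
    order = np.lexsort((cand_j, cand_i, -cand_d))[:k]
    edges = [(int(cand_i[t]), int(cand_j[t])) for t in order]
    distances = [float(cand_d[t]) for t in order]
    return NegativeSampleResult(psi, dis_avg, edges, distances)


def shuffle_samples(
    positives: list[tuple[int, int]],
    negatives: list[tuple[int, int]],
    seed: int,
) -> list[tuple[int, int, int]]:
    """Interleave positives (label 1) and negatives (label 0) in seeded order.

    Labels travel with their edges; the output is a permutation of the
    concatenated sample list, deterministic per seed.
    """
    samples = [(i, j, 1) for i, j in positives] + [(i, j, 0) for i, j in negatives]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    return [samples[t] for t in perm]
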