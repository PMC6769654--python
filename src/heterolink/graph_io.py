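"""Reading, validation and assembly of the four-network heterogeneous dataset.

The prediction task lives on four networks: an undirected gene-gene (PPI)
backbone, two bipartite attachment networks (miRNA->gene targets and
disease->gene annotations), and the known disease-miRNA associations.  All
feature propagation is anchored on the PPI gene set, so miRNA and disease
nodes whose gene neighbours fall entirely outside the PPI carry no signal
and are removed during assembly, together with any associations that
reference them.

Edge lists are plain TSV/whitespace files, one edge per line, ``#`` comments
allowed, extra columns (e.g. weights) ignored — the backbone is treated as
unweighted and undirected.  Node identifiers are compared verbatim: MeSH and
Entrez identifiers are case-significant, so no case folding is applied.
miRNA, disease and gene identifiers live in disjoint namespaces enforced by
the ``kind`` argument rather than by string prefixes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp
import yaml

EDGE_KINDS = ("gene-gene", "mirna-gene", "disease-gene", "disease-mirna")

#: manifest keys naming the four edge-list files, in assembly order
MANIFEST_KEYS = ("gene_gene", "mirna_gene", "disease_gene", "disease_mirna")


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list files."""


class AssemblyError(ValueError):
    """Raised when filtering leaves no trainable associations."""


def load_edge_list(path: str | Path, kind: str) -> set[tuple[str, str]]:
    """Read a two-column edge list and return the deduplicated edge set.

    Parameters
    ----------
    path
        File with one edge per line: two whitespace/tab separated node
        identifiers; further columns are ignored.  Blank lines and lines
        starting with ``#`` are skipped.
    kind
        One of :data:`EDGE_KINDS`.  For ``gene-gene`` the edge is
        undirected: ``(a, b)`` and ``(b, a)`` collapse to one edge stored
        with endpoints sorted; self-loops are dropped (the backbone has no
        self-loops before the convolutional self-loop augmentation).

    Raises
    ------
    EdgeListError
        If a non-comment line has fewer than two tokens (the message names
        the line number) or if no edges remain.
    """
    if kind not in EDGE_KINDS:
        raise ValueError(f"unknown edge kind {kind!r}; expected one of {EDGE_KINDS}")
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            a, b = tokens[0], tokens[1]
            if kind == "gene-gene":
                if a == b:
                    continue  # self-interaction carries no backbone edge
                edges.add((a, b) if a <= b else (b, a))
            else:
                edges.add((a, b))
    if not edges:
        raise EdgeListError(f"{path}: no edges found")
    return edges


def write_edge_list(path: str | Path, edges: Iterable[tuple[str, str]], header: str | None = None) -> None:
    """Write an edge set as a two-column TSV, sorted for reproducibility."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


@dataclasses.dataclass
class GeneNetwork:
    """Undirected, unweighted gene-gene (PPI) graph.

    ``adjacency`` is a binary symmetric CSR matrix with zero diagonal whose
    row/column order follows ``gene_ids``.
    """

    gene_ids: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_edges(cls, edges: set[tuple[str, str]]) -> "GeneNetwork":
        gene_ids = sorted({g for e in edges for g in e})
        idx = {g: i for i, g in enumerate(gene_ids)}
        rows, cols = [], []
        for a, b in edges:
            ia, ib = idx[a], idx[b]
            rows.extend((ia, ib))
            cols.extend((ib, ia))
        data = np.ones(len(rows), dtype=np.float64)
        adj = sp.csr_matrix((data, (rows, cols)), shape=(len(gene_ids), len(gene_ids)))
        adj.data[:] = 1.0  # defensive: duplicates collapse to binary
        return cls(gene_ids, adj)

    def edge_set(self) -> set[tuple[str, str]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return {
            (self.gene_ids[i], self.gene_ids[j]) if self.gene_ids[i] <= self.gene_ids[j]
            else (self.gene_ids[j], self.gene_ids[i])
            for i, j in zip(coo.row, coo.col)
        }


@dataclasses.dataclass
class BipartiteNetwork:
    """miRNA->gene or disease->gene incidence, columns indexed by the gene order."""

    row_ids: list[str]
    col_ids: list[str]
    incidence: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.incidence.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("incidence shape does not match id lists")

    @property
    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def edge_set(self) -> set[tuple[str, str]]:
        coo = self.incidence.tocoo()
        return {(self.row_ids[i], self.col_ids[j]) for i, j in zip(coo.row, coo.col)}


@dataclasses.dataclass
class AssociationMatrix:
    """Binary d x m disease-miRNA association labels (1 = known association)."""

    disease_ids: list[str]
    mirna_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        d, m = len(self.disease_ids), len(self.mirna_ids)
        if self.matrix.shape != (d, m):
            raise ValueError("association matrix shape mismatch")
        vals = np.unique(self.matrix)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("association matrix must be binary")

    @property
    def n_positives(self) -> int:
        return int(self.matrix.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.matrix)
        return list(zip(rows.tolist(), cols.tolist()))

    def edge_set(self) -> set[tuple[str, str]]:
        return {
            (self.disease_ids[i], self.mirna_ids[j])
            for i, j in zip(*np.nonzero(self.matrix))
        }


@dataclasses.dataclass
class HeteroDataset:
    """One consistent heterogeneous dataset sharing a single gene ordering."""

    gene_net: GeneNetwork
    mirna_gene: BipartiteNetwork
    disease_gene: BipartiteNetwork
    associations: AssociationMatrix

    def __post_init__(self) -> None:
        genes = self.gene_net.gene_ids
        if self.mirna_gene.col_ids != genes or self.disease_gene.col_ids != genes:
            raise ValueError("bipartite networks do not share the gene ordering")
        if self.associations.disease_ids != self.disease_gene.row_ids:
            raise ValueError("association disease ids do not match disease-gene rows")
        if self.associations.mirna_ids != self.mirna_gene.row_ids:
            raise ValueError("association miRNA ids do not match miRNA-gene rows")

    @property
    def n_genes(self) -> int:
        return self.gene_net.n_genes

    @property
    def n_diseases(self) -> int:
        return len(self.associations.disease_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.associations.mirna_ids)


def _bipartite_from_edges(
    edges: set[tuple[str, str]], gene_index: dict[str, int], gene_ids: list[str]
) -> BipartiteNetwork:
    kept = [(r, g) for r, g in edges if g in gene_index]
    row_ids = sorted({r for r, _ in kept})
    row_index = {r: i for i, r in enumerate(row_ids)}
    rows = [row_index[r] for r, g in kept]
    cols = [gene_index[g] for r, g in kept]
    inc = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(row_ids), len(gene_ids))
    )
    inc.data[:] = 1.0
    return BipartiteNetwork(row_ids, gene_ids, inc)


def assemble(
    gene_edges: set[tuple[str, str]],
    mg_edges: set[tuple[str, str]],
    dg_edges: set[tuple[str, str]],
    dm_edges: set[tuple[str, str]],
) -> HeteroDataset:
    """Anchor every network on the PPI gene universe and drop orphans.

    The gene universe is the set of genes appearing in the PPI edge set.
    Bipartite edges pointing outside the universe are dropped; miRNA or
    disease nodes left with no surviving gene link are removed (a node with
    no PPI-anchored gene receives no propagated features and is untrainable);
    associations referencing removed nodes are removed in turn.  A node is
    removed only when *none* of its genes are in the PPI — the least
    destructive reading of PPI anchoring.

    Raises
    ------
    AssemblyError
        If no disease-miRNA association survives filtering.
    """
    gene_net = GeneNetwork.from_edges(gene_edges)
    gene_index = gene_net.index
    mirna_gene = _bipartite_from_edges(mg_edges, gene_index, gene_net.gene_ids)
    disease_gene = _bipartite_from_edges(dg_edges, gene_index, gene_net.gene_ids)

    d_index = disease_gene.row_index
    m_index = mirna_gene.row_index
    kept_assoc = [(d, m) for d, m in dm_edges if d in d_index and m in m_index]
    if not kept_assoc:
        raise AssemblyError("no trainable associations after PPI-anchored filtering")

    matrix = np.zeros((len(disease_gene.row_ids), len(mirna_gene.row_ids)), dtype=np.int8)
    for d, m in kept_assoc:
        matrix[d_index[d], m_index[m]] = 1
    associations = AssociationMatrix(disease_gene.row_ids, mirna_gene.row_ids, matrix)
    return HeteroDataset(gene_net, mirna_gene, disease_gene, associations)


def load_manifest(path: str | Path) -> dict[str, Path]:
    """Read a YAML manifest naming the four edge-list files.

    Keys: ``gene_gene``, ``mirna_gene``, ``disease_gene``, ``disease_mirna``.
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise EdgeListError(f"{path}: manifest must be a mapping")
    missing = [k for k in MANIFEST_KEYS if k not in raw]
    if missing:
        raise EdgeListError(f"{path}: manifest missing keys {missing}")
    return {k: (path.parent / raw[k]).resolve() for k in MANIFEST_KEYS}


def load_dataset(manifest_path: str | Path) -> HeteroDataset:
    """Load and assemble the four networks named by a manifest file."""
    paths = load_manifest(manifest_path)
    return assemble(
        load_edge_list(paths["gene_gene"], "gene-gene"),
        load_edge_list(paths["mirna_gene"], "mirna-gene"),
        load_edge_list(paths["disease_gene"], "disease-gene"),
        load_edge_list(paths["disease_mirna"], "disease-mirna"),
    )
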