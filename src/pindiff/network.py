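"""Static interaction network and its projection onto per-sample transcriptomes.

A sample-specific network is the subgraph of the static protein interaction
network induced on the genes expressed in that sample.  For RNA-seq the
expressed/not-expressed cut is 1 RPKM; for array intensities the cut is the
value sitting at the same percentile of the array matrix as 1 RPKM does in a
reference RNA-seq matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io import EdgeList, ExpressionMatrix

__all__ = [
    "WeightedNetwork",
    "SampleNetwork",
    "expression_threshold",
    "project",
]

RNASEQ_THRESHOLD = 1.0  # RPKM


@dataclass
class WeightedNetwork:
    """Weighted undirected graph: node order, symmetric adjacency, weighted degrees."""

    nodes: list[str]
    adjacency: sp.csr_matrix  # symmetric, zero diagonal
    node_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if (self.adjacency != self.adjacency.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.node_index = {g: i for i, g in enumerate(self.nodes)}

    @classmethod
    def from_edge_list(cls, edges: EdgeList) -> "WeightedNetwork":
        nodes = edges.genes
        index = {g: i for i, g in enumerate(nodes)}
        ia = edges.edges["gene_a"].map(index).to_numpy()
        ib = edges.edges["gene_b"].map(index).to_numpy()
        w = edges.edges["weight"].to_numpy(dtype=float)
        n = len(nodes)
        adj = sp.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([ia, ib]), np.concatenate([ib, ia]))),
            shape=(n, n),
        ).tocsr()
        return cls(nodes, adj)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree of each node (row sums of the adjacency)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class SampleNetwork:
    """Expression-induced subgraph of a :class:`WeightedNetwork` for one sample."""

    sample_id: str
    parent: WeightedNetwork
    expressed: list[str]  # genes of the parent that pass the threshold
    adjacency: sp.csr_matrix
    node_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.node_index = {g: i for i, g in enumerate(self.expressed)}

    @property
    def nodes(self) -> list[str]:
        return self.expressed

    @property
    def n_nodes(self) -> int:
        return len(self.expressed)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def n_components(self) -> int:
        n, _ = connected_components(self.adjacency, directed=False)
        return n

    def seed_vector(self, genes: set[str]) -> np.ndarray:
        """Binary prior-knowledge vector: 1 at annotated genes present in the sample."""
        y = np.zeros(self.n_nodes)
        for g in genes:
            i = self.node_index.get(g)
            if i is not None:
                y[i] = 1.0
        return y


def expression_threshold(
    matrix: ExpressionMatrix,
    reference: ExpressionMatrix | None = None,
) -> float:
    """Expressed/not-expressed cut for a matrix.

    RNA-seq matrices use 1 RPKM.  Array matrices require an RNA-seq
    ``reference``: the returned threshold is the value of the array matrix at
    the same (global, linearly interpolated) percentile that 1 RPKM occupies
    among all entries of the reference.
    """
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    if matrix.platform == "rnaseq":
        return RNASEQ_THRESHOLD
    if reference is None:
        raise ValueError("array platform requires a reference RNA-seq matrix")
    if reference.platform != "rnaseq":
        raise ValueError("reference matrix must be RNA-seq")
    ref = reference.values.to_numpy().ravel()
    q = float(np.mean(ref < RNASEQ_THRESHOLD))
    return float(np.quantile(matrix.values.to_numpy().ravel(), q))


def project(
    network: WeightedNetwork,
    matrix: ExpressionMatrix,
    sample_id: str,
    threshold: float | None = None,
) -> SampleNetwork:
    """Induce the subgraph on genes expressed (>= threshold) in ``sample_id``.

    Genes of the network absent from the expression matrix are treated as
    unexpressed.  Isolated expressed nodes are retained.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    if sample_id not in matrix.values.columns:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    if threshold is None:
        threshold = expression_threshold(matrix)
    expr = matrix.values[sample_id]
    expressed_set = set(expr.index[expr.to_numpy() >= threshold])
    keep = [g for g in network.nodes if g in expressed_set]
    if not keep:
        raise ValueError(f"sample {sample_id!r}: no expressed genes in the network")
    idx = np.array([network.node_index[g] for g in keep])
    sub = network.adjacency[idx][:, idx].tocsr()
    return SampleNetwork(sample_id, network, keep, sub)


def projection_summary(net: SampleNetwork) -> dict:
    """Per-sample network statistics (node/edge/component counts)."""
    return {
        "sample": net.sample_id,
        "n_expressed": net.n_nodes,
        "n_edges": net.n_edges,
        "n_components": net.n_components,
    }
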