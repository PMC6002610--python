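"""Thresholded Pearson correlation graphs and Markov clustering.

Sample-to-sample graphs (nodes = samples, correlated over genes) expose the
dominant structure of an experiment — litter of origin on all genes, treatment
on differentially expressed genes — while gene-to-gene graphs at a high
threshold capture co-expression modules. Edges keep the signed correlation:
r >= threshold, so anti-correlated pairs are never connected (BioLayout /
Graphia convention). Clustering is the Markov Cluster algorithm (MCL):
alternate expansion (matrix squaring of the column-stochastic transition
matrix) and inflation (elementwise powering, here 2.2 by default) until the
matrix stops changing; clusters are read off the limit matrix's attractor
structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .io import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class CorrelationGraph:
    """Undirected graph of nodes passing a signed Pearson threshold."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (i, j, r) with i before j in nodes
    threshold: float
    axis: str  # "samples" | "genes"

    def __post_init__(self) -> None:
        for i, j, w in self.edges:
            if i == j:
                raise ValueError("self-edges are not stored")
            if w < self.threshold - 1e-12 or abs(w) > 1 + 1e-12:
                raise ValueError(f"edge ({i},{j}) weight {w} violates "
                                 "threshold/correlation bounds")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sparse.csr_matrix:
        n = len(self.nodes)
        pos = {v: k for k, v in enumerate(self.nodes)}
        if not self.edges:
            return sparse.csr_matrix((n, n))
        rows, cols, data = [], [], []
        for i, j, w in self.edges:
            a, b = pos[i], pos[j]
            rows += [a, b]
            cols += [b, a]
            data += [w, w]
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold, axis=self.axis)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


def correlation_graph(expr: ExpressionMatrix, axis: str = "samples",
                      threshold: float = 0.99,
                      log_transform: bool = True) -> CorrelationGraph:
    """Build the thresholded Pearson graph along ``axis``.

    Correlations are computed on log2(value + 1) by default (for counts, TPM
    or CPM; a matrix already tagged log2 is used as-is). Profiles with zero
    variance get no edges and a logged warning; the threshold applies to the
    signed r, so only positive co-variation connects nodes.
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    x = expr.values.to_numpy(dtype=float)
    if log_transform and expr.unit != "log2":
        x = np.log2(x + 1.0)
    if axis == "samples":
        x = x.T
        nodes = expr.sample_ids
    else:
        nodes = expr.gene_ids
    if x.shape[1] < 3:
        raise ValueError("need at least 3 observations along the correlated axis")
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        log.warning("%d zero-variance profile(s) retained without edges",
                    int(flat.sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[~np.isfinite(r)] = 0.0
    iu, ju = np.triu_indices(len(nodes), k=1)
    hit = r[iu, ju] >= threshold
    edges = [(nodes[a], nodes[b], float(np.clip(r[a, b], -1.0, 1.0)))
             for a, b in zip(iu[hit], ju[hit])]
    return CorrelationGraph(list(nodes), edges, threshold, axis)


@dataclass
class Clustering:
    """Node -> cluster map; clusters numbered 1..k by descending size.

    Every node is assigned; clusters smaller than ``min_size`` stay in the
    map but are flagged via :meth:`small_clusters`.
    """

    assignments: dict[str, int]
    min_size: int = 3
    converged: bool = True

    def sizes(self) -> pd.Series:
        return pd.Series(self.assignments).value_counts().sort_index()

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def small_clusters(self) -> list[int]:
        sz = self.sizes()
        return list(sz.index[sz < self.min_size])

    def labels(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.assignments[n] for n in nodes])

    def to_tsv(self, path) -> None:
        pd.Series(self.assignments, name="cluster").to_csv(
            path, sep="\t", index_label="node")


def _number_clusters(groups: list[list[str]]) -> dict[str, int]:
    # descending size, ties by smallest member label -> input-order invariant
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    return {node: k for k, grp in enumerate(ordered, start=1) for node in grp}


def mcl_cluster(graph: CorrelationGraph, inflation: float = 2.2,
                max_iter: int = 100, tol: float = 1e-6,
                prune: float = 1e-8, min_size: int = 3) -> Clustering:
    """Markov clustering of a correlation graph.

    Self-loops are added with each node's maximum incident edge weight
    (1 for isolated nodes), columns normalised to a stochastic matrix, then
    expansion (M @ M) alternates with inflation (elementwise power and
    renormalisation) until the largest entry change drops below ``tol`` or
    ``max_iter`` is hit (a warning is logged and the current clustering
    returned). Clusters are the connected components of the limit matrix's
    nonzero pattern, so nodes from different components of the input graph
    are never merged.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    a = graph.adjacency().tolil()
    n = len(graph.nodes)
    maxw = np.asarray(abs(a).max(axis=1).todense()).ravel()
    loops = np.where(maxw > 0, maxw, 1.0)
    a.setdiag(loops)
    m = sparse.csr_matrix(a)

    def normalise(mat: sparse.csr_matrix) -> sparse.csr_matrix:
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        d = sparse.diags(1.0 / colsum)
        return (mat @ d).tocsr()

    m = normalise(m)
    converged = False
    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m                      # expansion
        m.data **= inflation           # inflation
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
        m = normalise(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge in %d iterations; returning the "
                    "current clustering", max_iter)

    pattern = ((m + m.T) > 0).astype(np.int8)
    _, labels = connected_components(pattern, directed=False)
    groups: dict[int, list[str]] = {}
    for node, lab in zip(graph.nodes, labels):
        groups.setdefault(int(lab), []).append(node)
    return Clustering(_number_clusters(list(groups.values())),
                      min_size=min_size, converged=converged)


def export_graph(graph: CorrelationGraph, clustering: Clustering | None,
                 path: str | Path,
                 node_attrs: pd.DataFrame | None = None) -> None:
    """Write a GraphML file with cluster labels and optional node metadata.

    The export is lossless for the graph structure, edge weights, cluster
    ids and any supplied per-node attribute columns, and can be read back
    with :func:`read_graphml`.
    """
    g = graph.to_networkx()
    if clustering is not None:
        missing = set(graph.nodes) - set(clustering.assignments)
        if missing:
            raise ValueError(f"clustering does not cover node(s): "
                             f"{sorted(missing)[:5]}")
        nx.set_node_attributes(
            g, {v: int(clustering.assignments[v]) for v in graph.nodes},
            "cluster")
    if node_attrs is not None:
        for col in node_attrs.columns:
            values = {v: node_attrs.loc[v, col] for v in graph.nodes
                      if v in node_attrs.index}
            nx.set_node_attributes(g, values, str(col))
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
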