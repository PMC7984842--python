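"""Protein covariation network: construction, denoising and module detection.

The graph is the complete, signed, weighted Pearson-correlation matrix of
protein log2 profiles over the biological samples. It is denoised by Network
Enhancement — a diffusion re-weighting of a symmetric non-negative kernel
(k-nearest-neighbour truncation, row-stochastic 'ave' normalization, a
transition-field construction, and the closed-form eigenvalue update
d -> (1-alpha) d / (1 - alpha d^order)) that amplifies consistently strong
edges and suppresses weak, inconsistent ones. Modules are found by Leiden
optimization of the asymptotic Surprise quality

    S = m * KL(q || <q>)

where m is the total edge weight, q the fraction of edge weight inside
modules and <q> the fraction of node pairs inside modules: the statistical
unexpectedness of the observed within-module edge concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd

from .io import DataError, ProteinMatrix, SampleDesign

__all__ = [
    "CovariationGraph",
    "Partition",
    "covariation_matrix",
    "network_enhancement",
    "surprise_quality",
    "partition_surprise_leiden",
    "module_viz_threshold",
]


@dataclass
class CovariationGraph:
    nodes: list[str]
    weights: np.ndarray  # symmetric; diagonal ignored by consumers
    enhanced: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node count")
        if np.max(np.abs(W - W.T)) > 1e-9:
            raise ValueError("weight matrix is not symmetric")
        if self.enhanced and (W < 0).any():
            raise ValueError("enhanced graph must be non-negative")
        self.weights = (W + W.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.nodes)

    def offdiag(self) -> np.ndarray:
        W = self.weights.copy()
        np.fill_diagonal(W, 0.0)
        return W

    def to_igraph(self) -> ig.Graph:
        W = self.offdiag()
        iu = np.triu_indices(self.n, k=1)
        mask = W[iu] > 0
        edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
        g = ig.Graph(n=self.n, edges=edges)
        g.es["weight"] = W[iu][mask].tolist()
        g.vs["name"] = list(self.nodes)
        return g

    def module_edge_list(self, partition: "Partition") -> pd.DataFrame:
        """Per-module (source, target, weight) rows for positive edges."""
        W = self.offdiag()
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                mi = partition.module_of[self.nodes[i]]
                if W[i, j] > 0 and mi == partition.module_of[self.nodes[j]]:
                    rows.append((mi, self.nodes[i], self.nodes[j], W[i, j]))
        return pd.DataFrame(rows, columns=["module", "source", "target", "weight"])


@dataclass
class Partition:
    """Protein → module assignment with its Surprise quality."""

    module_of: dict[str, str]  # node -> module id ("M1" is the largest)
    quality: float
    seed: int
    n_restarts: int
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes = list(self.module_of)

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def members(self, module_id: str) -> list[str]:
        return [n for n in self.nodes if self.module_of[n] == module_id]

    @staticmethod
    def sort_key(module_id: str):
        return (len(module_id), module_id)

    def membership(self, nodes: list[str]) -> np.ndarray:
        labels = sorted(set(self.module_of.values()), key=self.sort_key)
        idx = {m: i for i, m in enumerate(labels)}
        return np.array([idx[self.module_of[n]] for n in nodes])


def covariation_matrix(
    matrix: ProteinMatrix | pd.DataFrame, design: SampleDesign, log2: bool = True
) -> CovariationGraph:
    """Pairwise Pearson correlation over biological samples (SPQC excluded).

    Computed on log2 intensities by default (a flag exposes the linear
    scale). A protein with zero variance has no defined correlation and is
    reported by name.
    """
    values = matrix.values if isinstance(matrix, ProteinMatrix) else matrix
    cols = [c for c in design.biological["sample_id"] if c in values.columns]
    X = values[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DataError("covariation requires a complete matrix; impute first")
    if log2:
        if (X <= 0).any():
            raise DataError("non-positive intensity; cannot log2-transform")
        X = np.log2(X)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = values.index[int(np.argmax(sd == 0))]
        raise DataError(f"protein {bad!r} has zero variance; correlation undefined")
    W = np.corrcoef(X)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return CovariationGraph(list(values.index), W, enhanced=False)


# ---------------------------------------------------------------------------
# Network Enhancement


def _ne_dn(w: np.ndarray) -> np.ndarray:
    """Row-stochastic 'ave' normalization (after scaling by n)."""
    w = w * len(w)
    deg = np.abs(w).sum(axis=1) + np.finfo(float).eps
    return w / deg[:, None]


def _dominate_set(aff: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest entries per row, then symmetrize by averaging."""
    n = len(aff)
    out = np.zeros_like(aff)
    for i in range(n):
        idx = np.argsort(aff[i], kind="stable")[::-1][:k]
        out[i, idx] = aff[i, idx]
    return (out + out.T) / 2.0


def _transition_fields(W: np.ndarray) -> np.ndarray:
    zero_rows = W.sum(axis=1) == 0
    W = _ne_dn(W * len(W))
    w = np.sqrt(np.abs(W).sum(axis=0) + np.finfo(float).eps)
    W = W / w[None, :]
    W = W @ W.T
    W[zero_rows, :] = 0.0
    W[:, zero_rows] = 0.0
    return W


def network_enhancement(
    graph: CovariationGraph,
    k_neighbors: int | None = None,
    alpha: float = 0.9,
    diffusion_order: int = 2,
    clip_negative: bool = True,
) -> CovariationGraph:
    """Diffusion-based re-weighting of the covariation kernel.

    Negative correlations are clipped to zero by default (``clip_negative``;
    set False to use absolute values) before enhancement, since the diffusion
    and the downstream community detection operate on a non-negative kernel.
    Disconnected components never exchange weight: every step acts within the
    block structure of the input.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if diffusion_order < 1:
        raise ValueError("diffusion_order must be >= 1")
    n = graph.n
    if k_neighbors is None:
        k_neighbors = min(20, int(np.ceil(n / 10)))
    if not 1 <= k_neighbors < n:
        raise ValueError("k_neighbors must be in [1, n)")

    W_in = graph.offdiag()
    W_in = np.clip(W_in, 0.0, None) if clip_negative else np.abs(W_in)

    active = np.abs(W_in).sum(axis=1) > 0
    idx = np.flatnonzero(active)
    W0 = W_in[np.ix_(idx, idx)]
    DD = np.abs(W0).sum(axis=1)

    W = _ne_dn(W0)
    W = (W + W.T) / 2.0
    if len(np.unique(W)) <= 2:
        P = W
    else:
        P = _dominate_set(np.abs(W), min(k_neighbors, len(W) - 1)) * np.sign(W)
    P = P + np.eye(len(P)) + np.diag(np.abs(P).sum(axis=1))
    P = _transition_fields(P)

    d, U = np.linalg.eigh(P)
    d = d - np.finfo(float).eps
    d = (1.0 - alpha) * d / (1.0 - alpha * d**diffusion_order)
    W = (U * d) @ U.T

    diag = np.diag(W).copy()
    np.fill_diagonal(W, 0.0)
    W = W / np.maximum(1.0 - diag, np.finfo(float).eps)[:, None]
    W = DD[:, None] * W
    W[W < 0] = 0.0
    W = (W + W.T) / 2.0

    out = np.zeros_like(W_in)
    out[np.ix_(idx, idx)] = W
    return CovariationGraph(list(graph.nodes), out, enhanced=True)


# ---------------------------------------------------------------------------
# Surprise quality and Leiden clustering


def surprise_quality(graph: CovariationGraph, partition: Partition) -> float:
    """Asymptotic Surprise S = m * KL(q || <q>) (natural log).

    m: total (off-diagonal, upper-triangle) edge weight; q: intra-module
    share of edge weight; <q>: intra-module share of node pairs. S >= 0,
    and S = 0 when q equals <q> (e.g. the single-module partition).
    """
    W = graph.offdiag()
    if (W < 0).any():
        raise ValueError("Surprise requires non-negative weights")
    n = graph.n
    memb = partition.membership(graph.nodes)
    iu = np.triu_indices(n, k=1)
    w = W[iu]
    m = w.sum()
    if m <= 0:
        return 0.0
    intra = memb[iu[0]] == memb[iu[1]]
    q = w[intra].sum() / m
    total_pairs = n * (n - 1) / 2
    qe = intra.sum() / total_pairs

    def xlogx_ratio(a, b):
        if a <= 0:
            return 0.0
        if b <= 0:
            return np.inf
        return a * np.log(a / b)

    return float(m * (xlogx_ratio(q, qe) + xlogx_ratio(1 - q, 1 - qe)))


def _relabel_by_size(memb: np.ndarray, nodes: list[str]) -> dict[str, str]:
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, c in enumerate(memb):
        sizes[c] = sizes.get(c, 0) + 1
        first.setdefault(c, i)
    order = sorted(sizes, key=lambda c: (-sizes[c], first[c]))
    rename = {c: f"M{r + 1}" for r, c in enumerate(order)}
    return {node: rename[c] for node, c in zip(nodes, memb)}


def partition_surprise_leiden(
    graph: CovariationGraph, seed: int = 0, n_restarts: int = 100
) -> Partition:
    """Best-of-``n_restarts`` Leiden optimization of Surprise.

    Module ids are relabeled M1, M2, ... by descending size (ties by first
    appearance). Deterministic for a fixed (graph, seed, n_restarts).
    """
    if graph.n == 0:
        raise ValueError("empty graph")
    if (graph.offdiag() < 0).any():
        raise ValueError("Leiden-Surprise requires non-negative weights; enhance or clip first")
    g = graph.to_igraph()
    best: tuple[float, np.ndarray] | None = None
    for r in range(n_restarts):
        part = la.find_partition(
            g, la.SurpriseVertexPartition, weights="weight",
            seed=int(seed) + r, n_iterations=-1,
        )
        memb = np.array(part.membership)
        p = Partition(dict(zip(graph.nodes, memb.astype(str))), 0.0, seed, 1, list(graph.nodes))
        s = surprise_quality(graph, p)
        if best is None or s > best[0]:
            best = (s, memb)
    module_of = _relabel_by_size(best[1], graph.nodes)
    return Partition(module_of, float(best[0]), int(seed), int(n_restarts), list(graph.nodes))


# ---------------------------------------------------------------------------
# visualization threshold


def module_viz_threshold(
    graph: CovariationGraph, partition: Partition, module_id: str
) -> tuple[float, pd.DataFrame, pd.Series]:
    """Thin a module subgraph to its strongest connected backbone.

    Edges are removed one at a time in ascending weight order (ties by node
    order) until removing the next would split the subgraph; the returned
    threshold is the weight of that first unremovable edge. Also returns the
    weighted degree centrality of each member node in the full module
    subgraph. A module that is already disconnected is returned unchanged
    with a warning.
    """
    members = partition.members(module_id)
    if not members:
        raise ValueError(f"module {module_id!r} has no members")
    pos = {n: i for i, n in enumerate(graph.nodes)}
    W = graph.offdiag()
    edges = []
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            w = W[pos[members[a]], pos[members[b]]]
            if w > 0:
                edges.append((members[a], members[b], float(w)))
    degree = pd.Series(0.0, index=members)
    for u, v, w in edges:
        degree[u] += w
        degree[v] += w

    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(members)
    G.add_weighted_edges_from(edges)
    frame = lambda es: pd.DataFrame(es, columns=["source", "target", "weight"])
    if len(members) > 1 and not nx.is_connected(G):
        warnings.warn(f"module {module_id!r} subgraph is disconnected; no thresholding applied")
        return 0.0, frame(edges), degree

    ordered = sorted(edges, key=lambda e: (e[2], e[0], e[1]))
    threshold = ordered[0][2] if ordered else 0.0
    for u, v, w in ordered:
        G.remove_edge(u, v)
        if not nx.is_connected(G):
            G.add_edge(u, v, weight=w)
            threshold = w
            break
        threshold = w
    retained = [(u, v, d["weight"]) for u, v, d in G.edges(data=True)]
    retained.sort(key=lambda e: (e[2], e[0], e[1]))
    return float(threshold), frame(retained), degree
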