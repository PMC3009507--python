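"""Topological proximity in interaction networks and its relation to
functional similarity.

Proximity of node j to node i is measured with a random walk with restart
(RWR): a walk starts at i, moves to a neighbor with probability
proportional to edge weight, and at every step returns to i with restart
probability c.  The stationary distribution p satisfies

    p = (1 - c) W^T p + c e_i

where W is the row-stochastic transition matrix and e_i the restart
vector.  The stationary mass at j is the proximity of j to i.  The
measure is asymmetric; the pairwise proximity used downstream averages
the two directions.  Small c lets the walk explore farther; c = 1 keeps
it pinned at the source.  Compared with shortest-path distance, RWR
integrates over all paths, making it robust to single missing or
spurious edges.

The correlation analysis z-normalizes molecule-pair similarity scores,
groups node pairs into equal-count proximity bins, and reports per-bin
mean similarity plus the Pearson correlation over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import pearsonr

from .ontology import AnnotationCorpus
from .similarity import pair_similarity

__all__ = [
    "InteractionGraph",
    "ProximityMatrix",
    "rwr_proximity",
    "shortest_path_matrix",
    "znormalize",
    "bin_and_average",
    "proximity_similarity_pairs",
    "proximity_similarity_correlation",
    "restart_sweep",
    "UNREACHABLE",
]

#: Sentinel for unreachable node pairs in shortest-path matrices.
UNREACHABLE = np.inf


class InteractionGraph:
    """An undirected, weighted molecular interaction network.

    Built from ``(u, v)`` or ``(u, v, weight)`` edges; duplicate edges are
    merged by summing weights, self-loops are rejected, weights must be
    positive.  Node ordering is lexicographic and deterministic.
    """

    def __init__(self, edges: Iterable[tuple], nodes: Iterable[str] = ()) -> None:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 2:
                u, v, w = *edge, 1.0
            else:
                u, v, w = edge
            w = float(w)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            if w <= 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
        self._graph = g
        self.nodes: list[str] = sorted(g.nodes)
        self._index = {n: i for i, n in enumerate(self.nodes)}

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionGraph":
        return cls(((u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)),
                   nodes=g.nodes)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric weighted adjacency in the canonical node order."""
        return nx.to_scipy_sparse_array(
            self._graph, nodelist=self.nodes, weight="weight", format="csr"
        )


@dataclass
class ProximityMatrix:
    """Pairwise node proximity scores.

    ``matrix`` holds the symmetrized scores for ``kind="rwr"`` (average
    of the two walk directions) or BFS hop counts for
    ``kind="shortest_path"`` with ``inf`` marking unreachable pairs.
    ``raw`` keeps the pre-symmetrization RWR matrix (row i = stationary
    distribution of the walk restarting at node i; rows sum to 1).
    """

    nodes: list[str]
    matrix: np.ndarray
    kind: str
    c: float | None = None
    raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def value(self, u: str, v: str) -> float:
        return float(self.matrix[self._index[u], self._index[v]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.nodes, columns=self.nodes)


def rwr_proximity(
    graph: InteractionGraph,
    c: float = 0.3,
    tolerance: float = 1e-10,
    max_iter: int = 1000,
) -> ProximityMatrix:
    """Random-walk-with-restart proximity for every source node.

    Iterates ``p <- (1 - c) W^T p + c e_i`` per source until the L1
    change drops below ``tolerance``.  Isolated (degree-zero) nodes are
    absorbing at the source: mass reaching them restarts.  The returned
    matrix averages proximity over the two directions of each pair; the
    pre-symmetrization matrix is kept in ``raw``.

    Raises
    ------
    ValueError
        For a restart probability outside (0, 1].
    RuntimeError
        If any source fails to converge within ``max_iter`` iterations;
        the message carries the worst residual.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {c}")
    n = len(graph)
    a = graph.adjacency().toarray().astype(float)
    degrees = a.sum(axis=1)
    dangling = degrees == 0
    w = np.zeros_like(a)
    nz = ~dangling
    w[nz] = a[nz] / degrees[nz, None]
    wt = w.T
    raw = np.zeros((n, n))
    worst_residual = 0.0
    for i in range(n):
        p = np.zeros(n)
        p[i] = 1.0
        for _ in range(max_iter):
            p_new = (1.0 - c) * (wt @ p)
            if dangling.any():
                p_new[i] += (1.0 - c) * p[dangling].sum()
            p_new[i] += c
            residual = np.abs(p_new - p).sum()
            p = p_new
            if residual < tolerance:
                break
        else:
            worst_residual = max(worst_residual, residual)
        raw[i] = p
    if worst_residual > 0.0:
        raise RuntimeError(
            f"random walk failed to converge within {max_iter} iterations "
            f"(worst L1 residual {worst_residual:.3e})"
        )
    sym = 0.5 * (raw + raw.T)
    return ProximityMatrix(list(graph.nodes), sym, kind="rwr", c=c, raw=raw)


def shortest_path_matrix(graph: InteractionGraph) -> ProximityMatrix:
    """Unweighted breadth-first hop counts between all node pairs.

    Unreachable pairs carry the ``inf`` sentinel and are excluded from
    any downstream correlation.
    """
    n = len(graph)
    mat = np.full((n, n), UNREACHABLE)
    idx = {node: i for i, node in enumerate(graph.nodes)}
    for source, lengths in nx.all_pairs_shortest_path_length(graph.graph):
        i = idx[source]
        for target, dist in lengths.items():
            mat[i, idx[target]] = dist
    return ProximityMatrix(list(graph.nodes), mat, kind="shortest_path")


def znormalize(scores: Sequence[float], ddof: int = 0) -> np.ndarray:
    """Affine transform to mean 0, standard deviation 1.

    Population standard deviation by default (``ddof=0``).  Constant
    input has no defined z-score and raises.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("z-normalization requires at least two values")
    sd = x.std(ddof=ddof)
    if sd == 0.0:
        raise ValueError("z-normalization undefined for zero-variance input")
    return (x - x.mean()) / sd


def bin_and_average(
    proximity_pairs: Sequence[float],
    similarity_pairs: Sequence[float],
    n_bins: int,
    labels: Sequence | None = None,
) -> pd.DataFrame:
    """Equal-count proximity bins with per-bin mean z-normalized similarity.

    Pairs are sorted by proximity (ties broken by ``labels`` when given —
    typically lexicographic node-pair tuples — for a stable, reproducible
    assignment) and split into ``n_bins`` groups whose sizes differ by at
    most one.  Similarity values are z-normalized over all pairs before
    averaging.

    Returns a frame with columns ``bin``, ``mean_proximity``,
    ``mean_z_similarity``, ``n_pairs``, ordered by increasing proximity.
    """
    prox = np.asarray(proximity_pairs, dtype=float)
    sim = np.asarray(similarity_pairs, dtype=float)
    if prox.shape != sim.shape:
        raise ValueError("proximity and similarity pair lists must align")
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if prox.size < n_bins:
        raise ValueError(f"{prox.size} pairs cannot fill {n_bins} bins")
    z = znormalize(sim)
    if labels is not None:
        order = sorted(range(prox.size), key=lambda k: (prox[k], labels[k]))
        order = np.asarray(order)
    else:
        order = np.argsort(prox, kind="stable")
    rows = []
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        rows.append(
            {
                "bin": b,
                "mean_proximity": float(prox[chunk].mean()),
                "mean_z_similarity": float(z[chunk].mean()),
                "n_pairs": int(chunk.size),
            }
        )
    return pd.DataFrame(rows)


def proximity_similarity_pairs(
    prox: ProximityMatrix,
    corpus: AnnotationCorpus,
    measure: str | Callable[[str, str], float] = "rho_JC",
    term_measure: str = "delta_I",
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Aligned (proximity, similarity) values over annotated node pairs.

    Iterates unordered pairs of network nodes that are both annotated in
    the corpus, skipping pairs with an undefined (infinite/NaN) proximity
    — e.g. nodes in different components of a shortest-path matrix.
    """
    if callable(measure):
        sim_fn = measure
    else:
        def sim_fn(u: str, v: str) -> float:
            return pair_similarity(corpus[u], corpus[v], measure, corpus, term_measure)

    labels: list[tuple[str, str]] = []
    pvals: list[float] = []
    svals: list[float] = []
    nodes = prox.nodes
    for i in range(len(nodes)):
        if nodes[i] not in corpus:
            continue
        for j in range(i + 1, len(nodes)):
            if nodes[j] not in corpus:
                continue
            p = prox.matrix[i, j]
            if not np.isfinite(p):
                continue
            labels.append((nodes[i], nodes[j]))
            pvals.append(float(p))
            svals.append(sim_fn(nodes[i], nodes[j]))
    return labels, np.asarray(pvals), np.asarray(svals)


def proximity_similarity_correlation(
    prox: ProximityMatrix,
    corpus: AnnotationCorpus,
    measure: str | Callable[[str, str], float] = "rho_JC",
    term_measure: str = "delta_I",
) -> float:
    """Pearson correlation between topological proximity and functional
    similarity over all annotated unordered node pairs."""
    _, pvals, svals = proximity_similarity_pairs(prox, corpus, measure, term_measure)
    if pvals.size < 3:
        raise ValueError("correlation requires at least three defined node pairs")
    if np.std(pvals) == 0.0 or np.std(svals) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(pearsonr(pvals, svals).statistic)


def restart_sweep(
    graph: InteractionGraph,
    corpus: AnnotationCorpus,
    measure: str | Callable[[str, str], float] = "rho_JC",
    c_values: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    term_measure: str = "delta_I",
    tolerance: float = 1e-10,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Proximity-similarity correlation as a function of the restart
    probability c.  Returns a frame with columns ``c``, ``correlation``."""
    rows = []
    for c in c_values:
        prox = rwr_proximity(graph, c=c, tolerance=tolerance, max_iter=max_iter)
        rows.append(
            {"c": c, "correlation": proximity_similarity_correlation(prox, corpus, measure, term_measure)}
        )
    return pd.DataFrame(rows)
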