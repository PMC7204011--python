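"""Clustering of fingerprint collections.

Curated-scale sets are clustered hierarchically on the dense pairwise J_D
matrix (McQuitty/WPGMA by default, the linkage that gave the most
homogeneous groupings), with dendrograms cut at 50 evenly spaced heights
and optional purity scoring against reference labels. Large sets are
sparsified by keeping each fingerprint's top-k strongest similarities
(k = 1400 at census scale) and clustered with Markov clustering (MCL) on
the resulting similarity graph. Every cluster is summarized by its medoid
— the member least distant from all others — and clusters of 4 or fewer
members are flagged as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .compare import pairwise_table
from .fingerprint import DotPlot

LINKAGE_METHODS = {
    "mcquitty": "weighted",
    "average": "average",
    "complete": "complete",
    "single": "single",
    "ward": "ward",
}

SINGLETON_MAX_SIZE = 4
DEFAULT_TOPK = 1400
DEFAULT_INFLATION = 2.0


def pairwise_matrix(plots: dict[str, DotPlot], threads: int = 1) -> pd.DataFrame:
    """Symmetric J_D matrix over all fingerprint pairs (diagonal 0)."""
    ids = sorted(plots)
    if len(ids) < 2:
        raise ValueError("need at least 2 fingerprints")
    idx = {v: i for i, v in enumerate(ids)}
    d = np.zeros((len(ids), len(ids)))
    table = pairwise_table(plots, threads=threads)
    for row in table.itertuples(index=False):
        x, y = idx[row.id_a], idx[row.id_b]
        d[x, y] = d[y, x] = row.j_d
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass(frozen=True)
class HClusterResult:
    """Dendrogram with per-level assignments and optional purity report."""

    ids: list[str]
    tree: np.ndarray = field(repr=False)
    cut_heights: np.ndarray = field(repr=False)
    assignments: pd.DataFrame = field(repr=False)  # rows = ids, one column per cut
    purity: pd.DataFrame | None = None  # per cut: n_clusters, fraction pure, majority purity


def _purity_at_cut(labels: np.ndarray, reference: list) -> tuple[int, float, float]:
    clusters: dict[int, list] = {}
    for lab, ref in zip(labels, reference):
        clusters.setdefault(int(lab), []).append(ref)
    n = len(clusters)
    pure = sum(1 for refs in clusters.values() if len(set(refs)) == 1)
    majority = sum(max(refs.count(r) for r in set(refs)) for refs in clusters.values())
    return n, pure / n, majority / len(reference)


def hcluster(
    distances: pd.DataFrame,
    method: str = "mcquitty",
    cut_levels: int = 50,
    reference_labels: dict[str, object] | None = None,
) -> HClusterResult:
    """Agglomerative clustering of a J_D matrix, cut at evenly spaced heights.

    McQuitty (WPGMA) linkage is the default: on a merge, the new cluster's
    distance to any other is the unweighted mean of the two merged
    clusters' distances to it. Cut heights are evenly spaced between 0 and
    the final merge height. With ``reference_labels`` a purity report is
    attached: per cut, the fraction of clusters whose members all share
    one label, and the overall majority-label fraction.
    """
    scipy_method = LINKAGE_METHODS.get(method)
    if scipy_method is None:
        raise ValueError(f"unknown linkage {method!r}; choose from {sorted(LINKAGE_METHODS)}")
    ids = list(distances.index)
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    tree = linkage(squareform(d, checks=False), method=scipy_method)
    hmax = tree[-1, 2] if len(tree) else 0.0
    heights = np.linspace(0.0, hmax, cut_levels)
    cols = {}
    purity_rows = []
    for k, h in enumerate(heights):
        labels = fcluster(tree, t=h, criterion="distance")
        cols[f"cut_{k:02d}"] = labels
        if reference_labels is not None:
            refs = [reference_labels[i] for i in ids]
            n, frac_pure, majority = _purity_at_cut(labels, refs)
            purity_rows.append((k, float(h), n, frac_pure, majority))
    assignments = pd.DataFrame(cols, index=ids)
    purity = (
        pd.DataFrame(
            purity_rows, columns=["cut", "height", "n_clusters", "fraction_pure", "majority_purity"]
        )
        if reference_labels is not None
        else None
    )
    return HClusterResult(
        ids=ids, tree=tree, cut_heights=heights, assignments=assignments, purity=purity
    )


@dataclass(frozen=True)
class SimilarityGraph:
    """Sparsified J_X similarity graph (no self-edges, weights in (0, 1])."""

    graph: nx.Graph
    k: int

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def sparsify_topk(similarities: pd.DataFrame, k: int = DEFAULT_TOPK) -> SimilarityGraph:
    """Keep each node's k largest-J_X edges; union-symmetrize.

    An edge survives if either endpoint retained it. Zero similarities are
    never stored; self-similarities are ignored.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(similarities.index)
    s = similarities.to_numpy(dtype=float).copy()
    np.fill_diagonal(s, 0.0)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for x, row in enumerate(s):
        order = np.argsort(-row, kind="stable")[:k]
        for y in order:
            if row[y] > 0:
                g.add_edge(ids[x], ids[int(y)], weight=float(row[y]))
    return SimilarityGraph(graph=g, k=k)


@dataclass(frozen=True)
class ClusterResult:
    """Cluster assignment with medoids and singleton flags."""

    assignment: dict[str, int]
    medoids: dict[int, str]
    sizes: dict[int, int]
    singleton: dict[int, bool]
    converged: bool = True

    def members(self, cluster: int) -> list[str]:
        return sorted(i for i, c in self.assignment.items() if c == cluster)


def mcl_cluster(
    graph: SimilarityGraph | nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = 100,
    tol: float = 1e-6,
    distances: pd.DataFrame | None = None,
) -> ClusterResult:
    """Markov clustering of a similarity graph.

    Iterates expansion (matrix squaring) and inflation (element-wise power
    ``inflation`` followed by column re-normalization) on the
    column-stochastic adjacency matrix (self-loops added, the standard MCL
    regularization) until the matrix changes by less than ``tol``;
    clusters are the connected components of the attractor structure of
    the limit matrix. Clusters of ≤ 4 members are flagged singleton. If
    ``distances`` (J_D) is given, medoids minimize summed J_D; otherwise
    1 − J_X edge weights are used within clusters.
    """
    g = graph.graph if isinstance(graph, SimilarityGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    ids = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(ids)}
    m = len(ids)
    a = np.zeros((m, m))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
    np.fill_diagonal(a, 1.0)  # unit self-loops (standard MCL regularization)
    col = a.sum(axis=0)
    t = a / col

    converged = False
    for _ in range(max_iter):
        prev = t
        t = t @ t  # expansion
        t = np.power(t, inflation)  # inflation
        t[t < 1e-12] = 0.0
        colsum = t.sum(axis=0)
        colsum[colsum == 0] = 1.0
        t /= colsum
        if np.abs(t - prev).max() < tol:
            converged = True
            break

    support = nx.Graph()
    support.add_nodes_from(range(m))
    rows, cols_nz = np.nonzero(t > 1e-8)
    support.add_edges_from(zip(rows.tolist(), cols_nz.tolist()))
    comps = sorted(nx.connected_components(support), key=lambda c: sorted(ids[i] for i in c)[0])

    assignment: dict[str, int] = {}
    medoids: dict[int, str] = {}
    sizes: dict[int, int] = {}
    singleton: dict[int, bool] = {}
    for cid, comp in enumerate(comps):
        members = sorted(ids[i] for i in comp)
        for v in members:
            assignment[v] = cid
        sizes[cid] = len(members)
        singleton[cid] = len(members) <= SINGLETON_MAX_SIZE
        if distances is not None:
            medoids[cid] = find_medoid(members, distances)
        else:
            sub = pd.DataFrame(1.0, index=members, columns=members)
            for u in members:
                for v in members:
                    if u == v:
                        sub.loc[u, v] = 0.0
                    elif g.has_edge(u, v):
                        sub.loc[u, v] = 1.0 - float(g[u][v].get("weight", 0.0))
            medoids[cid] = find_medoid(members, sub)
    return ClusterResult(
        assignment=assignment, medoids=medoids, sizes=sizes, singleton=singleton, converged=converged
    )


def find_medoid(members: list[str], distances: pd.DataFrame) -> str:
    """The member minimizing summed J_D to all other members (ties: lexicographic)."""
    if not members:
        raise ValueError("empty cluster")
    members = sorted(members)
    sums = [float(distances.loc[m, members].sum()) for m in members]
    return members[int(np.argmin(sums))]


def export_mcl_abc(similarities: pd.DataFrame, path) -> None:
    """Write the upper-triangle non-zero similarities as an MCL ABC edge list
    (``a<TAB>b<TAB>J_X``), sorted by (a, b)."""
    ids = list(similarities.index)
    with open(path, "w") as fh:
        for x, a in enumerate(ids):
            for b in ids[x + 1 :]:
                w = float(similarities.loc[a, b])
                if w > 0:
                    fh.write(f"{a}\t{b}\t{w:.6g}\n")
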