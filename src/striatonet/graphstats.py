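"""Network measures and modularity for the striatal connectome.

Degree distributions are reported for the directed out-edges (the quantity
the construction rule controls); every other measure — shortest paths,
global efficacy, clustering, betweenness centrality, modularity — is
computed on the symmetrised union graph, because triangle counts and the
modularity matrix are undirected formalisms.

Conventions
-----------
mean path        m = sum d_ij / (N (N-1)) over reachable ordered pairs.
global efficacy  l = sum (1/d_ij) / (N (N-1)) with 1/inf = 0.
clustering       c(i) = (# triangles at i) / (k_i (k_i - 1) / 2 * 2); nodes
                 with degree < 2 get c(i) = 0.
betweenness      BC(i) = sum over unordered pairs j<k of g_jk(i)/g_jk,
                 unnormalised, fractional over tied shortest paths.
modularity       Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j);
                 for a +/-1 split vector s this is (1/4m) s^T B s.

Community detection is recursive spectral bisection of the modularity
matrix (leading-eigenvector sign) with a Kernighan-Lin style fine-tuning
pass, accepting a split only if it raises Q and both parts keep at least
``min_size`` members.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .connectome import SpatialNetwork

__all__ = [
    "GraphMetrics",
    "CommunityPartition",
    "degree_distribution",
    "path_and_efficacy",
    "clustering",
    "betweenness",
    "modularity",
    "detect_communities",
]


@dataclass
class GraphMetrics:
    out_degree: np.ndarray
    mean_path: float
    efficacy: float
    inverse_efficacy: float
    clustering: np.ndarray
    betweenness: np.ndarray


def degree_distribution(net: SpatialNetwork) -> dict[str, dict[int, float]]:
    """Empirical out-degree distribution P(k), split by cell type."""
    deg = net.out_degrees()
    out: dict[str, dict[int, float]] = {}
    for ct in ("MSN", "FS"):
        mask = net.table.cell_type == ct
        d = deg[mask]
        if d.size == 0:
            out[ct] = {}
            continue
        ks, counts = np.unique(d, return_counts=True)
        out[ct] = {int(k): float(c) / d.size for k, c in zip(ks, counts)}
    return out


def _sym(net: SpatialNetwork | sp.spmatrix) -> sp.csr_matrix:
    if isinstance(net, SpatialNetwork):
        return net.symmetrised()
    M = sp.csr_matrix(net)
    M = M.maximum(M.T)
    M.setdiag(0)
    M.eliminate_zeros()
    M.data = np.ones_like(M.data)
    return M


def path_and_efficacy(net: SpatialNetwork | sp.spmatrix) -> tuple[float, float, float]:
    """(mean path, global efficacy, inverse efficacy) on the symmetrised graph.

    Unreachable pairs are excluded from the mean path and contribute 0 to the
    efficacy sum.
    """
    M = _sym(net)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    D = shortest_path(M, method="D", unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    mean_path = float(d[finite].mean()) if finite.any() else float("inf")
    inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    efficacy = float(inv.sum() / (n * (n - 1)))
    inverse_efficacy = 1.0 / efficacy if efficacy > 0 else float("inf")
    return mean_path, efficacy, inverse_efficacy


def clustering(net: SpatialNetwork | sp.spmatrix) -> np.ndarray:
    """Per-node clustering coefficient on the symmetrised simple graph."""
    M = _sym(net)
    G = nx.from_scipy_sparse_array(M)
    c = nx.clustering(G)
    return np.array([c[i] for i in range(M.shape[0])], float)


def betweenness(net: SpatialNetwork | sp.spmatrix) -> np.ndarray:
    """Unnormalised betweenness centrality over unordered pairs."""
    M = _sym(net)
    G = nx.from_scipy_sparse_array(M)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(M.shape[0])], float)


def graph_metrics(net: SpatialNetwork) -> GraphMetrics:
    m, l, inv_l = path_and_efficacy(net)
    return GraphMetrics(
        out_degree=net.out_degrees(),
        mean_path=m,
        efficacy=l,
        inverse_efficacy=inv_l,
        clustering=clustering(net),
        betweenness=betweenness(net),
    )


def write_metrics_csv(net: SpatialNetwork, metrics: GraphMetrics, path) -> None:
    """Node-level metric table (id, cell_type, out_degree, clustering, BC)."""
    import pandas as pd

    pd.DataFrame(
        {
            "id": net.table.ids,
            "cell_type": net.table.cell_type,
            "out_degree": metrics.out_degree,
            "clustering": metrics.clustering,
            "betweenness": metrics.betweenness,
        }
    ).to_csv(path, index=False)


def metrics_summary(net: SpatialNetwork, metrics: GraphMetrics) -> dict:
    msn, fs = net.table.msn_mask, net.table.fs_mask
    return {
        "mean_path": metrics.mean_path,
        "efficacy": metrics.efficacy,
        "inverse_efficacy": metrics.inverse_efficacy,
        "msn_mean_out_degree": float(metrics.out_degree[msn].mean()) if msn.any() else None,
        "fs_mean_out_degree": float(metrics.out_degree[fs].mean()) if fs.any() else None,
        "msn_mean_clustering": float(metrics.clustering[msn].mean()) if msn.any() else None,
        "fs_mean_clustering": float(metrics.clustering[fs].mean()) if fs.any() else None,
    }


# ---------------------------------------------------------------------------
# modularity / community detection
# ---------------------------------------------------------------------------


@dataclass
class CommunityPartition:
    assignment: np.ndarray  # community id per node
    Q: float
    m: int  # undirected edge count
    min_size: int

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.assignment))

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment)


def modularity(A: sp.spmatrix | np.ndarray, assignment: np.ndarray) -> float:
    """Direct evaluation of Q on an undirected simple graph."""
    M = _sym(sp.csr_matrix(A))
    k = np.asarray(M.sum(axis=1)).ravel()
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    assignment = np.asarray(assignment)
    q = 0.0
    for c in np.unique(assignment):
        idx = np.flatnonzero(assignment == c)
        e_in = M[np.ix_(idx, idx)].sum()  # counts each internal edge twice
        q += e_in / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _restricted_B_dense(M: sp.csr_matrix, k: np.ndarray, two_m: float, idx: np.ndarray) -> np.ndarray:
    """Generalised modularity matrix of a subgraph: B^(g) = B_g - diag(row sums of B_g)."""
    A_g = M[np.ix_(idx, idx)].toarray().astype(float)
    k_g = k[idx]
    B = A_g - np.outer(k_g, k_g) / two_m
    B -= np.diag(B.sum(axis=1))
    return B


def _leading_vector(B: np.ndarray) -> tuple[float, np.ndarray]:
    if B.shape[0] <= 600:
        w, v = np.linalg.eigh(B)
        return float(w[-1]), v[:, -1]
    lam, vec = sp.linalg.eigsh(sp.csr_matrix(B), k=1, which="LA")
    return float(lam[0]), vec[:, 0]


def _fine_tune(B: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style pass: greedily flip each node once per sweep,
    keep the best intermediate configuration; repeat while Q improves."""
    n = len(s)
    diag = np.diag(B).copy()
    best = s.copy()
    best_q = best @ B @ best
    improved = True
    while improved:
        improved = False
        s_work = best.copy()
        free = np.ones(n, dtype=bool)
        Bs = B @ s_work
        flips: list[int] = []
        qs = np.empty(n)
        q = best_q
        for step in range(n):
            # flipping node i changes s^T B s by -4 s_i (B s)_i + 4 B_ii
            gains = -4 * s_work * Bs + 4 * diag
            gains[~free] = -np.inf
            i = int(np.argmax(gains))
            q += gains[i]
            Bs -= 2.0 * s_work[i] * B[:, i]  # incremental update of B s
            s_work[i] = -s_work[i]
            free[i] = False
            flips.append(i)
            qs[step] = q
        k_best = int(np.argmax(qs))
        if qs[k_best] > best_q + 1e-10:
            best_q = qs[k_best]
            best[flips[: k_best + 1]] *= -1
            improved = True
    return best


def detect_communities(
    net: SpatialNetwork | sp.spmatrix,
    min_size: int = 180,
    max_iters: int = 100,
) -> CommunityPartition:
    """Size-constrained recursive spectral modularity partition."""
    M = _sym(net if isinstance(net, SpatialNetwork) else sp.csr_matrix(net))
    n = M.shape[0]
    k = np.asarray(M.sum(axis=1)).ravel().astype(float)
    two_m = float(k.sum())
    m_edges = int(round(two_m / 2))
    assignment = np.zeros(n, dtype=int)
    if two_m == 0 or n < 2 * min_size:
        return CommunityPartition(assignment, modularity(M, assignment), m_edges, min_size)

    next_id = 1
    stack = [np.arange(n)]
    iters = 0
    while stack and iters < max_iters:
        iters += 1
        idx = stack.pop()
        if len(idx) < 2 * min_size:
            continue
        B = _restricted_B_dense(M, k, two_m, idx)
        lam, v = _leading_vector(B)
        if lam <= 1e-12:
            continue  # indivisible
        s = np.where(v >= 0, 1, -1)
        if np.all(s == s[0]):
            continue
        s = _fine_tune(B, s)
        dq = (s @ B @ s) / (2.0 * two_m)
        n_pos = int((s == 1).sum())
        if dq <= 1e-10 or n_pos < min_size or len(idx) - n_pos < min_size:
            continue  # split rejected: no Q gain or size boundary condition
        part = idx[s == 1]
        assignment[part] = next_id
        next_id += 1
        stack.append(part)
        stack.append(idx[s == -1])

    # relabel to consecutive ids
    _, assignment = np.unique(assignment, return_inverse=True)
    return CommunityPartition(assignment, modularity(M, assignment), m_edges, min_size)


def write_partition_csv(part: CommunityPartition, path) -> None:
    import pandas as pd

    pd.DataFrame({"id": np.arange(len(part.assignment)), "community": part.assignment}).to_csv(
        path, index=False
    )
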