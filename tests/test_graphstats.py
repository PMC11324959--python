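"""Graph measures against brute-force oracles and hand-computable fixtures."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from striatonet.connectome import SpatialNetwork, build_network
from striatonet.geometry import NeuronTable
from striatonet.graphstats import (
    betweenness,
    clustering,
    degree_distribution,
    detect_communities,
    modularity,
    path_and_efficacy,
)

from conftest import random_digraph


def _net_from_dense(A, cell_type=None):
    n = len(A)
    table = NeuronTable(
        pos=np.zeros((n, 3)),
        nucleus=np.array(["caudate"] * n, object),
        cell_type=np.array(cell_type or ["MSN"] * n, object),
    )
    return SpatialNetwork(table=table, A=sp.csr_matrix(np.asarray(A)))


# ------------------------------------------------------------------ oracles


def _sym_dense(A):
    M = ((np.asarray(A) + np.asarray(A).T) > 0).astype(int)
    np.fill_diagonal(M, 0)
    return M


def _bfs_dists(M):
    n = len(M)
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(M[u]):
                    if D[s, v] == np.inf:
                        D[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return D


def _brute_clustering(M):
    n = len(M)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(M[i])
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(M[j, l] for j, l in itertools.combinations(nbrs, 2))
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def _brute_betweenness(M):
    """Exhaustive shortest-path enumeration over unordered pairs."""
    n = len(M)
    D = _bfs_dists(M)
    bc = np.zeros(n)

    def count_paths(j, k, via=None):
        # number of shortest j->k paths (optionally through `via`)
        if not np.isfinite(D[j, k]):
            return 0
        paths = [[j]]
        for _ in range(int(D[j, k])):
            paths = [
                p + [v]
                for p in paths
                for v in np.flatnonzero(M[p[-1]])
                if D[j, v] == len(p) and np.isfinite(D[v, k]) and D[j, v] + D[v, k] == D[j, k]
            ]
        paths = [p for p in paths if p[-1] == k]
        if via is None:
            return len(paths)
        return sum(via in p[1:-1] for p in paths)

    for j, k in itertools.combinations(range(n), 2):
        g = count_paths(j, k)
        if g == 0:
            continue
        for i in range(n):
            if i in (j, k):
                continue
            bc[i] += count_paths(j, k, via=i) / g
    return bc


# ------------------------------------------------------------------- tests


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(4, 12), seed=st.integers(0, 10_000), p=st.sampled_from([0.15, 0.3, 0.5]))
def test_metrics_match_brute_force_on_random_graphs(n, seed, p):
    A = random_digraph(n, p, seed)
    net = _net_from_dense(A)
    M = _sym_dense(A)
    D = _bfs_dists(M)

    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D[off])
    m_exp = D[off][finite].mean() if finite.any() else np.inf
    l_exp = np.where(np.isfinite(D[off]), 1.0 / np.maximum(D[off], 1), 0.0).sum() / (n * (n - 1))
    m, l, inv_l = path_and_efficacy(net)
    assert m == pytest.approx(m_exp)
    assert l == pytest.approx(l_exp)

    assert clustering(net) == pytest.approx(_brute_clustering(M))
    assert betweenness(net) == pytest.approx(_brute_betweenness(M))


def test_path_fixtures():
    K5 = 1 - np.eye(5, dtype=int)
    m, l, _ = path_and_efficacy(_net_from_dense(K5))
    assert (m, l) == (1.0, 1.0)
    # two disconnected K2: 4 ordered pairs at distance 1, 8 unreachable
    two_k2 = np.zeros((4, 4), int)
    two_k2[0, 1] = two_k2[1, 0] = two_k2[2, 3] = two_k2[3, 2] = 1
    m, l, _ = path_and_efficacy(_net_from_dense(two_k2))
    assert m == 1.0  # unreachable pairs excluded from the mean path
    assert l == pytest.approx(4 * 1.0 / (4 * 3))  # and contribute 0 to efficacy


def test_clustering_fixtures():
    tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    assert clustering(_net_from_dense(tri)) == pytest.approx([1, 1, 1])
    star = np.zeros((6, 6), int)
    star[0, 1:] = 1
    assert clustering(_net_from_dense(star))[0] == 0.0  # S5 centre
    # degree-1 nodes take c=0 by convention
    assert clustering(_net_from_dense(star))[1] == 0.0


def test_betweenness_fixtures():
    p3 = np.zeros((3, 3), int)
    p3[0, 1] = p3[1, 0] = p3[1, 2] = p3[2, 1] = 1
    assert betweenness(_net_from_dense(p3)) == pytest.approx([0, 1, 0])
    k4 = 1 - np.eye(4, dtype=int)
    assert betweenness(_net_from_dense(k4)) == pytest.approx([0, 0, 0, 0])
    s4 = np.zeros((4, 4), int)
    s4[0, 1:] = 1
    assert betweenness(_net_from_dense(s4))[0] == pytest.approx(3.0)  # 3 leaf pairs


def test_degree_distribution_point_masses():
    k4 = 1 - np.eye(4, dtype=int)
    hist = degree_distribution(_net_from_dense(k4))
    assert hist["MSN"] == {3: 1.0}
    assert hist["FS"] == {}  # empty class is an empty histogram, not an error


def test_degree_distribution_split_by_type(small_net):
    hist = degree_distribution(small_net)
    for ct in ("MSN", "FS"):
        if hist[ct]:
            assert sum(hist[ct].values()) == pytest.approx(1.0)
    deg = small_net.out_degrees()[small_net.table.msn_mask]
    lo = min(hist["MSN"])
    assert lo >= small_net.k_local_msn - 1 or small_net.n_underconnected > 0


# --------------------------------------------------------------- modularity


def _two_cliques(k=10):
    A = np.zeros((2 * k, 2 * k), int)
    A[:k, :k] = 1 - np.eye(k)
    A[k:, k:] = 1 - np.eye(k)
    A[0, k] = A[k, 0] = 1
    return A


def test_two_clique_partition_recovers_planted_split():
    A = _two_cliques(10)
    part = detect_communities(sp.csr_matrix(A), min_size=5)
    assert part.n_communities == 2
    labels = part.assignment
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels[0] != labels[10]
    # Q of the returned assignment equals the direct definition
    assert part.Q == pytest.approx(modularity(A, labels))


def test_two_clique_split_is_global_optimum_by_exhaustion():
    """All 2^(n-1) bipartitions of the 20-node two-clique graph score no
    better than the planted one (direct s^T B s evaluation)."""
    A = _two_cliques(10).astype(float)
    k = A.sum(axis=1)
    two_m = k.sum()
    B = A - np.outer(k, k) / two_m
    n = 20
    bits = ((np.arange(2 ** (n - 1))[:, None] >> np.arange(n)) & 1).astype(np.int8)
    S = 2 * bits - 1  # node 19 fixed in community -1
    Q_all = np.einsum("ij,jk,ik->i", S, B, S) / (2 * two_m)
    planted = np.array([1] * 10 + [-1] * 10)
    Q_planted = planted @ B @ planted / (2 * two_m)
    assert Q_planted == pytest.approx(Q_all.max())
    part = detect_communities(sp.csr_matrix(A.astype(int)), min_size=5)
    assert part.Q == pytest.approx(Q_planted)


def test_complete_graph_stays_single_community():
    K12 = 1 - np.eye(12, dtype=int)
    part = detect_communities(sp.csr_matrix(K12), min_size=2)
    assert part.n_communities == 1


def test_min_size_boundary_blocks_split():
    A = _two_cliques(8)
    part = detect_communities(sp.csr_matrix(A), min_size=9)
    assert part.n_communities == 1  # 8 < min_size on each side


def test_partition_invariant_to_relabelling():
    A = _two_cliques(9)
    rng = np.random.default_rng(3)
    perm = rng.permutation(18)
    Ap = A[np.ix_(perm, perm)]
    p1 = detect_communities(sp.csr_matrix(A), min_size=4)
    p2 = detect_communities(sp.csr_matrix(Ap), min_size=4)
    assert p1.Q == pytest.approx(p2.Q)
    # community structure maps through the permutation
    relabelled = p1.assignment[perm]
    same = relabelled[:, None] == relabelled[None, :]
    same2 = p2.assignment[:, None] == p2.assignment[None, :]
    assert (same == same2).all()


def test_q_of_partition_beats_trivial(small_net):
    part = detect_communities(small_net, min_size=5)
    trivial = modularity(small_net.symmetrised(), np.zeros(small_net.n, int))
    assert part.Q >= trivial - 1e-12
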