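"""Spatial small-world connectome construction.

Each MSN makes ``k_msn`` (default 20) directed contacts onto distinct
neurons sampled uniformly from the 5 mm ball around it; FS interneurons do
the same with a five-fold denser rule (``k_fs=100``).  Independently, for
each local edge a remote out-edge (target uniform outside the ball) is
*added* with probability ``p_remote`` — an additive variant of the
Watts-Strogatz construction (no rewiring-removal), so the expected MSN
out-degree is ``k_msn * (1 + p_remote)``.

Adjacency convention: ``A[i, j] = 1`` means presynaptic neuron ``j``
contacts postsynaptic neuron ``i`` — row ``i`` lists the inputs entering
the synaptic sum ``sum_j A_ij s_j`` of the dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .geometry import NeuronTable

__all__ = ["SpatialNetwork", "build_network", "read_adjacency", "write_adjacency"]


@dataclass
class SpatialNetwork:
    """Neuron table plus directed binary adjacency (CSR, A[i,j]: j -> i)."""

    table: NeuronTable
    A: sp.csr_matrix
    k_local_msn: int = 20
    k_local_fs: int = 100
    p_remote: float = 0.05
    radius: float = 5.0
    n_underconnected: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.table.n
        if self.A.shape != (n, n):
            raise ValueError(
                f"adjacency is {self.A.shape} but table has {n} rows"
            )

    @property
    def n(self) -> int:
        return self.table.n

    def out_degrees(self) -> np.ndarray:
        """Out-degree per neuron (number of postsynaptic targets)."""
        return np.asarray(self.A.sum(axis=0)).ravel().astype(int)

    def in_degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel().astype(int)

    def symmetrised(self) -> sp.csr_matrix:
        """Undirected union graph used by the path/clustering/modularity metrics."""
        M = self.A.maximum(self.A.T).tocsr()
        M.setdiag(0)
        M.eliminate_zeros()
        return M


def build_network(
    table: NeuronTable,
    k_msn: int = 20,
    k_fs: int = 100,
    radius: float = 5.0,
    p_remote: float = 0.05,
    seed: int = 0,
) -> SpatialNetwork:
    """Build the directed spatial small-world network.

    If a node has fewer than ``k`` candidates inside its ball it connects to
    all of them; such nodes are counted in ``n_underconnected`` and a single
    warning is emitted rather than silently under-connecting.
    """
    if not 0.0 <= p_remote <= 1.0:
        raise ValueError("p_remote must lie in [0, 1]")
    n = table.n
    rng = np.random.default_rng(seed)
    tree = cKDTree(table.pos)
    neighbours = tree.query_ball_point(table.pos, r=radius)

    rows: list[int] = []  # postsynaptic (target)
    cols: list[int] = []  # presynaptic (source)
    n_under = 0
    all_ids = np.arange(n)
    for i in range(n):
        k = k_msn if table.cell_type[i] == "MSN" else k_fs
        ball = np.array([j for j in neighbours[i] if j != i])
        if len(ball) < k:
            n_under += 1
            local = ball
        else:
            local = rng.choice(ball, size=k, replace=False)
        targets = set(local.tolist())
        # additive remote stage: one candidate remote edge per local edge
        n_remote = int(rng.binomial(len(local), p_remote)) if p_remote > 0 else 0
        in_ball = set(ball.tolist()) | {i}
        added = 0
        while added < n_remote:
            j = int(rng.integers(n))
            if j in in_ball or j in targets:
                continue  # remote means outside the ball; no multi-edges
            targets.add(j)
            added += 1
        tgt = sorted(targets)
        rows.extend(tgt)
        cols.extend([i] * len(tgt))

    if n_under:
        warnings.warn(
            f"{n_under} node(s) had fewer than k candidates within {radius} mm; "
            "connected to all available",
            stacklevel=2,
        )
    A = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return SpatialNetwork(
        table=table,
        A=A,
        k_local_msn=k_msn,
        k_local_fs=k_fs,
        p_remote=p_remote,
        radius=radius,
        n_underconnected=n_under,
        seed=seed,
    )


def write_adjacency(net: SpatialNetwork, path) -> None:
    """Write the adjacency in Matrix Market coordinate pattern format."""
    scipy.io.mmwrite(path, net.A.tocoo(), field="pattern", symmetry="general")


def read_adjacency(path, table: NeuronTable, **kwargs) -> SpatialNetwork:
    """Read a Matrix Market adjacency and attach it to ``table``."""
    M = scipy.io.mmread(path).tocsr()
    M.data = np.ones_like(M.data, dtype=np.int8)
    if M.shape != (table.n, table.n):
        raise ValueError(
            f"adjacency declares shape {M.shape} but table has {table.n} rows"
        )
    return SpatialNetwork(table=table, A=M, **kwargs)
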