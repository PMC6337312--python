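"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths (and, for graph metrics, the
library) used by the implementation: shortest paths come from scipy's
sparse-graph BFS, betweenness from (a) explicit enumeration of all shortest
paths and (b) a from-scratch Brandes pair-dependency accumulation, and the
optimal-superposition RMSD from scipy's rotation solver.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _sp
from scipy.spatial.transform import Rotation


def adjacency(n: int, edges: set[tuple[int, int]]) -> np.ndarray:
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


def bfs_L_oracle(n: int, edges: set[tuple[int, int]]):
    """Per-node average shortest path over reachable nodes, via scipy BFS."""
    d = _sp(csr_matrix(adjacency(n, edges)), method="D", unweighted=True)
    L = np.full(n, np.nan)
    reach = np.zeros(n)
    for i in range(n):
        row = d[i]
        finite = np.isfinite(row) & (np.arange(n) != i)
        k = finite.sum()
        reach[i] = k / (n - 1) if n > 1 else 0.0
        if k > 0:
            L[i] = row[finite].sum() / k
    return L, reach


def enumerate_bc_oracle(n: int, edges: set[tuple[int, int]]) -> np.ndarray:
    """Normalised betweenness by explicit enumeration of all shortest paths.

    Exponential; intended for n <= 12.
    """
    a = adjacency(n, edges)
    d = _sp(csr_matrix(a), method="D", unweighted=True)
    raw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        paths = []
        stack = [[s]]
        while stack:
            path = stack.pop()
            u = path[-1]
            if u == t:
                paths.append(path)
                continue
            for v in range(n):
                if a[u, v] and d[s, v] == len(path) and d[v, t] == d[s, t] - len(path):
                    stack.append(path + [v])
        for p in paths:
            for v in p[1:-1]:
                raw[v] += 1.0 / len(paths)
    if n < 3:
        return np.zeros(n)
    return raw * 2.0 / ((n - 1) * (n - 2))


def brandes_bc_oracle(n: int, edges: set[tuple[int, int]]) -> np.ndarray:
    """Normalised betweenness via an independently coded Brandes algorithm."""
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = []
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            order.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if n < 3:
        return np.zeros(n)
    return bc / 2.0 * 2.0 / ((n - 1) * (n - 2))


def random_geometric_edges(
    n: int, rng: np.random.Generator, box: float = 30.0, cutoff: float = 6.7
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Random points in a cube and their contact edges at ``cutoff``."""
    pts = rng.uniform(0, box, size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    ii, jj = np.where(np.triu(d <= cutoff, k=1))
    return pts, {(int(i), int(j)) for i, j in zip(ii, jj)}


def optimal_rmsd_oracle(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via scipy's rotation solver."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref, mob)
    return float(np.sqrt(((rot.apply(mob) - ref) ** 2).sum(axis=1).mean()))
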