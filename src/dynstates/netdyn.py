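"""Time-resolved graph analysis of windowed connectivity.

Each window's connectivity matrix is binarized by keeping the m largest
|off-diagonal| entries, with m set by a target edge density (fraction of
the N(N-1)/2 possible edges).  Global efficiency (mean inverse shortest
path length over ordered node pairs, 0 for disconnected pairs) and local
efficiency (global efficiency of each node's neighbor-induced subgraph)
are computed per window at every density on a grid, averaged across the
grid, and the temporal SD of each measure summarizes the dynamics.  A
static counterpart uses the whole-time-course correlation matrix.

Shortest paths use breadth-first search (scipy.sparse.csgraph, unweighted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensityGrid",
    "EfficiencySeries",
    "max_edges",
    "threshold_to_density",
    "global_efficiency",
    "local_efficiency",
    "efficiency_dynamics",
    "static_efficiency",
]


def max_edges(N: int) -> int:
    """Maximum possible undirected edges on N nodes: N(N-1)/2."""
    if N < 2:
        raise ValueError("need at least 2 nodes")
    return N * (N - 1) // 2


@dataclass(frozen=True)
class DensityGrid:
    """Edge-density grid with the integer edge counts it induces for N nodes."""

    densities: tuple[float, ...]
    n_nodes: int

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if np.any(d <= 0) or np.any(d > 1):
            raise ValueError("densities must lie in (0, 1]")
        if np.any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing")
        counts = self.edge_counts
        if np.any(np.diff(counts) <= 0):
            raise ValueError("densities too close: duplicate edge counts")

    @property
    def edge_counts(self) -> np.ndarray:
        m = max_edges(self.n_nodes)
        return np.rint(np.asarray(self.densities) * m).astype(int)

    @classmethod
    def from_edge_counts(cls, counts: np.ndarray, n_nodes: int) -> "DensityGrid":
        m = max_edges(n_nodes)
        return cls(densities=tuple(np.asarray(counts) / m), n_nodes=n_nodes)

    @classmethod
    def default(cls, n_nodes: int = 27, d_min: float = 0.037, d_max: float = 0.393,
                max_points: int | None = None) -> "DensityGrid":
        """Every integer edge count between round(d_min*M) and round(d_max*M)
        (13..138 for 27 nodes); optionally thinned to ~max_points counts."""
        m = max_edges(n_nodes)
        lo, hi = int(round(d_min * m)), int(round(d_max * m))
        counts = np.arange(lo, hi + 1)
        if max_points is not None and counts.size > max_points:
            counts = np.unique(np.rint(np.linspace(lo, hi, max_points)).astype(int))
        return cls.from_edge_counts(counts, n_nodes)


def threshold_to_density(matrix: np.ndarray, density: float) -> np.ndarray:
    """Binarize by keeping the m = round(density * N(N-1)/2) largest
    |off-diagonal| entries as edges.  Ties at the cutoff are broken by
    (row, col) lexicographic order, so the result is deterministic."""
    M = np.asarray(matrix, dtype=float)
    N = M.shape[0]
    if M.shape != (N, N) or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be square and symmetric")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    m = int(round(density * max_edges(N)))
    if m == 0:
        raise ValueError(f"density {density} yields zero edges for N={N}")
    iu, ju = np.triu_indices(N, k=1)
    vals = np.abs(M[iu, ju])
    # sort by (-|value|, row, col): lexsort keys last-first
    order = np.lexsort((ju, iu, -vals))
    keep = order[:m]
    adj = np.zeros((N, N), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return adj


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by breadth-first search,
    run for all sources simultaneously (level-synchronous frontier expansion
    as a boolean matrix product).  Unreachable pairs are +inf."""
    A = np.asarray(adj, dtype=bool)
    N = A.shape[0]
    D = np.full((N, N), np.inf)
    np.fill_diagonal(D, 0.0)
    reach = np.eye(N, dtype=bool)
    dist = 0
    while True:
        new_reach = reach | (reach @ A)
        newly = new_reach & ~reach
        if not newly.any():
            break
        dist += 1
        D[newly] = dist
        reach = new_reach
    return D


def _pairwise_inv_distances(adj: np.ndarray) -> np.ndarray:
    d = bfs_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d(i,j) over ordered node pairs (BFS distances;
    disconnected pairs contribute 0)."""
    adj = np.asarray(adj)
    N = adj.shape[0]
    if N < 2:
        return 0.0
    inv = _pairwise_inv_distances(adj)
    return float(inv.sum() / (N * (N - 1)))


def local_efficiency(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per node, the global efficiency of the subgraph induced by its
    neighbors (0 for nodes with fewer than 2 neighbors); plus the mean."""
    adj = np.asarray(adj)
    N = adj.shape[0]
    eloc = np.zeros(N)
    for i in range(N):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        eloc[i] = global_efficiency(sub)
    return eloc, float(eloc.mean())


@dataclass
class EfficiencySeries:
    """Density-integrated efficiencies per window plus temporal SDs."""

    global_eff: np.ndarray       # (W,)
    local_eff: np.ndarray        # (W,)
    sd_global: float
    sd_local: float
    grid: DensityGrid


def _grid_integrated_efficiencies(matrix: np.ndarray, grid: DensityGrid) -> tuple[float, float]:
    eg, el = [], []
    for d in grid.densities:
        adj = threshold_to_density(matrix, d)
        eg.append(global_efficiency(adj))
        el.append(local_efficiency(adj)[1])
    return float(np.mean(eg)), float(np.mean(el))


def efficiency_dynamics(window_matrices: np.ndarray, grid: DensityGrid) -> EfficiencySeries:
    """Per-window global/local efficiency averaged over the density grid,
    and their SDs over windows (W-1 denominator).  Needs >= 2 windows."""
    mats = np.asarray(window_matrices, dtype=float)
    if mats.ndim != 3:
        raise ValueError("expected a (W, N, N) stack of window matrices")
    if mats.shape[0] < 2:
        raise ValueError("need at least 2 windows for a temporal SD")
    eg = np.empty(mats.shape[0])
    el = np.empty(mats.shape[0])
    for i, M in enumerate(mats):
        eg[i], el[i] = _grid_integrated_efficiencies(M, grid)
    return EfficiencySeries(
        global_eff=eg,
        local_eff=el,
        sd_global=float(eg.std(ddof=1)),
        sd_local=float(el.std(ddof=1)),
        grid=grid,
    )


def static_efficiency(data: np.ndarray, grid: DensityGrid,
                      network_names: list[str] | None = None) -> tuple[float, float]:
    """Whole-time-course counterpart: full correlation matrix -> density
    thresholding -> grid-averaged global and local efficiency."""
    X = np.asarray(data, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = X.std(axis=0)
    const = sd <= 1e-12 * np.maximum(1.0, np.abs(X.mean(axis=0)))
    if np.any(const):
        j = int(np.flatnonzero(const)[0])
        name = network_names[j] if network_names else str(j)
        raise ValueError(f"constant time course in network {name!r}")
    corr = np.corrcoef(X, rowvar=False)
    return _grid_integrated_efficiencies(corr, grid)
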