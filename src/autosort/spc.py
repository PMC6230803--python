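"""Superparamagnetic clustering (SPC) of spike features.

Data points are mapped onto a q-state Potts spin model on a sparse
nearest-neighbour graph. Swendsen-Wang Monte Carlo dynamics are run on a fixed
grid of temperatures; at each temperature, pairs of neighbouring points whose
spins co-align in a large fraction of sweeps are linked, and the connected
components of the linked pairs are the clusters. At low temperature everything
co-aligns (one cluster); at high temperature correlations die and clusters
shatter; natural clusters live in the superparamagnetic regime in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree

__all__ = ["SPCParams", "InteractionGraph", "TemperatureMap",
           "build_interaction_graph", "run_spc"]


@dataclass
class SPCParams:
    """SPC configuration.

    The temperature grid is ``t_min..t_max`` in steps of ``t_step`` (defaults
    give 26 temperatures, T_0 = 0 to T_25 = 0.25). ``q_states`` is the number
    of Potts states, ``knn`` the neighbourhood size of the interaction graph,
    ``sweeps`` the number of post-burn-in Swendsen-Wang sweeps over which
    spin-spin correlations are estimated, and ``link_threshold`` the
    correlation cutoff that turns neighbour pairs into links.
    """

    t_min: float = 0.0
    t_max: float = 0.25
    t_step: float = 0.01
    q_states: int = 20
    knn: int = 11
    sweeps: int = 300
    burn_in: int = 100
    link_threshold: float = 0.5
    mutual_knn: bool = False  # True: mutual-KNN edges; False: symmetric union
    zscore: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn < 2:
            raise ValueError("knn must be >= 2")
        if not 0.0 < self.link_threshold < 1.0:
            raise ValueError("link_threshold must be in (0, 1)")

    @property
    def temperatures(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.t_step)) + 1
        return self.t_min + self.t_step * np.arange(n)


@dataclass
class InteractionGraph:
    """Sparse weighted graph: edge list (u < v) with ferromagnetic couplings J."""

    n_nodes: int
    edges_u: np.ndarray
    edges_v: np.ndarray
    couplings: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.edges_u.size

    def is_connected(self) -> bool:
        adj = coo_matrix(
            (np.ones(self.n_edges), (self.edges_u, self.edges_v)),
            shape=(self.n_nodes, self.n_nodes),
        )
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1


@dataclass
class TemperatureMap:
    """Cluster structure across the SPC temperature grid.

    ``labels[i]`` is the partition at temperature ``temperatures[i]``: an
    integer label per clustered event, where label k means the (k+1)-th
    largest cluster at that temperature (rank by size, 0-based).
    ``sizes[i]`` lists cluster sizes in descending order, so ``sizes[i][k]``
    is |C_{k+1}^{T_i}| in the temperature-plot sense.
    """

    temperatures: np.ndarray
    labels: np.ndarray            # (n_temps, n_events) rank-coded partitions
    sizes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_temperatures(self) -> int:
        return self.temperatures.size

    @property
    def n_events(self) -> int:
        return self.labels.shape[1]

    def size_of(self, t_index: int, rank: int) -> int:
        """|C_{rank}^{T_i}| with 1-based rank; 0 when the rank does not exist."""
        s = self.sizes[t_index]
        return int(s[rank - 1]) if 1 <= rank <= s.size else 0

    def members(self, t_index: int, rank: int) -> np.ndarray:
        """Event indices of the rank-th largest cluster (1-based rank)."""
        return np.flatnonzero(self.labels[t_index] == rank - 1)


def build_interaction_graph(features: np.ndarray, p: SPCParams) -> InteractionGraph:
    """Mutual-K-nearest-neighbour graph unioned with a minimum spanning tree.

    The MST union guarantees connectivity. Couplings are
    J_ij = (1/K_hat) * exp(-||v_i - v_j||^2 / (2 a^2)) with ``a`` the mean
    nearest-neighbour distance and K_hat the mean degree; coincident points
    get the maximal coupling 1/K_hat.
    """
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n = x.shape[0]
    if n < p.knn + 1:
        raise ValueError(f"need at least knn+1 = {p.knn + 1} points")
    if p.zscore:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    tree = cKDTree(x)
    k = min(p.knn + 1, n)
    dists, idx = tree.query(x, k=k)
    # mean nearest-neighbour distance (first column is the point itself)
    nn_dist = dists[:, 1]
    a = float(nn_dist.mean())
    if a == 0.0:
        a = 1.0  # all points coincident: any scale works, J collapses to max

    # KNN edge set: symmetric union by default (i-j linked when either lists
    # the other, so peripheral points keep degree >= K), mutual on request
    pairs = set()
    # with coincident points the query's self column is not guaranteed first,
    # so filter self explicitly instead of dropping column 0
    neighbor_sets = [set(int(j) for j in row if j != i)
                     for i, row in enumerate(idx)]
    for i in range(n):
        for j in neighbor_sets[i]:
            if not p.mutual_knn or i in neighbor_sets[j]:
                pairs.add((min(i, j), max(i, j)))

    # union with the MST of the full KNN graph for connectivity
    rows = np.repeat(np.arange(n), k - 1)
    cols = idx[:, 1:].ravel()
    vals = dists[:, 1:].ravel()
    vals = np.where(vals == 0.0, 1e-300, vals)  # MST needs nonzero weights
    knn_graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
    sym = knn_graph.maximum(knn_graph.T)
    mst = minimum_spanning_tree(sym)
    # the KNN graph may itself be disconnected; bridge remaining components
    n_comp, comp = connected_components(sym, directed=False)
    mst_coo = mst.tocoo()
    for u, v in zip(mst_coo.row, mst_coo.col):
        pairs.add((min(int(u), int(v)), max(int(u), int(v))))
    if n_comp > 1:
        reps = [np.flatnonzero(comp == c) for c in range(n_comp)]
        base = reps[0]
        for other in reps[1:]:
            d2 = ((x[base][:, None, :] - x[other][None, :, :]) ** 2).sum(-1)
            bi, oi = np.unravel_index(np.argmin(d2), d2.shape)
            u, v = int(base[bi]), int(other[oi])
            pairs.add((min(u, v), max(u, v)))

    eu, ev = (np.array(sorted(pairs), dtype=np.int64).T
              if pairs else (np.empty(0, np.int64), np.empty(0, np.int64)))
    d2 = ((x[eu] - x[ev]) ** 2).sum(axis=1)
    k_hat = 2.0 * eu.size / n
    couplings = np.exp(-d2 / (2.0 * a * a)) / k_hat
    return InteractionGraph(n_nodes=n, edges_u=eu, edges_v=ev, couplings=couplings)


def _rank_partition(component_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel a partition so label k is the (k+1)-th largest cluster."""
    counts = np.bincount(component_labels)
    order = np.argsort(-counts, kind="stable")
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(order.size)
    return rank_of[component_labels], counts[order]


def run_spc(graph: InteractionGraph, p: SPCParams) -> TemperatureMap:
    """Swendsen-Wang Potts dynamics over the temperature grid.

    At each temperature: spins start from a fresh random configuration; each
    sweep freezes every edge whose endpoints share a spin with probability
    1 - exp(-J_ij / T) (at T = 0 every positive-J edge freezes), takes the
    connected components of frozen edges as Swendsen-Wang clusters and
    redraws one uniform spin per cluster. After burn-in, the fraction f_ij of
    sweeps with equal endpoint spins is accumulated per edge, shifted to the
    Potts correlation G = (q f - 1)/(q - 1), and edges with G above the link
    threshold define the clusters. Fully deterministic given the seed.
    """
    rng = np.random.default_rng(p.seed)
    n, q = graph.n_nodes, p.q_states
    eu, ev, j = graph.edges_u, graph.edges_v, graph.couplings
    temps = p.temperatures
    all_labels = np.empty((temps.size, n), dtype=np.int64)
    all_sizes: list[np.ndarray] = []
    ones = np.ones(eu.size)

    for ti, t in enumerate(temps):
        if t <= 0.0:
            p_freeze = np.where(j > 0, 1.0, 0.0)
            frozen_all = True  # T=0 limit: every positive-J bond freezes
        else:
            p_freeze = 1.0 - np.exp(-j / t)
            frozen_all = False
        spins = rng.integers(q, size=n)
        equal_counts = np.zeros(eu.size, dtype=np.int64)
        for sweep in range(p.burn_in + p.sweeps):
            aligned = True if frozen_all else (spins[eu] == spins[ev])
            frozen = (rng.random(eu.size) < p_freeze) & aligned
            adj = coo_matrix((ones[frozen], (eu[frozen], ev[frozen])), shape=(n, n))
            _, comp = connected_components(adj, directed=False)
            new_spins = rng.integers(q, size=comp.max() + 1)
            spins = new_spins[comp]
            if sweep >= p.burn_in:
                equal_counts += spins[eu] == spins[ev]
        f = equal_counts / p.sweeps
        corr = (q * f - 1.0) / (q - 1.0)
        linked = corr > p.link_threshold
        # SPC capture step: every point also links to its maximum-correlation
        # neighbour provided that correlation clears a lower bar (half the
        # link threshold). Keeps cluster peripheries attached until the whole
        # cluster decorrelates, without percolating the paramagnetic phase.
        if eu.size and t > 0.0:
            nodes = np.concatenate([eu, ev])
            eidx = np.tile(np.arange(eu.size), 2)
            order_e = np.argsort(corr[eidx], kind="stable")
            best_edge = np.full(n, -1, dtype=np.int64)
            best_edge[nodes[order_e]] = eidx[order_e]  # last write = max corr
            cap_thr = 0.5 * p.link_threshold
            has_best = best_edge >= 0
            good = np.zeros(n, dtype=bool)
            good[has_best] = corr[best_edge[has_best]] > cap_thr
            capture = np.zeros(eu.size, dtype=bool)
            capture[best_edge[good]] = True
            linked = linked | capture
        adj = coo_matrix((ones[linked], (eu[linked], ev[linked])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
        labels, sizes = _rank_partition(comp)
        all_labels[ti] = labels
        all_sizes.append(sizes)

    return TemperatureMap(temperatures=temps, labels=all_labels, sizes=all_sizes)
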