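"""Graph metrics on binary undirected networks.

Implements degree, the rich-club coefficient phi(k) and its normalization
against degree-preserving randomized networks, and global / local / nodal
efficiency with hop-count distances.  Disconnected pairs contribute zero to
efficiency sums (the 1/inf = 0 convention), so every metric is defined on
arbitrary graphs, including empty ones.

The null model is the Maslov-Sneppen double-edge swap: repeatedly pick two
edges (a, b), (c, d) and rewire to (a, d), (c, b) when that creates neither
self-loops nor multi-edges.  Degree sequences are preserved exactly;
connectedness is not enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "degree",
    "rich_club_coefficient",
    "rich_club_curve",
    "degree_preserving_nulls",
    "normalized_rich_club",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "RichClubCurve",
    "NullEnsemble",
    "EfficiencySummary",
]

DEFAULT_N_NULLS = 100
DEFAULT_SWAPS_PER_EDGE = 10


def _binary(net) -> np.ndarray:
    """Accept a StructuralNetwork-like object or a raw 0/1 adjacency."""
    a = net.binary if hasattr(net, "binary") else np.asarray(net)
    a = (np.asarray(a) > 0).astype(np.int8)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    return a


def degree(net) -> np.ndarray:
    """Node degrees: row sums of the binary adjacency."""
    return _binary(net).sum(axis=1).astype(int)


def rich_club_coefficient(net, k: int) -> float:
    """phi(k) = realized / possible edges among nodes of degree > k.

    Returns ``nan`` when fewer than 2 nodes have degree above ``k``
    (the coefficient is undefined there, not zero).
    """
    a = _binary(net)
    if k < 0:
        raise ValueError("k must be >= 0")
    s = degree(a) > k
    m = int(s.sum())
    if m < 2:
        return float("nan")
    e_in = int(a[np.ix_(s, s)].sum()) // 2
    return 2.0 * e_in / (m * (m - 1))


@dataclass
class RichClubCurve:
    """phi and phi_norm on an aligned grid k = 1 .. max_degree - 1.

    Undefined values (club smaller than 2 nodes, or a zero null mean) are
    ``nan`` and carried through rather than dropped, so curves from
    different subjects stay aligned.
    """

    k_values: np.ndarray
    phi: np.ndarray
    phi_norm: np.ndarray | None = None
    null_mean_phi: np.ndarray | None = None
    n_nulls: int = 0

    def as_records(self, subject_id: str | None = None) -> list[dict]:
        rows = []
        for i, k in enumerate(self.k_values):
            row = {"k": int(k), "phi": float(self.phi[i])}
            if self.phi_norm is not None:
                row["phi_norm"] = float(self.phi_norm[i])
                row["null_mean_phi"] = float(self.null_mean_phi[i])
                row["n_nulls"] = self.n_nulls
            if subject_id is not None:
                row = {"subject_id": subject_id, **row}
            rows.append(row)
        return rows


def _phi_over_grid(edges: np.ndarray, deg: np.ndarray, k_values: np.ndarray) -> np.ndarray:
    """phi(k) for all k at once, given an edge list and the degree vector."""
    phi = np.full(len(k_values), np.nan)
    for i, k in enumerate(k_values):
        s = deg > k
        m = int(s.sum())
        if m < 2:
            continue
        if edges.size:
            e_in = int(np.count_nonzero(s[edges[:, 0]] & s[edges[:, 1]]))
        else:
            e_in = 0
        phi[i] = 2.0 * e_in / (m * (m - 1))
    return phi


def rich_club_curve(net) -> RichClubCurve:
    """phi(k) for k = 1 .. max_degree - 1 (empty grid for degenerate nets)."""
    a = _binary(net)
    deg = degree(a)
    kmax = int(deg.max(initial=0))
    k_values = np.arange(1, max(kmax, 1))
    edges = np.column_stack(np.nonzero(np.triu(a)))
    return RichClubCurve(k_values=k_values, phi=_phi_over_grid(edges, deg, k_values))


@dataclass
class NullEnsemble:
    """Degree-preserving randomized surrogates of one source network."""

    edge_lists: list[np.ndarray]
    n_nodes: int
    swaps_per_edge: int
    seed: int | None = None
    degenerate: bool = False  # True when no valid swap existed (e.g. complete graph)

    @property
    def n_nulls(self) -> int:
        return len(self.edge_lists)

    def adjacency(self, i: int) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        e = self.edge_lists[i]
        a[e[:, 0], e[:, 1]] = 1
        a[e[:, 1], e[:, 0]] = 1
        return a


def _swap_kernel_py(
    edges: np.ndarray, adj: np.ndarray, n_swaps: int, seed: int
) -> int:
    """Reference double-edge-swap kernel (see the numba version below)."""
    rng = np.random.default_rng(seed)
    n_edges = edges.shape[0]
    done = 0
    tries = 0
    max_tries = 20 * n_swaps + 100
    while done < n_swaps and tries < max_tries:
        tries += 1
        e1 = int(rng.integers(n_edges))
        e2 = int(rng.integers(n_edges))
        if e1 == e2:
            continue
        a, b = int(edges[e1, 0]), int(edges[e1, 1])
        c, d = int(edges[e2, 0]), int(edges[e2, 1])
        if rng.integers(2):
            c, d = d, c
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 0], edges[e1, 1] = min(a, d), max(a, d)
        edges[e2, 0], edges[e2, 1] = min(c, b), max(c, b)
        done += 1
    return done


try:  # jit-compiled kernel; the pure-python fallback is behaviorally identical
    from numba import njit

    @njit(cache=True)
    def _swap_kernel_nb(edges, adj, n_swaps, seed):  # pragma: no cover
        np.random.seed(seed)
        n_edges = edges.shape[0]
        done = 0
        tries = 0
        max_tries = 20 * n_swaps + 100
        while done < n_swaps and tries < max_tries:
            tries += 1
            e1 = np.random.randint(n_edges)
            e2 = np.random.randint(n_edges)
            if e1 == e2:
                continue
            a, b = edges[e1, 0], edges[e1, 1]
            c, d = edges[e2, 0], edges[e2, 1]
            if np.random.randint(2) == 1:
                c, d = d, c
            if a == d or c == b:
                continue
            if adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = False
            adj[b, a] = False
            adj[c, d] = False
            adj[d, c] = False
            adj[a, d] = True
            adj[d, a] = True
            adj[c, b] = True
            adj[b, c] = True
            edges[e1, 0], edges[e1, 1] = min(a, d), max(a, d)
            edges[e2, 0], edges[e2, 1] = min(c, b), max(c, b)
            done += 1
        return done

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _double_edge_swap(
    edges: np.ndarray, n_nodes: int, n_swaps: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Perform up to ``n_swaps`` successful swaps; returns (edges, n_done).

    A dense boolean adjacency gives O(1) multi-edge checks.  Failed
    proposals (self-loop or duplicate edge) are skipped and retried with
    fresh random picks, up to a bounded total number of tries.  The random
    stream is a fresh substream seeded from ``rng``, so results are
    reproducible given the caller's generator state.
    """
    edges = edges.copy()
    if len(edges) < 2:
        return edges, 0
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    adj[edges[:, 0], edges[:, 1]] = True
    adj[edges[:, 1], edges[:, 0]] = True
    seed = int(rng.integers(2**31 - 1))
    kernel = _swap_kernel_nb if _HAVE_NUMBA else _swap_kernel_py
    done = int(kernel(edges, adj, int(n_swaps), seed))
    return edges, done


def degree_preserving_nulls(
    net,
    n_nulls: int = DEFAULT_N_NULLS,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator | None = None,
) -> NullEnsemble:
    """Generate double-edge-swap surrogates with the exact degree sequence."""
    a = _binary(net)
    n = a.shape[0]
    edges = np.column_stack(np.nonzero(np.triu(a))).astype(np.int64)
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to randomize")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_swaps = swaps_per_edge * len(edges)
    lists = []
    degenerate = False
    for _ in range(n_nulls):
        swapped, n_done = _double_edge_swap(edges, n, n_swaps, rng)
        if n_done == 0:
            degenerate = True
        lists.append(swapped)
    if degenerate:
        warnings.warn(
            "no valid double-edge swap exists; null networks equal the source",
            stacklevel=2,
        )
    return NullEnsemble(
        edge_lists=lists,
        n_nodes=n,
        swaps_per_edge=swaps_per_edge,
        seed=seed if isinstance(seed, int) else None,
        degenerate=degenerate,
    )


def normalized_rich_club(
    net,
    n_nulls: int = DEFAULT_N_NULLS,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator | None = None,
) -> RichClubCurve:
    """phi_norm(k) = phi(k) / mean phi over degree-preserving nulls.

    Because the nulls share the source's degree sequence, the club at each
    ``k`` is the same node set in every surrogate; only the realized edge
    count within it varies.  Entries where phi is undefined, or where the
    null mean is zero, are ``nan``.
    """
    a = _binary(net)
    deg = degree(a)
    curve = rich_club_curve(a)
    ens = degree_preserving_nulls(a, n_nulls=n_nulls, swaps_per_edge=swaps_per_edge, seed=seed)
    null_phi = np.vstack(
        [_phi_over_grid(e, deg, curve.k_values) for e in ens.edge_lists]
    )
    null_mean = null_phi.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_norm = np.where(null_mean > 0, curve.phi / null_mean, np.nan)
    curve.phi_norm = phi_norm
    curve.null_mean_phi = null_mean
    curve.n_nulls = n_nulls
    return curve


def _hop_distances(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="D", directed=False, unweighted=True)


def global_efficiency(net) -> float:
    """Mean inverse hop distance over ordered node pairs (1/inf = 0)."""
    a = _binary(net)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = _hop_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(net, i: int | None = None) -> np.ndarray | float:
    """Per-node mean inverse hop distance to all other nodes.

    With ``i`` given, returns that node's scalar efficiency; otherwise the
    full length-N vector.
    """
    a = _binary(net)
    n = a.shape[0]
    if n < 2:
        return 0.0 if i is not None else np.zeros(n)
    d = _hop_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    eff = inv.sum(axis=1) / (n - 1)
    return float(eff[i]) if i is not None else eff


def local_efficiency(net) -> float:
    """Mean over nodes of the global efficiency of each neighborhood subgraph.

    Nodes with fewer than two neighbors contribute zero.
    """
    a = _binary(net)
    n = a.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs) < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


@dataclass
class EfficiencySummary:
    """Whole-network efficiency metrics for one subject."""

    global_eff: float
    local_eff: float
    mean_degree: float
    nodal_eff: np.ndarray = field(repr=False)

    @classmethod
    def from_network(cls, net) -> "EfficiencySummary":
        a = _binary(net)
        return cls(
            global_eff=global_efficiency(a),
            local_eff=local_efficiency(a),
            mean_degree=float(degree(a).mean()) if a.shape[0] else 0.0,
            nodal_eff=np.asarray(nodal_efficiency(a)),
        )
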