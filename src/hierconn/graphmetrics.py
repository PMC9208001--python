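"""Weighted graph metrics and degree-preserving null models.

Implements the weighted rich-club coefficient and its rewiring-null
normalization, Louvain community detection (best of seeded restarts),
participation coefficients and weighted global efficiency.

The weighted rich-club coefficient at degree level k is

    phi_w(k) = W_{>k} / sum of the E_{>k} largest weights in the network,

where W_{>k} and E_{>k} are the total weight and the number of edges among
the nodes of binary degree > k.  It is normalized by the mean coefficient of
an ensemble of degree-preserving rewired surrogates in which weights travel
with the edges; phi_norm(k) > 1 over a range of k indicates rich-club
organization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import ThresholdedNetwork

__all__ = [
    "RichClubCurve",
    "CommunityPartition",
    "NullEnsemble",
    "degree_and_strength",
    "rich_club_raw",
    "rewire_nulls",
    "rich_club_normalized",
    "detect_communities",
    "participation_coefficient",
    "global_efficiency",
]


@dataclass
class RichClubCurve:
    """phi_w over degree levels k = 1..k_max; NaN marks undefined levels."""

    k: np.ndarray
    phi: np.ndarray
    phi_rand: np.ndarray | None = None
    phi_norm: np.ndarray | None = None
    n_nulls: int = 0
    seed: int | None = None


@dataclass
class CommunityPartition:
    membership: np.ndarray  # node -> community id (0-based, contiguous)
    q: float
    resolution: float
    seed: int | None = None

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1 if self.membership.size else 0


@dataclass
class NullEnsemble:
    nulls: list[np.ndarray]
    swaps_per_edge: int
    seed: int


def degree_and_strength(net: ThresholdedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Binary degree (retained-edge count) and strength (weight sum) per node."""
    w = net.weights
    return np.count_nonzero(w, axis=1), w.sum(axis=1)


def _rich_club_from_weights(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi_w(k) for k = 1..max_degree, NaN where undefined."""
    deg = np.count_nonzero(w, axis=1)
    iu = np.triu_indices(w.shape[0], k=1)
    all_w = w[iu]
    all_w = all_w[all_w > 0]
    ranked = np.sort(all_w)[::-1]
    cum = np.cumsum(ranked)
    kmax = int(deg.max()) if deg.size else 0
    ks = np.arange(1, kmax + 1)
    phi = np.full(ks.shape, np.nan)
    for idx, k in enumerate(ks):
        members = deg > k
        if members.sum() < 2:
            continue
        sub = w[np.ix_(members, members)]
        m = int(np.count_nonzero(np.triu(sub, 1)))
        if m == 0:
            continue
        phi[idx] = sub.sum() / 2 / cum[m - 1]
    return ks, phi


def rich_club_raw(net: ThresholdedNetwork) -> RichClubCurve:
    """Raw weighted rich-club curve of a thresholded network."""
    ks, phi = _rich_club_from_weights(net.weights)
    return RichClubCurve(ks, phi)


def rewire_nulls(
    net: ThresholdedNetwork,
    n_nulls: int,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> NullEnsemble:
    """Degree-preserving double-edge-swap surrogates; weights travel with edges.

    Each surrogate applies ``swaps_per_edge * E`` swap attempts; an attempt is
    rejected if it would create a self-loop or a duplicate edge.  Every
    surrogate therefore preserves each node's binary degree exactly and the
    multiset of edge weights.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    mask = net.weights[iu, ju] > 0
    edges0 = np.column_stack([iu[mask], ju[mask]])
    weights0 = net.weights[iu[mask], ju[mask]]
    n_edges = edges0.shape[0]
    if n_edges < 2:
        warnings.warn("network too small to rewire; nulls equal the original")
        return NullEnsemble([net.weights.copy() for _ in range(n_nulls)], swaps_per_edge, seed or 0)

    nulls = []
    attempts = swaps_per_edge * n_edges
    for _ in range(n_nulls):
        edges = edges0.copy()
        present = {tuple(e) for e in map(tuple, edges)}
        pick = rng.integers(0, n_edges, size=(attempts, 2))
        flip = rng.random(attempts) < 0.5
        for t in range(attempts):
            e1, e2 = pick[t]
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip[t]:
                c, d = d, c
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            old1 = (a, b)  # rows are stored sorted
            old2 = (int(edges[e2][0]), int(edges[e2][1]))
            if new1 in present or new2 in present or new1 == new2:
                continue
            present.discard(old1)
            present.discard(old2)
            present.add(new1)
            present.add(new2)
            edges[e1] = new1
            edges[e2] = new2
        w = np.zeros_like(net.weights)
        w[edges[:, 0], edges[:, 1]] = weights0
        w = w + w.T
        nulls.append(w)
    return NullEnsemble(nulls, swaps_per_edge, seed or 0)


def rich_club_normalized(
    net: ThresholdedNetwork,
    n_nulls: int = 1000,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> RichClubCurve:
    """Rich-club curve normalized by the mean curve of rewired surrogates."""
    ks, phi = _rich_club_from_weights(net.weights)
    ensemble = rewire_nulls(net, n_nulls, swaps_per_edge, seed)
    null_curves = np.full((n_nulls, ks.size), np.nan)
    for i, w in enumerate(ensemble.nulls):
        _, phi_null = _rich_club_from_weights(w)
        null_curves[i, : phi_null.size] = phi_null
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        phi_rand = np.nanmean(null_curves, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = np.where(phi_rand > 0, phi / phi_rand, np.nan)
    return RichClubCurve(ks, phi, phi_rand, phi_norm, n_nulls=n_nulls, seed=seed)


def detect_communities(
    net: ThresholdedNetwork,
    resolution: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> CommunityPartition:
    """Louvain modularity maximization; best partition over seeded restarts.

    Isolated nodes become singleton communities.  Deterministic given seed.
    """
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    mask = net.weights[iu, ju] > 0
    g.add_weighted_edges_from(zip(iu[mask].tolist(), ju[mask].tolist(), net.weights[iu[mask], ju[mask]]))
    if g.number_of_edges() == 0:
        return CommunityPartition(np.arange(net.n_nodes), 0.0, resolution, seed)

    best_q, best = -np.inf, None
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed + r)
        q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best = q, comms
    membership = np.empty(net.n_nodes, dtype=int)
    for cid, nodes in enumerate(sorted(best, key=min)):
        membership[list(nodes)] = cid
    return CommunityPartition(membership, float(best_q), resolution, seed)


def participation_coefficient(
    net: ThresholdedNetwork,
    partition: CommunityPartition,
    weighted: bool = False,
) -> np.ndarray:
    """P_i = 1 - sum_s (kappa_is / k_i)^2 over communities s.

    ``kappa_is`` counts node i's retained edges into community s (binary, the
    default, matching the binary-degree convention) or sums their weights
    when ``weighted``.  Isolated nodes get P_i = 0.
    """
    if partition.membership.size != net.n_nodes:
        raise ValueError("partition does not cover the node set")
    a = (net.weights > 0).astype(float) if not weighted else net.weights
    n_comm = partition.n_communities
    onehot = np.zeros((net.n_nodes, n_comm))
    onehot[np.arange(net.n_nodes), partition.membership] = 1.0
    kappa = a @ onehot  # node x community
    k = a.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - np.sum((kappa / k[:, None]) ** 2, axis=1)
    p[k == 0] = 0.0
    return p


def global_efficiency(weights: np.ndarray) -> float:
    """Weighted global efficiency with edge lengths 1/w.

    ``E = mean over ordered pairs of 1/d_ij`` with 1/d = 0 for disconnected
    pairs; a single-node (or empty) graph has efficiency 0.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if n < 2:
        warnings.warn("global efficiency of a <2-node graph is 0")
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))
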