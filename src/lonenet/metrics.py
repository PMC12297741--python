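"""Node-level metrics on weighted signed networks.

Centrality (strength, closeness, betweenness, one-step expected influence),
signed spin-glass community detection by simulated annealing, and bridge
centrality (strength and one/two-step expected influence restricted to
edges leaving a node's community).  Shortest-path metrics use the inverse
absolute weight as edge length, so strong edges are short.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import as_rng

__all__ = [
    "as_weight_matrix",
    "centrality",
    "spinglass_communities",
    "spinglass_energy",
    "bridge_centrality",
    "zscore_table",
    "CommunityAssignment",
]


def as_weight_matrix(network) -> tuple[list[str], np.ndarray]:
    """Coerce a network-like object to (labels, symmetric weight matrix).

    Accepts fitted networks / parameter objects exposing ``labels`` and
    ``weights`` (or ``omega`` / ``pcor``), a square labeled DataFrame, a bare
    ndarray, or an explicit (labels, matrix) tuple.
    """
    if isinstance(network, tuple) and len(network) == 2:
        labels, W = network
        return list(labels), np.asarray(W, dtype=float)
    if isinstance(network, pd.DataFrame):
        if not network.index.equals(network.columns):
            raise ValueError("adjacency DataFrame must have matching index and columns")
        return [str(c) for c in network.columns], network.to_numpy(dtype=float)
    for attr in ("weights", "omega", "pcor"):
        if hasattr(network, attr) and hasattr(network, "labels"):
            return list(network.labels), np.asarray(getattr(network, attr), dtype=float)
    W = np.asarray(network, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("cannot interpret object as a weighted network")
    return [f"V{i + 1}" for i in range(W.shape[0])], W


def _distance_graph(labels: list[str], W: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(labels)
    p = len(labels)
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                G.add_edge(labels[i], labels[j], length=1.0 / abs(W[i, j]))
    return G


def centrality(network) -> pd.DataFrame:
    """Strength, closeness, betweenness and expected influence per node.

    Strength sums absolute weights, expected influence sums signed weights
    (identical whenever no edge is negative).  Closeness is the reciprocal of
    the summed shortest-path distances to the reachable nodes (within the
    node's component on disconnected graphs); betweenness gives fractional
    credit across tied shortest paths.
    """
    labels, W = as_weight_matrix(network)
    if len(labels) < 2:
        raise ValueError("need at least 2 nodes")
    strength = np.abs(W).sum(axis=1)
    ei = W.sum(axis=1)
    G = _distance_graph(labels, W)
    closeness = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        dists = nx.single_source_dijkstra_path_length(G, lab, weight="length")
        total = sum(d for node, d in dists.items() if node != lab)
        closeness[i] = 1.0 / total if total > 0 else 0.0
    btw = nx.betweenness_centrality(G, weight="length", normalized=False)
    return pd.DataFrame(
        {
            "strength": strength,
            "closeness": closeness,
            "betweenness": [btw[lab] for lab in labels],
            "expected_influence": ei,
        },
        index=pd.Index(labels, name="node"),
    )


def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores over nodes (sample SD); constant columns map to 0."""
    sd = table.std(ddof=1)
    out = (table - table.mean()) / sd.replace(0.0, np.nan)
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# Spin-glass communities
# ---------------------------------------------------------------------------


@dataclass
class CommunityAssignment:
    membership: pd.Series  # node -> community id (0-based, order of appearance)
    energy: float
    seed: int | None
    n_restarts: int

    def as_dict(self) -> dict[str, int]:
        return {str(k): int(v) for k, v in self.membership.items()}

    @property
    def n_communities(self) -> int:
        return int(self.membership.nunique())


def _signed_modularity_matrix(W: np.ndarray, gamma_pos: float, gamma_neg: float) -> np.ndarray:
    """Pairwise energy gains B_ij for co-assignment under the signed
    spin-glass Hamiltonian with configuration-model null terms applied to the
    positive and negative layers separately."""
    Wp = np.clip(W, 0.0, None)
    Wn = np.clip(-W, 0.0, None)
    B = np.zeros_like(W)
    for layer, gam, sign in ((Wp, gamma_pos, 1.0), (Wn, gamma_neg, -1.0)):
        m2 = layer.sum()  # == 2m
        if m2 > 0:
            s = layer.sum(axis=1)
            B += sign * (layer - gam * np.outer(s, s) / m2)
    np.fill_diagonal(B, 0.0)
    return B


def spinglass_energy(network, membership, gamma: float = 1.0) -> float:
    """Hamiltonian of a community assignment: H = -sum_{i<j, same community} B_ij."""
    labels, W = as_weight_matrix(network)
    B = _signed_modularity_matrix(W, gamma, gamma)
    c = np.asarray([membership[lab] for lab in labels])
    same = c[:, None] == c[None, :]
    return float(-0.5 * (B * same).sum())


def spinglass_communities(
    network,
    gamma: float = 1.0,
    seed: int | None = None,
    n_restarts: int = 10,
    t0: float = 1.0,
    cooling: float = 0.99,
    n_steps: int = 10_000,
) -> CommunityAssignment:
    """Signed spin-glass community detection by simulated annealing.

    Minimizes a Hamiltonian that rewards positive edges inside communities
    and negative edges between them, each against its own configuration-model
    null expectation scaled by the resolution ``gamma``.  Single-node moves
    under a geometric cooling schedule, best energy over ``n_restarts``
    random initializations; deterministic given ``seed``.
    """
    labels, W = as_weight_matrix(network)
    p = len(labels)
    B = _signed_modularity_matrix(W, gamma, gamma)
    rng = as_rng(seed)
    best_c, best_e = None, np.inf
    for _ in range(n_restarts):
        c = rng.integers(0, p, size=p)
        same = c[:, None] == c[None, :]
        energy = -0.5 * (B * same).sum()
        T = t0
        for _ in range(n_steps):
            i = int(rng.integers(p))
            new = int(rng.integers(p))
            old = c[i]
            if new != old:
                gain_old = B[i] @ (c == old)  # diag of B is zero, so i itself adds nothing
                gain_new = B[i] @ (c == new)
                dE = -(gain_new - gain_old)
                if dE < 0 or rng.random() < np.exp(-dE / max(T, 1e-12)):
                    c[i] = new
                    energy += dE
            T *= cooling
        # greedy polish: move nodes while any single move lowers the energy
        improved = True
        while improved:
            improved = False
            for i in range(p):
                gains = np.array([B[i] @ (c == k) for k in range(p)])
                k = int(np.argmax(gains))
                if gains[k] > gains[c[i]] + 1e-12:
                    energy -= gains[k] - gains[c[i]]
                    c[i] = k
                    improved = True
        if energy < best_e - 1e-12:
            best_e, best_c = float(energy), c.copy()
    # canonical labels in order of first appearance
    relabel: dict[int, int] = {}
    canon = np.empty(p, dtype=int)
    for i, k in enumerate(best_c):
        canon[i] = relabel.setdefault(int(k), len(relabel))
    membership = pd.Series(canon, index=pd.Index(labels, name="node"), name="community")
    return CommunityAssignment(membership, best_e, seed, n_restarts)


# ---------------------------------------------------------------------------
# Bridge centrality
# ---------------------------------------------------------------------------


def bridge_centrality(network, communities) -> pd.DataFrame:
    """Bridge strength and bridge expected influence (1- and 2-step).

    Bridge strength sums |w_ij| over neighbours j outside node i's community;
    bridge EI1 sums the signed weights; bridge EI2 adds the products
    w_ik * w_kj over all two-step paths i -> k -> j whose endpoint j lies
    outside i's community.  z-scored columns are appended.
    """
    labels, W = as_weight_matrix(network)
    if isinstance(communities, CommunityAssignment):
        comm = communities.as_dict()
    elif isinstance(communities, pd.Series):
        comm = {str(k): int(v) for k, v in communities.items()}
    else:
        comm = {str(k): int(v) for k, v in dict(communities).items()}
    missing = [lab for lab in labels if lab not in comm]
    if missing:
        raise ValueError(f"nodes missing from the community assignment: {missing}")
    c = np.asarray([comm[lab] for lab in labels])
    outside = c[:, None] != c[None, :]  # outside[i, j]: j not in i's community
    bridge_strength = (np.abs(W) * outside).sum(axis=1)
    ei1 = (W * outside).sum(axis=1)
    p = len(labels)
    ei2 = ei1.copy()
    for i in range(p):
        for k in range(p):
            if k == i or W[i, k] == 0:
                continue
            mask = outside[i].copy()
            mask[i] = False
            mask[k] = False
            ei2[i] += W[i, k] * (W[k] @ mask)
    table = pd.DataFrame(
        {
            "bridge_strength": bridge_strength,
            "bridge_ei1": ei1,
            "bridge_ei2": ei2,
        },
        index=pd.Index(labels, name="node"),
    )
    z = zscore_table(table).add_suffix("_z")
    return pd.concat([table, z], axis=1)
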