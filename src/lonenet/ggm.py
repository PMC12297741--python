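"""Regularized partial-correlation networks (EBIC-selected graphical lasso).

The network over continuous scores is a Gaussian graphical model: edges are
partial correlations obtained from a sparse precision matrix estimated by
the graphical lasso along a penalty path, with the extended BIC choosing the
penalty.  Also provides the unregularized partial-correlation network, the
Spearman validation matrix, and the focal-variable flow decomposition that
tiers the remaining variables by direct vs indirect connection to a focal
node.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

__all__ = [
    "GGMNetwork",
    "FlowDecomposition",
    "fit_ebicglasso",
    "pcor_network",
    "precision_to_pcor",
    "spearman_matrix",
    "extract_flow",
]

log = logging.getLogger(__name__)


@dataclass
class GGMNetwork:
    labels: list[str]
    pcor: np.ndarray
    selected_lambda: float = np.nan
    ebic: float = np.nan
    ebic_gamma: float = np.nan

    def __post_init__(self) -> None:
        self.pcor = np.asarray(self.pcor, dtype=float)
        if not np.allclose(self.pcor, self.pcor.T, atol=1e-10):
            raise ValueError("pcor must be symmetric")
        if np.any(np.abs(self.pcor) >= 1.0 + 1e-12):
            raise ValueError("partial correlations must satisfy |rho| < 1")
        np.fill_diagonal(self.pcor, 0.0)

    @property
    def weights(self) -> np.ndarray:
        return self.pcor

    def edge_count(self, tol: float = 1e-10) -> int:
        return int((np.abs(np.triu(self.pcor, 1)) > tol).sum())


@dataclass
class FlowDecomposition:
    focal: str
    tier1: list[str]  # directly connected to the focal node
    tier2: list[str]  # connected only through tier-1 nodes (>= 2 steps)
    unconnected: list[str] = field(default_factory=list)


def precision_to_pcor(K: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    d = np.sqrt(np.diag(K))
    rho = -K / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return (rho + rho.T) / 2.0


def spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations."""
    if len(data) < 3:
        raise ValueError("need at least 3 rows")
    return data.corr(method="spearman")


def _nearest_pd_correlation(S: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped repair of an indefinite correlation matrix."""
    vals, vecs = np.linalg.eigh(S)
    if vals.min() > floor:
        return S
    log.warning("correlation matrix not PD (min eig %.3g); clipping eigenvalues", vals.min())
    vals = np.clip(vals, floor, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def _correlation(data: pd.DataFrame, kind: str) -> np.ndarray:
    if kind not in ("pearson", "spearman"):
        raise ValueError("correlation_kind must be 'pearson' or 'spearman'")
    sd = data.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    return data.corr(method=kind).to_numpy()


def fit_ebicglasso(
    data: pd.DataFrame,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    correlation_kind: str = "pearson",
    lambdas: np.ndarray | None = None,
) -> GGMNetwork:
    """Estimate a GGM by graphical lasso with EBIC penalty selection.

    The penalty path runs from the smallest lambda yielding the empty graph
    down to ``lambda_min_ratio`` times that value (or a user-supplied grid);
    for each lambda the EBIC is
    ``-n (log det K - tr(S K)) + E log n + 4 E gamma log p`` with E the number
    of selected edges, and the minimizer is returned as a partial-correlation
    network.
    """
    n = len(data)
    if n <= 3:
        raise ValueError("need more than 3 rows")
    labels = [str(c) for c in data.columns]
    p = len(labels)
    S = _correlation(data.dropna(), correlation_kind)
    S = _nearest_pd_correlation(S)
    if lambdas is None:
        lam_max = np.abs(S - np.eye(p)).max()
        if lam_max <= 0:
            return GGMNetwork(labels, np.zeros((p, p)), np.inf, np.nan, gamma)
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    best = None
    n_failed = 0
    for lam in np.asarray(lambdas, float):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, K = graphical_lasso(S, alpha=float(lam), max_iter=200)
        except Exception:
            n_failed += 1
            continue
        E = int((np.abs(np.triu(K, 1)) > 1e-10).sum())
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            n_failed += 1
            continue
        ebic = -n * (logdet - np.trace(S @ K)) + E * np.log(n) + 4 * E * gamma * np.log(p)
        if best is None or ebic < best[0]:
            best = (float(ebic), float(lam), K)
    if best is None:
        raise RuntimeError("graphical lasso failed on every penalty value")
    if n_failed:
        log.warning("graphical lasso failed at %d of %d penalty values", n_failed, len(lambdas))
    ebic, lam, K = best
    return GGMNetwork(labels, precision_to_pcor(K), lam, ebic, gamma)


def pcor_network(data: pd.DataFrame, correlation_kind: str = "pearson") -> GGMNetwork:
    """Unregularized (saturated) partial-correlation network from the inverse
    correlation matrix; the fast estimator used in stability analyses."""
    labels = [str(c) for c in data.columns]
    S = _nearest_pd_correlation(_correlation(data.dropna(), correlation_kind))
    K = np.linalg.inv(S)
    K = (K + K.T) / 2.0
    return GGMNetwork(labels, precision_to_pcor(K))


def extract_flow(network: GGMNetwork, focal: str, tol: float = 1e-10) -> FlowDecomposition:
    """Tier the variables by how they reach a focal node.

    Tier 1: nonzero direct edge to the focal node.  Tier 2: reachable from
    the focal node but only through tier-1 nodes.  Variables with no path to
    the focal node are listed as unconnected.
    """
    if focal not in network.labels:
        raise ValueError(f"unknown focal variable: {focal!r}")
    G = nx.Graph()
    G.add_nodes_from(network.labels)
    p = len(network.labels)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(network.pcor[i, j]) > tol:
                G.add_edge(network.labels[i], network.labels[j])
    tier1 = sorted(G.neighbors(focal))
    reachable = nx.node_connected_component(G, focal) - {focal}
    tier2 = sorted(reachable - set(tier1))
    unconnected = sorted(set(network.labels) - reachable - {focal})
    return FlowDecomposition(focal, tier1, tier2, unconnected)
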