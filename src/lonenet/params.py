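"""Parameter containers shared across the estimation and simulation modules.

These hold ground-truth or fitted parameters for the three model families
used throughout the package: the Ising model for binary symptom data, the
Gaussian graphical model (GGM) for continuous scores, and the moderated
pairwise model whose edges vary linearly with a continuous moderator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IsingParameters",
    "GroundTruthGGM",
    "ModeratedTruth",
    "LikertSurvey",
    "validate_symmetric_zero_diag",
]


def validate_symmetric_zero_diag(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check a weight matrix is square, symmetric and has an exactly-zero diagonal."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.any(mat.diagonal() != 0.0):
        raise ValueError(f"{name} must have an exactly zero diagonal")
    return mat


@dataclass
class IsingParameters:
    """Thresholds and pairwise weights of a binary pairwise Markov random field.

    The model over x in {0,1}^p is
    ``P(x) ∝ exp(Σ_i tau_i x_i + Σ_{i<j} omega_ij x_i x_j)``.
    ``tau`` are the logistic-regression intercepts (symptom propensity);
    ``omega`` is the symmetric edge-weight matrix with zero diagonal.
    """

    labels: list[str]
    tau: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        self.omega = validate_symmetric_zero_diag(self.omega, "omega")
        p = len(self.labels)
        if len(set(self.labels)) != p:
            raise ValueError("node labels must be unique")
        if self.tau.shape[0] != p or self.omega.shape[0] != p:
            raise ValueError(
                f"inconsistent sizes: {p} labels, tau {self.tau.shape[0]}, "
                f"omega {self.omega.shape[0]}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def perturbed(self, node: str, delta: float) -> "IsingParameters":
        """Copy of the parameters with one node's threshold shifted by ``delta``."""
        idx = self.labels.index(node)
        tau = self.tau.copy()
        tau[idx] += delta
        return IsingParameters(self.labels, tau, self.omega.copy())


@dataclass
class GroundTruthGGM:
    """A known Gaussian graphical model given by its precision matrix K.

    The implied partial correlations are ``rho_ij = -K_ij / sqrt(K_ii K_jj)``
    with zero diagonal.
    """

    labels: list[str]
    precision: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        K = np.asarray(self.precision, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("precision must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("precision must be symmetric")
        if K.shape[0] != len(self.labels):
            raise ValueError("labels / precision size mismatch")
        try:
            np.linalg.cholesky(K)
        except np.linalg.LinAlgError as exc:
            raise ValueError("precision matrix is not positive definite") from exc
        self.precision = K

    @property
    def pcor(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.precision))
        rho = -self.precision / np.outer(d, d)
        np.fill_diagonal(rho, 0.0)
        return rho

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass
class ModeratedTruth:
    """Ground truth for a pairwise Gaussian model moderated by a scalar.

    The conditional edge between i and j at moderator value s is
    ``w0_ij + m_ij * s``; the conditional precision used for sampling is
    ``K(s) = I - W(s)`` so that the conditional partial correlation equals
    the conditional edge weight.
    """

    labels: list[str]
    base_weights: np.ndarray
    moderation_weights: np.ndarray
    moderator_mean: float = 0.0
    moderator_sd: float = 1.0
    # |s| is clipped here when drawing the moderator so the conditional
    # model stays positive definite for moderate moderation strengths
    moderator_truncation: float | None = 3.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.base_weights = validate_symmetric_zero_diag(self.base_weights, "base_weights")
        self.moderation_weights = validate_symmetric_zero_diag(
            self.moderation_weights, "moderation_weights"
        )
        p = len(self.labels)
        if self.base_weights.shape[0] != p or self.moderation_weights.shape[0] != p:
            raise ValueError("labels / weight matrix size mismatch")
        if self.moderator_sd < 0:
            raise ValueError("moderator_sd must be >= 0")

    def conditional_weights(self, s: float) -> np.ndarray:
        return self.base_weights + self.moderation_weights * s

    def conditional_precision(self, s: float) -> np.ndarray:
        return np.eye(len(self.labels)) - self.conditional_weights(s)


@dataclass
class LikertSurvey:
    """Participants x items table of 1..k Likert responses with key metadata.

    ``responses`` uses pandas' nullable integer dtype so missing answers are
    represented as <NA>.  ``reverse_keyed`` lists the positively-worded items
    that must be reverse-scored before summing, and ``scale_map`` assigns each
    item to its instrument.
    """

    responses: pd.DataFrame
    reverse_keyed: set[str] = field(default_factory=set)
    scale_map: dict[str, str] = field(default_factory=dict)
    n_levels: int = 5

    def __post_init__(self) -> None:
        self.reverse_keyed = set(self.reverse_keyed)
        unknown = self.reverse_keyed - set(self.responses.columns)
        if unknown:
            raise ValueError(f"reverse_keyed items not in survey: {sorted(unknown)}")
        vals = self.responses.to_numpy(dtype="float64", na_value=np.nan)
        bad = (~np.isnan(vals)) & ((vals < 1) | (vals > self.n_levels) | (vals % 1 != 0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"response out of 1..{self.n_levels} at row "
                f"{self.responses.index[r]!r}, item {self.responses.columns[c]!r}"
            )
        self.responses = self.responses.astype("Int64")

    @property
    def items(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def n_participants(self) -> int:
        return len(self.responses)
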