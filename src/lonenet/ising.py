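"""Ising network estimation by nodewise L1-regularized logistic regression.

Each binary symptom is regressed on all others along a path of L1 penalties;
the penalty for each node is selected by the extended BIC (EBIC), and the two
nodewise estimates of every edge are combined under the AND (default) or OR
rule with their arithmetic mean.  Thresholds are the selected models'
intercepts; the intercept carries a vanishing share of the penalty (the
constant column is scaled up internally) so it is effectively unpenalized —
it is the handle later perturbed by in-silico interventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.linear_model import LogisticRegression

from .params import IsingParameters

__all__ = ["IsingFitConfig", "IsingFitResult", "fit_ising", "ebic_score"]

_INTERCEPT_SCALING = 100.0


def ebic_score(
    neg2_loglik: float, k_params: int, n: int, p_candidates: int, gamma: float
) -> float:
    """Extended BIC: -2 log L + k ln(n) + 2 gamma k ln(P).

    ``P`` is the number of candidate predictors; ``gamma`` = 0 recovers the
    ordinary BIC, larger values prefer sparser models.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(
        neg2_loglik + k_params * np.log(n) + 2.0 * gamma * k_params * np.log(max(p_candidates, 1))
    )


@dataclass
class IsingFitConfig:
    ebic_gamma: float = 0.25
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    rule: str = "AND"

    def __post_init__(self) -> None:
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")


@dataclass
class IsingFitResult:
    params: IsingParameters
    selected_lambda: np.ndarray
    node_ebic: np.ndarray
    nodewise_coefs: np.ndarray  # row i = coefficients of node i's regression
    config: IsingFitConfig = field(default_factory=IsingFitConfig)

    @property
    def labels(self) -> list[str]:
        return self.params.labels

    @property
    def weights(self) -> np.ndarray:
        return self.params.omega


def _node_path(
    y: np.ndarray, Z: np.ndarray, n_lambda: int, lambda_min_ratio: float, gamma: float
) -> tuple[float, np.ndarray, float, float]:
    """Fit one node's penalty path and return (tau, coefs, lambda, ebic) at the
    EBIC minimum."""
    n, q = Z.shape
    ybar = y.mean()
    lam_max = np.abs(Z.T @ (y - ybar)).max() / n
    if lam_max <= 0:  # node unrelated to every other: intercept-only model
        tau = float(logit(ybar))
        ll = n * (ybar * np.log(ybar) + (1 - ybar) * np.log1p(-ybar))
        return tau, np.zeros(q), np.inf, ebic_score(-2 * ll, 0, n, q, gamma)
    lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    best = None
    clf = LogisticRegression(
        penalty="l1",
        solver="liblinear",
        fit_intercept=True,
        intercept_scaling=_INTERCEPT_SCALING,
        tol=1e-6,
        max_iter=1000,
        random_state=0,  # liblinear shuffles internally; fix for reproducibility
    )
    for lam in lams:
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Z, y)
        coefs = clf.coef_[0].copy()
        tau = float(clf.intercept_[0])
        eta = tau + Z @ coefs
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        k = int(np.count_nonzero(coefs))
        score = ebic_score(-2 * ll, k, n, q, gamma)
        if best is None or score < best[3]:
            best = (tau, coefs, float(lam), score)
    return best


def fit_ising(
    data: pd.DataFrame | np.ndarray, config: IsingFitConfig | None = None
) -> IsingFitResult:
    """Fit an Ising network to complete binary data.

    Runs the nodewise L1-logistic path for each symptom, selects each node's
    penalty by EBIC, then symmetrizes: under the AND rule an edge exists only
    when both nodewise coefficients are nonzero (their mean is the weight);
    under OR, a single surviving coefficient is used as-is.
    """
    config = config or IsingFitConfig()
    if isinstance(data, pd.DataFrame):
        labels = [str(c) for c in data.columns]
        X = data.to_numpy(dtype="float64", na_value=np.nan)
    else:
        X = np.asarray(data, dtype=float)
        labels = [f"V{i + 1}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("fit_ising requires complete rows (no missing values)")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("data must be binary 0/1")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than nodes ({p})")
    for j, lab in enumerate(labels):
        if X[:, j].min() == X[:, j].max():
            raise ValueError(f"constant column: {lab!r}")

    tau = np.zeros(p)
    B = np.zeros((p, p))  # B[i, j]: coefficient of node j in node i's regression
    sel_lambda = np.full(p, np.nan)
    node_ebic = np.full(p, np.nan)
    if p == 1:
        tau[0] = logit(X[:, 0].mean())
    else:
        for i in range(p):
            others = [j for j in range(p) if j != i]
            try:
                t_i, coefs, lam, score = _node_path(
                    X[:, i], X[:, others], config.n_lambda, config.lambda_min_ratio,
                    config.ebic_gamma,
                )
            except Exception as exc:  # pragma: no cover - solver failure is rare
                warnings.warn(
                    f"nodewise fit failed for {labels[i]!r} ({exc}); "
                    "falling back to the intercept-only model"
                )
                t_i, coefs, lam, score = float(logit(X[:, i].mean())), np.zeros(p - 1), np.inf, np.nan
            tau[i] = t_i
            B[i, others] = coefs
            sel_lambda[i] = lam
            node_ebic[i] = score

    omega = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = B[i, j], B[j, i]
            if config.rule == "AND":
                w = 0.5 * (a + b) if (a != 0 and b != 0) else 0.0
            else:
                if a != 0 and b != 0:
                    w = 0.5 * (a + b)
                else:
                    w = a + b  # at most one is nonzero
            omega[i, j] = omega[j, i] = w
    params = IsingParameters(labels, tau, omega)
    return IsingFitResult(params, sel_lambda, node_ebic, B, config)
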