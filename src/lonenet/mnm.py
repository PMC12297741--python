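"""Moderated network model: pairwise edges that vary with a continuous moderator.

Each variable is regressed (L1-regularized, EBIC- or CV-selected penalty) on
all other variables, the moderator, and every variable x moderator product.
The two nodewise estimates of each pairwise weight and of each three-way
interaction weight are combined under the AND rule with their arithmetic
mean, giving a base network ``w0`` and a moderation matrix ``m`` such that
the conditional edge at moderator value s is ``w0 + m s``.  All variables
are standardized internally, so weights live on the z-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .ising import ebic_score
from .simulate import as_rng

__all__ = ["MnmParameters", "MnmStability", "fit_mnm", "conditional_edge", "resample_mnm"]


@dataclass
class MnmParameters:
    """Pairwise and moderation weights of a fitted moderated network.

    ``labels`` lists the variables followed by the moderator; ``pairwise``
    is the symmetric (p+1)x(p+1) base-weight matrix (moderator included as a
    node), ``moderation`` the symmetric matrix of moderator x pair
    interaction weights (zero on the moderator row/column).
    """

    labels: list[str]
    pairwise: np.ndarray
    moderation: np.ndarray
    moderator: str
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pairwise", "moderation"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if not np.allclose(mat, mat.T, atol=1e-10) or np.any(mat.diagonal() != 0):
                raise ValueError(f"{name} must be symmetric with zero diagonal")
            setattr(self, name, mat)
        if self.moderator not in self.labels:
            raise ValueError("moderator must be among the labels")

    def pair_index(self, a: str, b: str) -> tuple[int, int]:
        if a not in self.labels or b not in self.labels or a == b:
            raise KeyError(f"unknown pair: ({a!r}, {b!r})")
        return self.labels.index(a), self.labels.index(b)


@dataclass
class MnmStability:
    proportions: pd.DataFrame  # per parameter: proportion of resamples nonzero
    n_boot: int
    seed: int | None


def _ebic_lasso(y: np.ndarray, Z: np.ndarray, gamma: float, n_lambda: int,
                lambda_min_ratio: float) -> np.ndarray:
    """Lasso path on centered data with EBIC selection; returns coefficients."""
    n, q = Z.shape
    lam_max = np.abs(Z.T @ y).max() / n
    if lam_max <= 0:
        return np.zeros(q)
    alphas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    _, coefs, _ = lasso_path(Z, y, alphas=alphas)
    best, best_coef = np.inf, np.zeros(q)
    for c in coefs.T:
        rss = float(((y - Z @ c) ** 2).sum())
        k = int(np.count_nonzero(c))
        score = ebic_score(n * np.log(max(rss, 1e-300) / n), k, n, q, gamma)
        if score < best:
            best, best_coef = score, c
    return best_coef


def _cv_lasso(y: np.ndarray, Z: np.ndarray, n_folds: int, n_lambda: int,
              lambda_min_ratio: float, seed: int | None) -> np.ndarray:
    n, q = Z.shape
    lam_max = np.abs(Z.T @ y).max() / n
    if lam_max <= 0:
        return np.zeros(q)
    alphas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    err = np.zeros(len(alphas))
    for tr, te in kf.split(Z):
        _, coefs, _ = lasso_path(Z[tr], y[tr], alphas=alphas)
        pred = Z[te] @ coefs
        err += ((y[te, None] - pred) ** 2).sum(axis=0)
    lam = alphas[int(np.argmin(err))]
    _, coefs, _ = lasso_path(Z, y, alphas=[lam])
    return coefs[:, 0]


def fit_mnm(
    data: pd.DataFrame,
    moderator: pd.Series | str,
    selection: str = "ebic",
    gamma: float = 0.25,
    n_folds: int = 10,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
    seed: int | None = None,
    moderated: bool = True,
) -> MnmParameters:
    """Fit the moderated network by nodewise regularized regression.

    ``moderator`` is a column name of ``data`` or a separate aligned Series.
    Every variable's design holds the other variables, the moderator, and the
    variable x moderator products; the moderator's own regression holds the
    plain variables.  Edges are AND-rule means of the two nodewise estimates.
    With ``moderated=False`` the moderator and its products are dropped from
    every design, reducing the fit to a plain nodewise-lasso GGM.
    """
    if isinstance(moderator, str):
        if moderator not in data.columns:
            raise ValueError(f"moderator column {moderator!r} not in data")
        mod = data[moderator].astype(float)
        vars_df = data.drop(columns=[moderator])
    else:
        mod = moderator.astype(float)
        vars_df = data
        if not mod.index.equals(vars_df.index):
            raise ValueError("moderator index must match the data index")
    if vars_df.isna().any().any() or mod.isna().any():
        raise ValueError("fit_mnm requires complete rows")
    if float(mod.std(ddof=1)) == 0:
        raise ValueError("moderator has zero variance")
    sd = vars_df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant column(s): {sd[sd == 0].index.tolist()}")

    var_names = [str(c) for c in vars_df.columns]
    mod_name = str(mod.name) if mod.name is not None else "moderator"
    p = len(var_names)
    X = ((vars_df - vars_df.mean()) / sd).to_numpy(dtype=float)
    s = ((mod - mod.mean()) / mod.std(ddof=1)).to_numpy(dtype=float)

    def select(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
        Zc = Z - Z.mean(axis=0)
        yc = y - y.mean()
        if selection == "ebic":
            return _ebic_lasso(yc, Zc, gamma, n_lambda, lambda_min_ratio)
        if selection == "cv":
            return _cv_lasso(yc, Zc, n_folds, n_lambda, lambda_min_ratio, seed)
        raise ValueError("selection must be 'ebic' or 'cv'")

    # pair_hat[i, j]: coefficient of x_j in node i's regression
    pair_hat = np.zeros((p, p))
    mod_hat = np.zeros((p, p))  # coefficient of x_j * s in node i's regression
    mod_main = np.zeros(p)  # coefficient of s in node i's regression
    for i in range(p):
        others = [j for j in range(p) if j != i]
        if moderated:
            Z = np.column_stack([X[:, others], s[:, None], X[:, others] * s[:, None]])
        else:
            Z = X[:, others]
        coef = select(X[:, i], Z)
        q = len(others)
        pair_hat[i, others] = coef[:q]
        if moderated:
            mod_main[i] = coef[q]
            mod_hat[i, others] = coef[q + 1 :]
    mod_on_vars = select(s, X) if moderated else np.zeros(p)

    labels = var_names + [mod_name]
    w0 = np.zeros((p + 1, p + 1))
    m = np.zeros((p + 1, p + 1))
    for i in range(p):
        for j in range(i + 1, p):
            if pair_hat[i, j] != 0 and pair_hat[j, i] != 0:
                w0[i, j] = w0[j, i] = 0.5 * (pair_hat[i, j] + pair_hat[j, i])
            if mod_hat[i, j] != 0 and mod_hat[j, i] != 0:
                m[i, j] = m[j, i] = 0.5 * (mod_hat[i, j] + mod_hat[j, i])
        if mod_main[i] != 0 and mod_on_vars[i] != 0:
            w0[i, p] = w0[p, i] = 0.5 * (mod_main[i] + mod_on_vars[i])
    return MnmParameters(
        labels, w0, m, mod_name,
        selection={"method": selection, "gamma": gamma, "n_lambda": n_lambda},
    )


def conditional_edge(params: MnmParameters, pair: tuple[str, str], s: float) -> float:
    """Edge weight between a pair at moderator value ``s``: w0 + m * s."""
    i, j = params.pair_index(*pair)
    return float(params.pairwise[i, j] + params.moderation[i, j] * s)


def resample_mnm(
    data: pd.DataFrame,
    moderator: pd.Series | str,
    n_boot: int = 1000,
    seed: int | None = None,
    max_failure_rate: float = 0.10,
    **fit_kwargs,
) -> MnmStability:
    """Row-resampling bootstrap of the MNM: per-parameter nonzero proportions."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = as_rng(seed)
    full = fit_mnm(data, moderator, **fit_kwargs)
    labels = full.labels
    P = len(labels)
    names, kinds, ii, jj = [], [], [], []
    for i in range(P):
        for j in range(i + 1, P):
            names.append(f"{labels[i]}--{labels[j]}")
            kinds.append("pairwise")
            ii.append(i)
            jj.append(j)
    pvar = len(labels) - 1
    for i in range(pvar):
        for j in range(i + 1, pvar):
            names.append(f"{full.moderator}x{labels[i]}x{labels[j]}")
            kinds.append("moderation")
            ii.append(i)
            jj.append(j)
    counts = np.zeros(len(names))
    n = len(data)
    sep_mod = not isinstance(moderator, str)
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        d = data.iloc[idx].reset_index(drop=True)
        mod_b = moderator.iloc[idx].reset_index(drop=True) if sep_mod else moderator
        try:
            fit = fit_mnm(d, mod_b, **fit_kwargs)
        except Exception:
            n_failed += 1
            continue
        for k, (kind, i, j) in enumerate(zip(kinds, ii, jj)):
            mat = fit.pairwise if kind == "pairwise" else fit.moderation
            counts[k] += mat[i, j] != 0
    n_ok = n_boot - n_failed
    if n_failed > max_failure_rate * n_boot or n_ok == 0:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    table = pd.DataFrame(
        {"parameter": names, "kind": kinds, "nonzero_proportion": counts / n_ok}
    )
    return MnmStability(table, n_boot, seed)
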