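"""Bootstrap accuracy and stability of network estimates.

Two resampling schemes: a nonparametric bootstrap over participants giving
per-edge confidence intervals, and a case-dropping bootstrap giving the
correlation-stability (CS) coefficient — the largest fraction of cases that
can be dropped while the re-estimated centrality still correlates at least
``cor_threshold`` with the full-sample centrality in at least ``prob`` of
the resamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import as_weight_matrix, centrality
from .simulate import as_rng

__all__ = ["StabilityResult", "edge_ci_bootstrap", "case_dropping_cs"]

DEFAULT_DROP_PROPS = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))


@dataclass
class StabilityResult:
    cs: float
    curve: pd.DataFrame  # per drop proportion: mean correlation, P(corr >= threshold)
    metric: str
    cor_threshold: float
    prob: float
    n_boot: int
    seed: int | None


def _edge_vector(network) -> tuple[list[tuple[str, str]], np.ndarray]:
    labels, W = as_weight_matrix(network)
    p = len(labels)
    pairs = [(labels[i], labels[j]) for i in range(p) for j in range(i + 1, p)]
    vals = np.array([W[i, j] for i in range(p) for j in range(i + 1, p)])
    return pairs, vals


def edge_ci_bootstrap(
    data: pd.DataFrame,
    estimator,
    n_boot: int = 1000,
    seed: int | None = None,
    max_failure_rate: float = 0.10,
    **estimator_kwargs,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for every edge weight.

    ``estimator`` maps a data table to any network object understood by
    ``metrics.as_weight_matrix`` (e.g. ``ising.fit_ising`` or
    ``ggm.fit_ebicglasso``).  Rows are resampled with replacement; failed
    replicates are skipped and counted, erroring if more than
    ``max_failure_rate`` fail.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = as_rng(seed)
    pairs, point = _edge_vector(estimator(data, **estimator_kwargs))
    n = len(data)
    draws = np.full((n_boot, len(pairs)), np.nan)
    n_failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            net = estimator(data.iloc[idx].reset_index(drop=True), **estimator_kwargs)
        except Exception:
            n_failed += 1
            continue
        _, draws[b] = _edge_vector(net)
    if n_failed > max_failure_rate * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    ok = ~np.isnan(draws[:, 0])
    lo, hi = np.nanpercentile(draws[ok], [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "node_i": [a for a, _ in pairs],
            "node_j": [b for _, b in pairs],
            "estimate": point,
            "boot_mean": draws[ok].mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
            "n_failed": n_failed,
        }
    )


def _stability_correlation(full: np.ndarray, sub: np.ndarray, kind: str) -> float:
    """Correlation between full-sample and subsample centralities.

    A vector without variance across nodes (e.g. the all-zero strengths of an
    empty network) carries no ordering information and counts as 0; identical
    non-degenerate vectors count as perfectly stable (1).
    """
    if np.std(full) == 0 or np.std(sub) == 0:
        return 0.0
    if np.array_equal(full, sub):
        return 1.0
    if kind == "spearman":
        return float(stats.spearmanr(full, sub).statistic)
    return float(np.corrcoef(full, sub)[0, 1])


def case_dropping_cs(
    data: pd.DataFrame,
    estimator,
    metric: str = "strength",
    drop_props: tuple[float, ...] = DEFAULT_DROP_PROPS,
    n_boot: int = 1000,
    cor_threshold: float = 0.7,
    prob: float = 0.95,
    seed: int | None = None,
    correlation: str = "spearman",
    **estimator_kwargs,
) -> StabilityResult:
    """Case-dropping bootstrap of a centrality metric and its CS coefficient.

    For each drop proportion, the estimator is refit on random row subsets
    and the chosen centrality column is correlated (Spearman by default) with
    the full-sample value; CS is the largest tested proportion whose
    correlations reach ``cor_threshold`` with empirical probability
    ``prob`` (0 if none does).
    """
    if metric not in ("strength", "closeness", "betweenness", "expected_influence"):
        raise ValueError(f"unknown centrality metric: {metric!r}")
    rng = as_rng(seed)
    full = centrality(estimator(data, **estimator_kwargs))[metric].to_numpy()
    n = len(data)
    rows = []
    cs = 0.0
    for prop_drop in sorted(drop_props):
        keep = n - int(math.floor(prop_drop * n))
        if keep < 3:
            raise ValueError(f"drop proportion {prop_drop} leaves fewer than 3 rows")
        cors = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                sub = centrality(estimator(data.iloc[idx].reset_index(drop=True),
                                           **estimator_kwargs))[metric].to_numpy()
                cors[b] = _stability_correlation(full, sub, correlation)
            except Exception:
                cors[b] = np.nan
        valid = cors[~np.isnan(cors)]
        if valid.size < (1 - 0.10) * n_boot:
            raise RuntimeError(f"too many failed refits at drop proportion {prop_drop}")
        p_ok = float((valid >= cor_threshold).mean())
        rows.append((prop_drop, float(valid.mean()), p_ok))
        if p_ok >= prob:
            cs = max(cs, prop_drop)
    curve = pd.DataFrame(rows, columns=["drop_proportion", "mean_correlation", "prop_above"])
    return StabilityResult(cs, curve, metric, cor_threshold, prob, n_boot, seed)
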