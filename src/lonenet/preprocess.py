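"""Data preparation ahead of network estimation.

Covers the full preprocessing path of a symptom-network survey study:
reverse-scoring positively worded items, dichotomizing 5-point responses
into symptom present/absent, excluding participants with excessive missing
data, screening for topologically redundant items, building a principal-
component SES composite from ordinal indicators, and residualizing scores
on demographic covariates for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import LikertSurvey

__all__ = [
    "reverse_score",
    "dichotomize",
    "filter_missing",
    "detect_redundant_items",
    "compute_ses_index",
    "residualize",
    "RedundancyReport",
    "SesIndex",
]


def reverse_score(survey: LikertSurvey, items: set[str] | None = None) -> LikertSurvey:
    """Map responses x -> (k+1) - x on the given items (default: the survey's
    reverse-keyed set) so that higher scores consistently mean more severity."""
    items = set(survey.reverse_keyed if items is None else items)
    unknown = items - set(survey.items)
    if unknown:
        raise ValueError(f"unknown items: {sorted(unknown)}")
    out = survey.responses.copy()
    for item in items:
        out[item] = (survey.n_levels + 1) - out[item]
    return LikertSurvey(out, survey.reverse_keyed, dict(survey.scale_map), survey.n_levels)


def dichotomize(survey: LikertSurvey | pd.DataFrame) -> pd.DataFrame:
    """Recode 5-point responses to symptom absent (1-2 -> 0) / present (3-5 -> 1).

    Missing responses stay missing.  Expects already reverse-scored input.
    """
    df = survey.responses if isinstance(survey, LikertSurvey) else survey
    vals = df.to_numpy(dtype="float64", na_value=np.nan)
    bad = (~np.isnan(vals)) & ((vals < 1) | (vals > 5))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"response out of range 1..5 at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    out = pd.DataFrame(
        np.where(np.isnan(vals), np.nan, (vals >= 3).astype(float)),
        index=df.index,
        columns=df.columns,
    )
    return out.astype("Int64")


def filter_missing(
    data: pd.DataFrame,
    scale_columns: list[str],
    required_scale: list[str] | None = None,
    item_missing_threshold: float = 0.30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants with an entirely-missing required scale or with more
    than ``item_missing_threshold`` of the scale items missing.

    Returns (retained rows, exclusion log with one reason per dropped row).
    """
    scale_columns = list(scale_columns)
    if not scale_columns:
        raise ValueError("scale_columns must not be empty")
    if not 0 < item_missing_threshold <= 1:
        raise ValueError("item_missing_threshold must be in (0, 1]")
    required_scale = list(required_scale) if required_scale is not None else scale_columns
    miss = data[scale_columns].isna()
    frac = miss.mean(axis=1)
    all_required_missing = data[required_scale].isna().all(axis=1)
    reasons = []
    for idx in data.index:
        if all_required_missing.loc[idx]:
            reasons.append((idx, "missing required scale"))
        elif frac.loc[idx] > item_missing_threshold:
            reasons.append(
                (idx, f"missing fraction {frac.loc[idx]:.3f} > {item_missing_threshold}")
            )
    log = pd.DataFrame(reasons, columns=["participant", "reason"])
    keep = ~data.index.isin(log["participant"])
    return data.loc[keep], log


@dataclass
class RedundancyReport:
    """Output of the topological-overlap screen for collinear items.

    ``pairs`` has one row per screened item pair with the proportion of
    bystander items showing significantly different correlations; pairs with
    a high zero-order correlation and a low proportion are flagged redundant.
    """

    pairs: pd.DataFrame
    suggested_removals: list[str]
    p_threshold: float
    proportion_threshold: float
    cor_min: float


def _hittner_test(r12: float, r13: float, r23: float, n: int) -> float:
    """Two-sided p for H0: rho12 == rho13 (dependent overlapping correlations),
    using the back-transformed-average-z covariance term."""
    clip = 0.999999
    r12, r13, r23 = (float(np.clip(r, -clip, clip)) for r in (r12, r13, r23))
    if r12 == r13:
        return 1.0
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = np.tanh((z12 + z13) / 2.0)
    rb2 = rbar**2
    c = (r23 * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r23**2)) / (1 - rb2) ** 2
    if c >= 1.0:  # degenerate overlap (a correlation at +-1): difference untestable
        return 1.0
    z = (z12 - z13) * np.sqrt((n - 3) / (2 - 2 * c))
    return float(2 * stats.norm.sf(abs(z)))


def detect_redundant_items(
    data: pd.DataFrame,
    p_threshold: float = 0.01,
    proportion_threshold: float = 0.25,
    method: str = "spearman",
    cor_min: float = 0.50,
) -> RedundancyReport:
    """Screen item pairs for topological overlap (collinear items).

    For each candidate pair (A, B) with |r(A,B)| >= ``cor_min``, the
    correlations r(A,Z) and r(B,Z) are compared over every other item Z with
    the dependent-overlapping-correlation test; if fewer than
    ``proportion_threshold`` of the comparisons are significant at
    ``p_threshold`` the two items carry near-identical information and the
    pair is flagged.  For each flagged pair the member with the smaller mean
    absolute correlation to the remaining items is suggested for removal.
    """
    cols = list(data.columns)
    if len(cols) < 4:
        raise ValueError("need at least 4 items")
    n = len(data)
    if n < 30:
        raise ValueError("need at least 30 rows")
    sd = data.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    R = data.corr(method=method).to_numpy()
    p = len(cols)
    rows = []
    removals: list[str] = []
    mean_abs_r = (np.abs(R).sum(axis=1) - 1.0) / (p - 1)
    for i in range(p):
        for j in range(i + 1, p):
            rij = R[i, j]
            others = [k for k in range(p) if k not in (i, j)]
            pvals = [_hittner_test(R[i, k], R[j, k], rij, n) for k in others]
            prop = float(np.mean([pv < p_threshold for pv in pvals]))
            flagged = bool(abs(rij) >= cor_min and prop < proportion_threshold)
            rows.append((cols[i], cols[j], float(rij), prop, flagged))
            if flagged:
                drop = cols[i] if mean_abs_r[i] <= mean_abs_r[j] else cols[j]
                if drop not in removals:
                    removals.append(drop)
    pairs = pd.DataFrame(
        rows, columns=["item_a", "item_b", "pair_correlation", "prop_significant", "flagged"]
    )
    return RedundancyReport(pairs, removals, p_threshold, proportion_threshold, cor_min)


@dataclass
class SesIndex:
    """First-principal-component composite of z-scored SES indicators."""

    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    partial: pd.Series  # True where the score used only a subset of indicators

    def __post_init__(self) -> None:
        if not 0 <= self.variance_explained <= 1:
            raise ValueError("variance_explained must be in [0, 1]")


def compute_ses_index(
    indicators: pd.DataFrame, education_col: str | None = None
) -> SesIndex:
    """Socioeconomic composite: z-score each indicator over complete cases,
    take the first principal component, fix the sign so the education loading
    is positive.

    Rows with some (not all) indicators missing get a score by projecting
    their available z-scores onto the complete-case loadings; such rows are
    flagged in ``partial``.
    """
    if indicators.shape[1] < 2:
        raise ValueError("need at least 2 indicator columns")
    education_col = education_col or indicators.columns[0]
    complete = indicators.dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 complete cases")
    mu = complete.mean()
    sd = complete.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        raise ValueError(f"indicator(s) with zero variance: {zero_var}")
    zc = ((complete - mu) / sd).to_numpy()
    _, svals, vt = np.linalg.svd(zc, full_matrices=False)
    loadings = vt[0]
    if loadings[indicators.columns.get_loc(education_col)] < 0:
        loadings = -loadings
    var_explained = float(svals[0] ** 2 / (svals**2).sum())
    z_all = (indicators - mu) / sd
    avail = z_all.notna().to_numpy()
    zmat = z_all.fillna(0.0).to_numpy()
    scores = zmat @ loadings
    scores[~avail.any(axis=1)] = np.nan
    partial = pd.Series(avail.any(axis=1) & ~avail.all(axis=1), index=indicators.index)
    return SesIndex(
        pd.Series(scores, index=indicators.index, name="ses"),
        pd.Series(loadings, index=indicators.columns),
        var_explained,
        partial,
    )


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return enc.astype(float)


def residualize(data: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each column by its residual from an OLS fit on an intercept
    plus all covariates (categoricals one-hot encoded with a reference level)."""
    if not data.index.equals(covariates.index):
        raise ValueError("data and covariates must share the same index")
    enc = _encode_covariates(covariates)
    X = np.column_stack([np.ones(len(enc)), enc.to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        dep = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        names = ["(intercept)"] + list(enc.columns)
        bad = [names[k] for k in np.flatnonzero(dep)]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    Y = data.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=data.index, columns=data.columns)
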