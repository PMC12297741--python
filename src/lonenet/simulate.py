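"""Synthetic data generation from known ground-truth network models.

The survey data analysed in applied symptom-network studies is rarely
deposited, so every pipeline stage here is exercised on data drawn from
known parameters: binary symptom matrices from an Ising model (Gibbs
sampling, with an exact 2^p enumeration oracle for small networks),
continuous scores from a Gaussian graphical model, moderator-dependent
continuous data for the moderated network model, and 5-point Likert
surveys whose preprocessing provably inverts back to the latent binary
states.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import GroundTruthGGM, IsingParameters, LikertSurvey, ModeratedTruth

__all__ = [
    "sample_ising",
    "enumerate_ising_moments",
    "sample_ggm_data",
    "sample_moderated_data",
    "sample_likert_cls",
    "generate_study",
    "write_edge_list",
    "write_thresholds",
]

MAX_ENUMERATION_NODES = 20


def as_rng(seed: int | np.random.SeedSequence | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_ising(
    params: IsingParameters,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    burn_in: int = 200,
) -> pd.DataFrame:
    """Draw ``n`` independent binary configurations from an Ising model.

    One Gibbs chain per simulated participant, started from an independent
    random state and run for ``burn_in`` full sweeps; the final state is the
    retained draw, so rows are independent by construction.  All chains share
    a common random node-update order within each sweep (a convenience that
    does not affect the stationary distribution) but use independent uniforms.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if burn_in < 1:
        raise ValueError("burn_in must be >= 1")
    rng = as_rng(seed)
    p = params.n_nodes
    tau, omega = params.tau, params.omega
    states = rng.integers(0, 2, size=(n, p)).astype(float)
    for _ in range(burn_in):
        order = rng.permutation(p)
        for j in order:
            field = tau[j] + states @ omega[:, j]
            states[:, j] = (rng.random(n) < expit(field)).astype(float)
    return pd.DataFrame(states.astype(np.int64), columns=params.labels)


def _all_states(p: int) -> np.ndarray:
    """All 2^p binary configurations as a (2^p, p) array."""
    idx = np.arange(2**p, dtype=np.int64)
    return ((idx[:, None] >> np.arange(p)) & 1).astype(float)


def enumerate_ising_moments(params: IsingParameters) -> dict:
    """Exact moments of an Ising model by summing over all 2^p states.

    Returns node activation probabilities, pairwise co-activation
    probabilities and the expected sum score; the independent oracle used to
    validate the Gibbs sampler and the in-silico intervention simulations.
    """
    p = params.n_nodes
    if p > MAX_ENUMERATION_NODES:
        raise ValueError(
            f"exact enumeration limited to {MAX_ENUMERATION_NODES} nodes (got {p})"
        )
    states = _all_states(p)
    energy = states @ params.tau + 0.5 * np.einsum("si,ij,sj->s", states, params.omega, states)
    energy -= energy.max()  # overflow guard; cancels in the normalisation
    w = np.exp(energy)
    w /= w.sum()
    node_means = w @ states
    pair_means = states.T @ (states * w[:, None])
    return {
        "node_means": node_means,
        "pair_means": pair_means,
        "expected_sum": float(node_means.sum()),
    }


def sample_ggm_data(
    truth: GroundTruthGGM,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw ``n`` rows from the zero-mean Gaussian with covariance K^-1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    x = rng.multivariate_normal(
        np.zeros(len(truth.labels)), truth.covariance, size=n, method="cholesky"
    )
    return pd.DataFrame(x, columns=truth.labels)


def sample_moderated_data(
    truth: ModeratedTruth,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw rows whose pairwise structure depends on a per-row moderator.

    For each participant a moderator value s is drawn (normal, optionally
    truncated), then the variables are drawn from the Gaussian with precision
    ``K(s) = I - (w0 + m s)``.  Returns (variables, moderator).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    p = len(truth.labels)
    s = truth.moderator_mean + truth.moderator_sd * rng.standard_normal(n)
    if truth.moderator_truncation is not None and truth.moderator_sd > 0:
        lim = truth.moderator_truncation
        out = np.abs((s - truth.moderator_mean) / truth.moderator_sd) > lim
        while out.any():  # redraw tail values so the marginal is truncated-normal
            s[out] = truth.moderator_mean + truth.moderator_sd * rng.standard_normal(out.sum())
            out = np.abs((s - truth.moderator_mean) / truth.moderator_sd) > lim
    Ks = (
        np.eye(p)[None, :, :]
        - truth.base_weights[None, :, :]
        - truth.moderation_weights[None, :, :] * s[:, None, None]
    )
    try:
        L = np.linalg.cholesky(Ks)
    except np.linalg.LinAlgError:
        eigmin = np.linalg.eigvalsh(Ks)[:, 0]
        bad = s[eigmin <= 0]
        raise ValueError(
            f"conditional structure not positive definite at moderator value "
            f"s={bad[0]:.4f} (and {bad.size - 1} further draws)"
        ) from None
    z = rng.standard_normal((n, p))
    # if K = L L', then x = L'^{-1} z has covariance K^{-1}
    x = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
    return pd.DataFrame(x, columns=truth.labels), pd.Series(s, name="moderator")


def sample_likert_cls(
    ising_truth: IsingParameters,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    reverse_keyed: set[str] | None = None,
    burn_in: int = 200,
    absent_weights: tuple[float, float] = (0.5, 0.5),
    present_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    return_latent: bool = False,
) -> LikertSurvey | tuple[LikertSurvey, pd.DataFrame]:
    """Emit a 5-point Likert survey from latent binary symptom states.

    Latent absence (0) maps to a response in {1, 2} and presence (1) to
    {3, 4, 5}, with configurable within-class severity weights; responses on
    reverse-keyed items are then flipped (x -> 6 - x) so the survey looks like
    raw positively-worded data.  Applying ``preprocess.reverse_score`` followed
    by ``preprocess.dichotomize`` recovers the latent states exactly.
    """
    rng = as_rng(seed)
    reverse_keyed = set(reverse_keyed or ())
    unknown = reverse_keyed - set(ising_truth.labels)
    if unknown:
        raise ValueError(f"reverse_keyed items not in the model: {sorted(unknown)}")
    labels = ising_truth.labels
    if n == 0:
        empty = pd.DataFrame({lab: pd.array([], dtype="Int64") for lab in labels})
        survey = LikertSurvey(empty, reverse_keyed, {lab: "CLS" for lab in labels})
        return (survey, empty.copy()) if return_latent else survey

    latent = sample_ising(ising_truth, n, rng, burn_in=burn_in)
    lat = latent.to_numpy()
    absent = np.asarray(absent_weights, float)
    present = np.asarray(present_weights, float)
    low = rng.choice([1, 2], size=lat.shape, p=absent / absent.sum())
    high = rng.choice([3, 4, 5], size=lat.shape, p=present / present.sum())
    resp = np.where(lat == 1, high, low)
    df = pd.DataFrame(resp, columns=labels)
    for item in reverse_keyed:  # un-reverse so that reverse-scoring restores severity order
        df[item] = 6 - df[item]
    survey = LikertSurvey(df, reverse_keyed, {lab: "CLS" for lab in labels})
    return (survey, latent) if return_latent else survey


def write_edge_list(labels: list[str], weights: np.ndarray, path) -> None:
    """Write a symmetric weight matrix as a long-format (node_i, node_j, weight) CSV."""
    rows = []
    p = len(labels)
    for i in range(p):
        for j in range(i + 1, p):
            rows.append((labels[i], labels[j], repr(float(weights[i, j]))))
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(path, index=False)


def write_thresholds(labels: list[str], tau: np.ndarray, path) -> None:
    rows = [(lab, repr(float(t))) for lab, t in zip(labels, tau)]
    pd.DataFrame(rows, columns=["node", "threshold"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Full synthetic study
# ---------------------------------------------------------------------------

CLS_ITEMS = [
    "CLS01", "CLS03", "CLS04", "CLS06", "CLS08", "CLS09", "CLS10", "CLS12",
    "CLS14", "CLS16", "CLS17", "CLS18", "CLS20", "CLS21", "CLS22", "CLS24",
]
CLS_REVERSE_KEYED = {"CLS01", "CLS04", "CLS08", "CLS10", "CLS16", "CLS22"}
CLS_REDUNDANT_PAIR = ("CLS20", "CLS21")  # CLS20 is emitted as a noisy copy of CLS21

FACETS = {
    "LON": ["LON"],
    "DEP": ["DEP_lowpos", "DEP_negaff"],
    "ANX": ["ANX_somatic", "ANX_general", "ANX_separation", "ANX_social", "ANX_school"],
    "ADHD": ["ADHD"],
    "PSS": ["PSS_family", "PSS_friends", "PSS_other"],
    "HOPE": ["HOPE_agency", "HOPE_pathways"],
}
SES_INDICATORS = ["father_edu", "mother_edu", "father_occ", "mother_occ", "income"]


def heterogeneous_ggm_truth(labels: list[str] | None = None) -> GroundTruthGGM:
    """A 10-variable sparse GGM truth with clearly distinct node strengths.

    Useful wherever centrality orderings must be estimable from data (e.g.
    stability benchmarks): a chain with varying edge weights plus three
    shortcut edges, so no two nodes have near-tied strength.
    """
    p = 10
    W = np.zeros((p, p))
    chain = [0.10, 0.45, 0.15, 0.40, 0.20, 0.35, 0.12, 0.30, 0.25]
    for i, w in enumerate(chain):
        W[i, i + 1] = W[i + 1, i] = w
    for i, j, w in ((0, 5, 0.30), (2, 7, 0.22), (1, 8, 0.18)):
        W[i, j] = W[j, i] = w
    labels = labels or [f"F{i + 1}" for i in range(p)]
    return GroundTruthGGM(labels, np.eye(p) - W)


def default_cls_truth(seed: int = 7) -> IsingParameters:
    """A plausibly dense all-positive 15-symptom Ising truth for the loneliness scale.

    The 15 core symptoms exclude the planted redundant item; edge weights and
    thresholds are drawn once from ranges typical of fitted symptom networks
    (positive co-occurrence, symptoms inactive more often than active).
    """
    rng = np.random.default_rng(seed)
    labels = [it for it in CLS_ITEMS if it != CLS_REDUNDANT_PAIR[0]]
    p = len(labels)
    omega = np.zeros((p, p))
    # ring backbone keeps the network connected, extra random edges add density
    for i in range(p):
        j = (i + 1) % p
        omega[i, j] = omega[j, i] = rng.uniform(0.4, 0.9)
    n_extra = int(round(0.15 * p * (p - 1) / 2))
    pairs = [(i, j) for i in range(p) for j in range(i + 2, p) if not (i == 0 and j == p - 1)]
    for k in rng.choice(len(pairs), size=n_extra, replace=False):
        i, j = pairs[k]
        omega[i, j] = omega[j, i] = rng.uniform(0.2, 0.6)
    tau = rng.uniform(-2.2, -0.8, size=p)
    return IsingParameters(labels, tau, omega)


def default_facet_truth() -> ModeratedTruth:
    """Facet-level moderated GGM truth for six psychological domains.

    Within-domain facets are positively tied; loneliness connects positively
    to depression/anxiety/ADHD facets and negatively to support and hope.
    SES moderation acts on the loneliness-depression pairs (buffering,
    negative moderation weight) and the loneliness-hope pairs (weakly
    positive, the negative association softening as SES rises).
    """
    labels = [f for facets in FACETS.values() for f in facets]
    idx = {lab: i for i, lab in enumerate(labels)}
    p = len(labels)
    w0 = np.zeros((p, p))
    m = np.zeros((p, p))

    def set_w(a: str, b: str, v: float, mv: float = 0.0) -> None:
        w0[idx[a], idx[b]] = w0[idx[b], idx[a]] = v
        if mv:
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = mv

    for facets in FACETS.values():  # within-domain cohesion
        for i, a in enumerate(facets):
            for b in facets[i + 1 :]:
                set_w(a, b, 0.18)
    set_w("LON", "DEP_lowpos", 0.31, -0.04)
    set_w("LON", "DEP_negaff", 0.20, -0.04)
    set_w("LON", "ANX_social", 0.15)
    set_w("LON", "ANX_separation", 0.10)
    set_w("LON", "ADHD", 0.08)
    set_w("LON", "PSS_friends", -0.20)
    set_w("LON", "PSS_family", -0.10)
    set_w("LON", "HOPE_agency", -0.23, 0.02)
    set_w("LON", "HOPE_pathways", -0.12, 0.02)
    set_w("DEP_negaff", "ANX_general", 0.20)
    set_w("DEP_lowpos", "HOPE_agency", -0.15)
    set_w("ADHD", "ANX_general", 0.12)
    set_w("ADHD", "HOPE_pathways", -0.08, 0.02)
    set_w("PSS_family", "HOPE_agency", 0.12)
    truth = ModeratedTruth(labels, w0, m)
    for s in (-3.0, 0.0, 3.0):  # guard: conditional model must be PD over the sampled range
        if np.linalg.eigvalsh(truth.conditional_precision(s))[0] <= 1e-8:
            raise ValueError(f"facet truth not positive definite at moderator s={s}")
    return truth


def generate_study(
    n: int = 2593,
    seed: int | np.random.SeedSequence | None = 0,
    missing_rate: float = 0.02,
    n_heavy_missing: int = 10,
    cls_truth: IsingParameters | None = None,
    facet_truth: ModeratedTruth | None = None,
) -> dict:
    """Generate a complete synthetic survey study for the full pipeline.

    Emulates the structure (not the distributions) of a school-age loneliness
    survey: a 16-item 5-point loneliness scale with 6 reverse-keyed items and
    one planted redundant item, facet scores for six psychological domains
    whose pairwise structure is moderated by latent SES, five ordinal SES
    indicators loading on that latent SES, independent demographic covariates,
    and a sprinkle of missing responses including rows that violate the
    30%-missing exclusion rule.

    Returns a dict with the observed tables, the codebook, and every piece of
    ground truth.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cls, s_dup, s_facet, s_ses, s_cov, s_miss = ss.spawn(6)
    cls_truth = cls_truth or default_cls_truth()
    facet_truth = facet_truth or default_facet_truth()

    survey, latent = sample_likert_cls(
        cls_truth, n, s_cls, reverse_keyed=CLS_REVERSE_KEYED & set(cls_truth.labels),
        return_latent=True,
    )
    # planted redundant item: a noisy copy of its partner's latent state,
    # emitted on the same Likert scale
    rng_dup = as_rng(s_dup)
    dup, src = CLS_REDUNDANT_PAIR
    lat_src = latent[src].to_numpy()
    lat_dup = np.where(rng_dup.random(n) < 0.05, 1 - lat_src, lat_src)
    low = rng_dup.choice([1, 2], size=n)
    high = rng_dup.choice([3, 4, 5], size=n)
    responses = survey.responses.copy()
    responses[dup] = np.where(lat_dup == 1, high, low)
    responses = responses[CLS_ITEMS].astype("Int64")

    facet_data, moderator = sample_moderated_data(facet_truth, n, s_facet)

    rng_ses = as_rng(s_ses)
    s = moderator.to_numpy()
    indicators = {}
    for name in SES_INDICATORS:
        raw = 0.7 * s + np.sqrt(1 - 0.7**2) * rng_ses.standard_normal(n)
        indicators[name] = np.clip(np.round(raw * 0.9 + 3), 1, 5).astype(int)
    ses = pd.DataFrame(indicators)

    rng_cov = as_rng(s_cov)
    covariates = pd.DataFrame(
        {
            "sex": rng_cov.choice(["boy", "girl"], size=n),
            "grade": rng_cov.choice([3, 4, 5, 6], size=n),
            "residence": rng_cov.choice(["urban", "rural"], size=n, p=[0.6, 0.4]),
            "only_child": rng_cov.choice([0, 1], size=n, p=[0.55, 0.45]),
        }
    )

    rng_miss = as_rng(s_miss)
    if missing_rate > 0:
        mask = rng_miss.random(responses.shape) < missing_rate
        responses = responses.mask(pd.DataFrame(mask, columns=responses.columns))
    if n_heavy_missing > 0 and n > n_heavy_missing:
        heavy = rng_miss.choice(n, size=n_heavy_missing, replace=False)
        for r in heavy[: n_heavy_missing // 2]:  # rows losing the whole scale
            responses.iloc[r, :] = pd.NA
        for r in heavy[n_heavy_missing // 2 :]:  # rows over the 30% threshold
            k = int(np.ceil(0.3 * len(CLS_ITEMS))) + 1
            cols = rng_miss.choice(len(CLS_ITEMS), size=k, replace=False)
            responses.iloc[r, cols] = pd.NA

    codebook = pd.DataFrame(
        {
            "item_id": CLS_ITEMS,
            "scale": "CLS",
            "reverse_keyed": ["yes" if it in CLS_REVERSE_KEYED else "no" for it in CLS_ITEMS],
        }
    )
    participant_id = pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")
    for tbl in (responses, facet_data, ses, covariates):
        tbl.index = participant_id
    moderator.index = participant_id

    return {
        "cls_responses": responses,
        "codebook": codebook,
        "facet_scores": facet_data,
        "ses_indicators": ses,
        "covariates": covariates,
        "latent_symptoms": latent.set_index(participant_id),
        "latent_ses": moderator,
        "cls_truth": cls_truth,
        "facet_truth": facet_truth,
        "facet_domains": {f: d for d, fs in FACETS.items() for f in fs},
    }
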