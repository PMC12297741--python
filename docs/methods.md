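# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a user should know before trusting a number.

## Ising network estimation (`lonenet.ising`)

The joint model over binary symptoms is the pairwise Markov random field
`P(x) ∝ exp(Σ τ_i x_i + Σ_{i<j} ω_ij x_i x_j)`.  Its conditionals are
logistic regressions, so each node is fit by ℓ1-penalized logistic
regression on all other nodes along a path of 100 log-spaced penalties from
the nodewise `λ_max` (the smallest penalty giving the empty model,
`max_j |x_jᵀ(y − ȳ)|/n`) down to `0.01·λ_max`.  Per node, the penalty
minimizing `EBIC_γ = −2ℓ + k ln n + 2γ k ln(p−1)` is selected, with
γ = 0.25 — the standard convention for this estimator, exposed in
`IsingFitConfig` because applied papers rarely print it.  Edges are
symmetrized by the AND rule (an edge requires both cross-coefficients
nonzero; its weight is their mean); the OR rule is available.

Two numerical conventions matter.  First, the inner solver is liblinear
(scikit-learn); it technically penalizes the intercept, so the constant
column is scaled by 100, making the intercept's share of the penalty
negligible — thresholds must not be shrunk because they are the handles the
intervention simulation perturbs.  Second, liblinear's coordinate descent
depends on column order at ~1e-5; permutation equivariance therefore holds
to solver tolerance, and the selected edge *sets* are permutation-exact in
practice.  `random_state` is pinned so refits are bitwise reproducible.

A degenerate single-column input is fit as the intercept-only model
(τ = logit of the activation rate).

## In-silico interventions (`lonenet.nira`)

For each symptom, the fitted thresholds are copied and the target's τ is
shifted by −δ (alleviating) or +δ (aggravating); `n_sim` participants are
simulated per condition (default 1000) and per-participant sum scores
recorded.  δ defaults to the sample SD of the fitted thresholds — the
convention of the node-identification simulation literature — with a
fixed-δ override; the resolved value is logged prominently because results
scale with it.  Welch two-sample *t* statistics are oriented
`mean(baseline) − mean(perturbed)`, so a working alleviation is positive
and a working aggravation negative; the 95% interval shown for each
condition is the normal-theory interval of the perturbed mean (sample
quantiles were considered and rejected for comparability across nodes at
small `n_sim`).  Target ranking sorts by the change in mean sum score with
ties broken by node label.  The participant-resampling bootstrap (default
5000 iterations of 70% resampled with replacement from every condition)
reports per-node effect means and SDs; the baseline resample is shared
across nodes within an iteration.

Gibbs sampling uses one independently initialized chain per simulated
participant with 200 burn-in sweeps, so draws are independent across
participants by construction; all chains follow a common random update
order per sweep (irrelevant to the stationary distribution, but it lets the
sweep vectorize across participants).  For p ≤ 20,
`enumerate_ising_moments` provides exact moments by summation over all 2^p
states; the test suite holds simulated condition means to within 3
Monte-Carlo SEs of these oracles.

## Gaussian graphical models (`lonenet.ggm`)

`fit_ebicglasso` computes the (Pearson by default, Spearman optional)
correlation matrix on complete rows, repairs indefiniteness by eigenvalue
clipping at 1e-8 (always logged), and runs the graphical lasso over 100
penalties from `max |r_ij|` down to 1% of it.  Selection minimizes
`−n(log det K − tr(SK)) + E ln n + 4γE ln p` with E the number of selected
edges and γ = 0.5.  Pearson-on-residuals is the default input because the
covariate-residualized scores the pipeline feeds it are continuous; raw
ordinal scores can use the Spearman option.  `pcor_network` exposes the
unregularized inverse-correlation network — useful as a fast estimator in
resampling loops.  `extract_flow` tiers variables around a focal node:
direct neighbours (tier 1), nodes reachable only through them (tier 2), and
unreachable nodes.

## Centrality, communities, bridges (`lonenet.metrics`)

Strength is `Σ|w|`, expected influence `Σw`; they are identical exactly
when no edge is negative, and the test suite asserts that identity rather
than assuming it.  Closeness and betweenness use the inverse absolute
weight `1/|w|` as edge length — the convention of the common plotting/
centrality tooling — so centrality values are only comparable across
software using the same convention.  Closeness on a disconnected graph is
computed within the node's component; betweenness gives fractional credit
across tied shortest paths.

Community detection minimizes a signed spin-glass Hamiltonian: positive
and negative layers each carry a configuration-model null term with
resolution γ (= 1), positive edges rewarding co-assignment and negative
edges rewarding separation.  The optimizer is single-site simulated
annealing (T₀ = 1, geometric cooling 0.99, 10⁴ steps, best of 10 random
restarts) followed by a greedy single-move polish; on every enumerable
test graph (p ≤ 8, all set partitions checked) it attains the global
optimum.  Assignments are deterministic given a seed.

Bridge strength / bridge EI restrict the strength / EI sums to edges whose
endpoint lies outside the node's community; the 2-step variant adds
`Σ w_ik w_kj` over paths `i→k→j` ending outside the community.  z-scores
use the sample SD over nodes.

## Bootstrap stability (`lonenet.stability`)

`edge_ci_bootstrap` refits on rows resampled with replacement (default
1000) and reports percentile CIs per edge; replicates may fail (up to 10%)
and are counted.  `case_dropping_cs` drops 10–75% of cases (5% steps),
correlates the re-estimated centrality with the full-sample centrality
(Spearman by default), and reports the CS coefficient: the largest drop
fraction at which the correlation reaches 0.7 in ≥ 95% of resamples.  A
centrality vector without variance across nodes (e.g. the all-zero
strengths of an empty network) carries no ordering information and counts
as correlation 0; a *non-degenerate* vector that is identical between full
sample and subsample counts as 1.  Consequence worth knowing: on pure
noise a sparsity-selecting estimator yields empty networks and CS = 0,
while an estimator that always returns the same informative network yields
the maximal CS — both are the intended readings.  Note that stability of a
centrality *ordering* is only meaningful when true strengths differ;
benchmarks use a ground truth with clearly heterogeneous strengths because
a uniform chain has near-tied strengths whose ranks no sample size can pin
down.

## Moderated network model (`lonenet.mnm`)

All variables and the moderator are z-scored; each variable's design holds
the other variables, the moderator, and variable × moderator products, fit
by lasso with per-node EBIC selection (γ = 0.25; 10-fold CV optional), and
the moderator's own regression holds the plain variables.  Pairwise and
three-way coefficients are aggregated by the AND rule with the arithmetic
mean — matching the Ising module so the two halves of the toolkit share
one symmetrization convention.  Reported weights are on the z-scale;
`conditional_edge` evaluates `w0 + m·s`.  With `moderated=False` the fit
reduces to a plain nodewise-lasso GGM (verified against an independent
implementation in the tests).  `resample_mnm` reports the proportion of
row-resamples in which each parameter is nonzero.

## Preprocessing (`lonenet.preprocess`)

Reverse-keyed 5-point items map `x → 6 − x`; dichotomization codes 1–2 as
symptom absent and 3–5 as present, preserving missingness.  Participants
are excluded when the whole required scale is missing or when more than
30% of scale items are missing; every exclusion is logged with a reason.

The redundancy screen compares, for each candidate item pair, their
correlations with every other item using the dependent-overlapping-
correlation test (back-transformed-average-z covariance term); a pair is
flagged when its zero-order correlation is at least 0.5 *and* fewer than
25% of the comparisons differ at p < 0.01.  The 0.5 gate follows the
screening tool this procedure mirrors; without it, independent items (whose
correlation profiles are indistinguishable because both are flat) would be
mass-flagged.  Spearman correlations by default.  Within a flagged pair the
member with the smaller mean absolute correlation to the remaining items is
suggested for removal — a deterministic, defensible default; the full pair
report is always emitted so a human can override.

The SES composite z-scores each indicator over complete cases and takes
the first principal component, sign-fixed so the education loading is
positive.  Rows with partially missing indicators are scored by projecting
their available z-scores onto the complete-case loadings and flagged.
Residualization regresses each score on an intercept plus one-hot-encoded
covariates and returns OLS residuals (zero mean, exactly orthogonal to the
design).

## Synthetic study generator (`lonenet.simulate`)

`generate_study` emulates the *structure* of a school-age loneliness
survey: n = 2593 participants by default; a 16-item 5-point loneliness
scale with the six reverse-keyed items of the instrument it mirrors; a
planted redundant item (a 5% flip-noise copy of a neighbouring symptom) so
the redundancy screen has a true positive; 15 core symptoms driven by a
dense all-positive Ising truth (ring backbone plus 15% extra edges, weights
0.2–0.9, thresholds −2.2 to −0.8 — ranges typical of fitted symptom
networks); 14 facet scores for six domains from a moderated Gaussian truth
whose loneliness–depression edges weaken with SES (moderation −0.04) and
loneliness–hope edges soften (+0.02), the published effect sizes for this
design; five ordinal SES indicators loading 0.7 on a latent SES;
independent demographic covariates; 2% random missingness plus a few rows
engineered to violate the 30% rule.

The Likert emission maps latent absence to a uniform draw on {1,2} and
presence to {3,5} uniformly (configurable severity weights), then flips
reverse-keyed items — so reverse-scoring followed by dichotomization
recovers the latent binary states *exactly*, which the tests assert for
every seed.

The moderator is standard normal truncated at |z| ≤ 3 (configurable,
including off).  Truncation keeps the conditional precision `I − (w0+m·s)`
positive definite under the moderation strengths used in the benchmarks; a
z-scored composite essentially never exceeds ±3 in samples of this size,
so the truncation is statistically invisible but removes a 1-in-10⁴
failure mode.

What the generator does **not** emulate: real item distributions, response
styles, reliability coefficients, demographic structure, or any coupling
between the loneliness scale and the facet scores across instruments.
Passing tests therefore demonstrate that the estimators recover the models
they assume, at realistic sizes — not that those models describe any
particular population.

## Pipeline and determinism (`lonenet.pipeline`, `lonenet.io`)

One configuration object (flat keys, YAML-loadable) drives the run;
every stochastic stage receives a seed derived from the master seed via
`SeedSequence`, the resolved intervention δ is logged, and CSV floats are
written with repr round-trip formatting.  Rerunning an identical
configuration reproduces all artifacts byte-for-byte (asserted in the
tests); `manifest.csv` records a SHA-256 per artifact.  Pipeline-stage
bootstrap defaults (edge-CI 50, case-dropping 20, 30-penalty paths) are
deliberately lighter than the module defaults so a full desk-scale replica
runs in about a minute; production analyses should raise them via the
configuration.

## Known limitations

- The Ising estimator assumes complete rows; the single-imputation option
  is deliberately minimal (item mode) and off by default.
- Intervention projections inherit every Ising assumption (pairwise
  interactions, no latent confounding); they rank plausible targets and are
  not effect-size forecasts for real interventions.
- The annealing optimizer is exact only as verified on enumerable graphs
  (p ≤ 8); larger graphs rely on restarts.
- Closeness/betweenness depend on the 1/|w| distance convention; compare
  across software with care.
- The MNM treats all nodes as Gaussian after residualization; categorical
  moderators and higher-order interactions are out of scope.
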