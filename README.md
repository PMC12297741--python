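# lonenet

Network psychometrics of childhood loneliness: Ising symptom networks with
in-silico interventions, regularized partial-correlation networks with
centrality / bridge / community analysis, and moderated network models —
as a reusable, tested Python toolkit with a fully seeded synthetic-study
generator.

## The problem

Survey studies of children's loneliness increasingly treat symptoms not as
interchangeable indicators of one latent trait but as a *network* of
mutually reinforcing experiences ("I have nobody to talk to", "it's hard to
make friends", ...).  Three questions follow naturally:

1. **Which symptom should an intervention target?**  Fit an Ising model to
   dichotomized symptom data and simulate *in-silico interventions*: shift
   one symptom's threshold down (alleviating) or up (aggravating) and
   project the change in the total symptom score.
2. **How does loneliness sit inside the wider psychological system**
   (depression, anxiety, ADHD symptoms, social support, hope)?  Estimate
   Gaussian graphical models over domain and facet scores, find communities,
   and measure which variables *bridge* them.
3. **Does context (family socioeconomic status) reshape these links?**  Fit
   a moderated network model in which every pairwise association may vary
   linearly with a continuous moderator.

The package implements this full workflow for item-level survey data, plus a
synthetic-data generator that emulates the *structure* of such a study (a
16-item 5-point loneliness scale with 6 reverse-keyed items, facet scores
for six domains, five ordinal SES indicators, demographic covariates) from
known ground truth, so every method can be validated against exact oracles.

## Models

**Ising network.**  For binary symptoms `x ∈ {0,1}^p`,
`P(x) ∝ exp(Σ_i τ_i x_i + Σ_{i<j} ω_ij x_i x_j)`.  Estimation is nodewise
ℓ1-regularized logistic regression along a 100-point penalty path, per-node
EBIC selection (`EBIC_γ = −2ℓ + k ln n + 2γk ln p`, γ = 0.25), AND-rule
symmetrization with the arithmetic mean (the eLasso procedure).  The
thresholds τ are the handles perturbed by the intervention simulation; a
Gibbs sampler (one independently initialized chain per simulated
participant) projects sum-score distributions, and Welch *t* tests compare
each perturbed condition with baseline — oriented so that effective
alleviation gives *t* > 0 and effective aggravation *t* < 0.  For p ≤ 20 an
exact `2^p` enumeration oracle is available.

**Gaussian graphical model.**  Edges are partial correlations
`ρ_ij = −K_ij/√(K_ii K_jj)` from a graphical-lasso precision matrix, with
the penalty chosen by EBIC (γ = 0.5).  Node metrics: strength `Σ_j |w_ij|`,
expected influence `Σ_j w_ij` (identical when no edge is negative),
closeness and betweenness on distances `1/|w_ij|`.  Communities come from a
signed spin-glass Hamiltonian minimized by simulated annealing; bridge
strength and 1-/2-step bridge expected influence sum (products of) weights
crossing community boundaries.  Stability: nonparametric edge-CI bootstrap
and the case-dropping CS coefficient.

**Moderated network model.**  Each variable is regressed (lasso + EBIC) on
all others, the moderator *s*, and all variable × moderator products; the
AND-rule aggregate gives base weights `w0` and moderation weights `m`, so
the conditional edge at moderator value *s* is `w0 + m·s`.

## Worked example

```python
import numpy as np
from lonenet import (IsingParameters, NiraConfig, centrality, fit_ising,
                     rank_targets, run_nira, sample_ising)

# ground truth: a 6-symptom chain whose hub S3 carries two extra strong edges
p = 6
omega = np.zeros((p, p))
for i in range(p - 1):
    omega[i, i + 1] = omega[i + 1, i] = 0.8
omega[2, 4] = omega[4, 2] = 0.9
omega[2, 5] = omega[5, 2] = 0.9
truth = IsingParameters([f"S{i+1}" for i in range(p)], np.full(p, -1.2), omega)

data = sample_ising(truth, n=3000, seed=42)   # 3000 simulated children
fit = fit_ising(data)                         # nodewise logistic lasso + EBIC
print("edges recovered:", int((fit.weights != 0).sum() // 2), "of 7")
print("strength:", centrality(fit)["strength"].round(2).to_dict())

res = run_nira(fit.params, NiraConfig(scenario="aggravating", delta=1.0, seed=7))
top = rank_targets(res)[0]
row = res.effects.loc[top]
print("top aggravation target:", top)
print(f"effect of aggravating {top}: {row['effect']:+.2f} points "
      f"(t = {row['t']:.1f}, p = {row['p']:.1e})")
```

Output:

```
edges recovered: 7 of 7
strength: {'S1': 0.87, 'S2': 1.73, 'S3': 3.34, 'S4': 1.4, 'S5': 2.14, 'S6': 1.63}
top aggravation target: S3
effect of aggravating S3: +0.51 points (t = -7.5, p = 8.8e-14)
```

The estimator recovers all seven true edges; S3, the node with the highest
strength, is also the symptom whose aggravation raises the projected total
score the most — the "central symptoms are prevention targets" pattern this
methodology is built around.  The negative *t* reflects the baseline-minus-
perturbed orientation: scores rose under aggravation.

## Command line

```bash
lonenet simulate --seed 0 -n 2593 --outdir data/     # synthetic study + truth
lonenet run-all --seed 0 --outdir out/               # full pipeline
lonenet ising --seed 0 --outdir out/                 # one stage (+ prerequisites)
```

`run-all` executes preprocess → Ising → interventions → GGMs → metrics →
stability → MNM, writes long-format edge CSVs, node-metric CSVs, a
seed/decision run log and a `manifest.csv` of content hashes; rerunning an
identical configuration reproduces every artifact byte-for-byte.

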