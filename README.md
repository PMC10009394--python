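# dyndag

Dynamic Bayesian network analysis of longitudinal binary symptom panels:
Bayesian structure learning over two-slice DBNs with partition MCMC, and
posterior distributions of do-calculus intervention effects between
adjacent time points.

## The problem

Symptom-network psychiatry treats disorders as systems of interacting
symptoms. Cross-sectional networks describe association, not direction; a
longitudinal panel — the same participants rated at several waves — lets
time orient the edges. `dyndag` is built for panels like a multi-wave
schizophrenia outpatient cohort: ~1200 participants, 12 binary symptom
indicators (nine PANSS items dichotomized at a rating of 4 or above, three
CDSS items), five waves at uniform spacing, with progressive loss to
follow-up.

## The model

A first-order stationary DBN over `n` binary variables: a within-slice DAG
`W` (identical in every wave) and a between-slice matrix `B` of edges from
wave `t` to wave `t+1` (self-edges encode symptom *momentum*). All adjacent
wave pairs with complete data are stacked into a transition table, one row
per (participant, pair).

- **Scoring** — decomposable BDeu marginal likelihood: per family with `q`
  parent configurations and prior weight `α = ess/(2q)` per cell,
  `Σ_j log B(α+k_j, α+m_j) − log B(α, α)`.
- **Structure posterior** — partition MCMC: a Markov chain over ordered
  layerings of the within-slice nodes, each scored by summing every node's
  layer-consistent parent sets (between-slice parents marginalised in
  closed form), then a concrete `(W, B)` drawn per retained state so that
  better-fitting graphs appear proportionally more often. An exhaustive
  enumeration oracle and a single-edge structure-MCMC baseline validate it.
- **Effects** — for each sampled structure, CPTs drawn from conjugate Beta
  posteriors, then the exact total causal effect
  `P(y_{t+1}=1 | do(x_t=1)) − P(y_{t+1}=1 | do(x_t=0))` for every pair on
  the mutilated unrolled graph. The collated draws give each pair's
  posterior effect distribution, mean, and 95% credible interval.
- **Reporting** — the effect-distribution grid and a consensus DBN graph
  (solid within-slice edges, dashed between-slice edges, double heads where
  the direction is unidentifiable), plus CSV/DOT/GraphML exports.

A synthetic-cohort module generates five-wave panels from known ground-truth
DBNs (additive CPTs with guaranteed parent contrasts, monotone MCAR
attrition), so every stage is testable without access to clinical data.

## Worked example

```python
from dyndag import (generate_true_dbn, simulate_cohort, build_transition_table,
                    build_score_table, sample_dags, edge_posteriors,
                    effect_distribution, build_consensus)

truth = generate_true_dbn(n_vars=12, seed=3)
panel = simulate_cohort(truth, n_participants=1208, n_waves=5, seed=4)
table = build_transition_table(panel)
scores = build_score_table(table, ess=1.0, max_parents=4)
sample = sample_dags(scores, n_samples=1000, chain_length=100_000, seed=5)
dist = effect_distribution(sample, table, seed=6)

df = dist.to_frame()
print(df[df.significant].sort_values("mean", ascending=False).head(6))
```

prints (the largest posterior-mean effects, all momentum terms):

```
source target mean lower upper  significant  n_draws
    P1     P1 0.54  0.52  0.57         True     1000
    P7     P7 0.54  0.51  0.57         True     1000
    P5     P5 0.48  0.45  0.51         True     1000
    P3     P3 0.48  0.45  0.51         True     1000
    P4     P4 0.45  0.42  0.48         True     1000
 CDSS1  CDSS1 0.37  0.34  0.40         True     1000
```

Each row is the posterior summary of the causal effect of the source
symptom at wave `t` on the target at wave `t+1`: e.g. forcing delusions (P1)
present raises the probability of delusions six months later by 0.54 on
average, and the 95% interval [0.52, 0.57] excludes zero, so the pair is
flagged significant. In this simulated cohort all 12 diagonal effects are
significant — every symptom self-predicts — which is exactly the momentum
structure the generator planted (`self_edge_prob = 0.9` plus positive
self-edge coefficients).

The same analysis runs from the shell on a YAML config:

```sh
dyndag all -c config.yaml -o out/       # or: simulate / fit / effects / report
```

writing `transition.csv`, `edges.csv`, `effects.csv`, `consensus.csv`,
`consensus.svg`, `effect_grid.svg` and a `manifest.json` with content hashes;
re-running the same config reproduces all tabular outputs byte-identically.

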