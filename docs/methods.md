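# Methods

## Model

`dyndag` analyses a panel of binary symptom indicators measured on the same
participants over `T` waves with a first-order, stationary **dynamic Bayesian
network**. The model has two parts, shared by every pair of adjacent waves:

- a within-slice DAG `W` over the `n` variables, identical in every slice —
  the contemporaneous dependence structure;
- a between-slice matrix `B` of directed edges from variables at wave `t` to
  variables at wave `t+1`. Time orients these edges, so `B` is unconstrained;
  the diagonal entry `i -> i` encodes a symptom's *momentum* (self-prediction
  over one interval).

Stationarity means the transition kernel and `W` do not change with wave.
Under this assumption every participant-wave-pair with complete data is an
exchangeable observation of the same transition process, so adjacent pairs
are pooled into a single **transition table**: one row per (participant,
pair), `2n` binary columns. Participants complete at several pairs contribute
once per pair; no within-participant correlation correction is applied —
rows are treated as independent draws from the stationary kernel.

### Dichotomization

PANSS items (rated 1–7) are coded present at a rating of 4 or above (clearly
present, at least moderate severity). CDSS items are rated 0–3 and carry no
canonical presence cutpoint; the default is >= 2 ("moderate"), exposed as
configuration. Missing ratings stay missing; a wave contributes only if all
`2n` values of the pair are observed (complete-case per pair, not per
participant).

## Scoring

Each family (node given its parents) is scored with the BDeu marginal
likelihood: binary child, `q = 2^k` parent configurations, per-cell Dirichlet
weight `alpha = ess/(2q)`, giving `sum_j log B(alpha + k_j, alpha + m_j) -
log B(alpha, alpha)`. The structure score sums

- slice-2 families: child at `t+1`, parents = W-parents at `t+1` plus
  B-parents at `t`, over the transition rows;
- slice-1 families (default on, `score_first_slice`): child at `t`, parents =
  W-parents at `t`, so the antecedent wave's data also inform the shared
  within-slice structure;
- the log structure prior — uniform over admissible structures by default,
  optionally a per-edge penalty `gamma^edges`.

Defaults: `ess = 1` (weakly informative BDeu), `max_parents = 4`. Neither is
identified by the data-collection design; both are declared, configurable
choices. The score is decomposable and score-equivalent (Markov-equivalent
within-slice DAGs receive identical likelihood), which the tests check
exhaustively on three nodes.

`build_score_table` precomputes every admissible family score once
(`O(n * C(2n-1, <=max_parents))` families); all downstream sampling is pure
table lookup. Arithmetic is entirely in the log domain via `gammaln`.

## Partition MCMC

The posterior over structures is sampled with a Markov chain over **ordered
partitions** (layerings) of the within-slice nodes. A DAG is *consistent*
with exactly one ordered partition — the layering in which every node's
parents lie in strictly earlier layers, with at least one parent in the
immediately preceding layer — so summing each node's scores over its
layer-consistent parent sets scores the partition without double-counting
any DAG. Between-slice parents are always admissible and are marginalised
in closed form inside each node's sum; after the chain, a concrete `(W, B)`
is drawn conditional on the partition in proportion to its score.

Moves and fixed proposal probabilities: relocate a node (0.5), split a layer
(0.2), merge adjacent layers (0.2), swap nodes between adjacent layers
(0.1). Each move type carries its exact Metropolis–Hastings proposal
correction (relocation counts destination slots on both sides; split/merge
use the `2^s - 2` ordered bipartitions of a layer of size `s`). Defaults:
chain length 10^6 proposals, 20% burn-in, thinning to 10 000 draws; the seed
is mandatory and the draw is bit-reproducible. A classic single-edge
toggle/reversal **structure MCMC** over concrete `(W, B)` is retained as an
independent cross-check, and `exhaustive_posterior` enumerates small
problems exactly; the test suite verifies all three agree.

Known limitation: on larger problems with short chains a single run can
freeze on one orientation of a Markov-equivalent within-slice pair (the
posterior mass that should split ~50/50 across orientations lands on one).
Between-slice posteriors are unaffected. Long chains, the structure-MCMC
cross-check and two-seed comparisons expose this when it matters.

## Intervention effects

For each sampled structure the two-slice network is unrolled to a `2n`-node
DAG and parameters are drawn from their conjugate posteriors — each CPT cell
`Beta(alpha + ones, alpha + zeros)` — one parameter draw per structure draw,
propagating parameter as well as structure uncertainty. The total causal
effect of slice-1 `s` on slice-2 `y` is

    P(y = 1 | do(s = 1)) - P(y = 1 | do(s = 0)),

computed *exactly* on the mutilated graph (incoming edges of `s` removed,
`s` clamped): summation restricted to the ancestral set of the target, with
a variable-elimination path beyond 20 ancestral variables, and a vectorized
all-pairs routine that enumerates the `2^n` slice-1 configurations once per
draw. No Monte-Carlo inference is used anywhere; effects are identically
zero when the target is not a descendant of the clamped source. The
assumptions are the usual ones: the DAG is causal and there are no
unmeasured confounders.

Collating one effect per (draw, source, target) gives the posterior effect
distribution for the full cross-slice grid, including the diagonal
(momentum). Summaries are the posterior mean and an equal-tailed 95%
credible interval from empirical quantiles; a pair is *significant* when the
interval excludes zero. Mixtures of structures that disagree about a
mediating slice-2 edge produce visibly bimodal effect distributions, with
modes at the per-structure exact effects.

## Synthetic cohorts

The generator emulates the shape of a large naturalistic outpatient cohort:
12 binary indicators, ~1208 participants, 5 waves, monotone MCAR dropout at
the interview level with default per-wave retention 0.905 (so ~810 of 1208
remain at wave 5). Wave 1 is drawn from the within-slice model with its own
CPT set (the stationarity idealisation applied to the initial state); later
waves follow the stationary transition CPTs.

CPTs are additive: `P(child=1 | pa) = base + sum_j c_j pa_j`, entries kept
inside [0.02, 0.98], so each parent's contrast equals `|c_j|` in every
configuration. Every coefficient magnitude is at least `effect_floor`
(default 0.3 — planted effects detectable at ~10^3 transition rows);
self-edge coefficients are always positive, other signs random. Since a
family of `k` parents needs `k * effect_floor` of probability range, the
generator budgets off-diagonal between-slice parents so the total
transition in-degree stays within `floor(0.96/effect_floor)`; within-slice
edges are sampled i.i.d. at `within_density` per orderable pair (binomial
edge count), and self-edges are exempt from the budget, so the floor can be
missed only in the rare case where the within-slice in-degree alone
exhausts the range. Default densities (`within_density = 0.15`,
`between_density = 0.05`, `self_edge_prob = 0.9`) produce graphs of roughly
the sparsity a 12-symptom network analysis reports: mostly momentum edges
plus a handful of cross-symptom links.

What the generator does **not** emulate: ordinal rating scales (it emits
binary data directly; dichotomization is exercised on constructed ordinal
fixtures), informative dropout, item-level missingness (off by default),
non-stationary kernels, and within-participant heterogeneity. Passing
recovery tests therefore show the estimator works when its assumptions
hold; they say nothing about robustness to violations of stationarity or
MCAR.

## Numerical choices

- Log-domain scoring throughout; score tables reproduce bit-for-bit for
  identical inputs.
- Beta parameter draws are clipped to [1e-12, 1 - 1e-12]: with per-cell
  prior weights as small as `ess/32`, Beta samples can underflow to exactly
  0/1, which the exact-inference divisions cannot tolerate.
- Ties in categorical sampling are resolved by the seeded generator stream,
  never by index order.
- Credible intervals are equal-tailed empirical quantiles (linear
  interpolation); highest-density intervals are out of scope.
- Degenerate inputs: empty data scores 0; an all-missing panel raises an
  error carrying per-pair completeness counts; zero-size effect samples are
  rejected.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each property is sharp: exact-oracle
agreement at 3 variables / 500 rows / 3x10^4 proposals; recovery of a
12-variable DBN at 1000 rows / 10^5 proposals / 1000 draws; effect recovery
and calibration at 6 variables / 500–1000 rows; brute-force effect
validation on 1000 random networks of up to 5 variables per slice (10
unrolled nodes). The library defaults remain at the full analysis scale
(10^6 proposals, 10 000 draws).
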