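"""Posterior sampling of two-slice DBN structures.

The target distribution is ``P(W, B | data) proportional to exp(score)``
with the decomposable BDe score of :mod:`dyndag.scoring` and a prior
uniform over admissible structures (optionally with a per-edge penalty,
both folded into the score table).

Two samplers are provided:

* **partition MCMC** (the default): a Markov chain over *ordered
  partitions* (layerings) of the within-slice nodes.  A within-slice DAG
  is consistent with exactly one ordered partition — the layering in
  which every node's parents sit in strictly earlier layers with at
  least one parent in the immediately preceding layer — so scoring a
  partition by summing the (B-marginalised) scores of all consistent
  parent sets per node, moving through partition space with
  Metropolis-Hastings, and then drawing a concrete DAG conditional on
  the partition yields draws proportional to their posterior score.
  Between-slice parents are always admissible (time orients them), so
  they are marginalised inside each node's layer-consistent sum and
  sampled last.

* **structure MCMC**: classic single-edge toggle/reversal moves on the
  concrete ``(W, B)`` pair, retained as an independent cross-check.

:func:`exhaustive_posterior` enumerates every admissible structure on
small problems and is the exact oracle against which both samplers are
validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from math import prod

import numpy as np
from scipy.special import logsumexp

from .panel_io import ConfigurationError
from .scoring import BudgetError, ScoreTable
from .structures import DbnStructure, topological_order

#: Proposal mix over partition moves: relocate a node, split a layer,
#: merge adjacent layers, swap nodes between adjacent layers.
MOVE_PROBS = {"relocate": 0.5, "split": 0.2, "merge": 0.2, "swap": 0.1}


@dataclass
class DagSample:
    """An ordered collection of posterior structure draws plus sampler
    metadata (chain length, burn-in, acceptance rates, seed)."""

    structures: list[DbnStructure]
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    @property
    def n(self) -> int:
        return self.structures[0].n

    def save(self, path, meta_path=None) -> None:
        """Newline-delimited draws (index + W and B bitstrings) with a
        JSON metadata sidecar."""
        n = self.n
        with open(path, "w") as fh:
            for k, s in enumerate(self.structures):
                wbits = "".join(str(int(b)) for b in s.within.ravel())
                bbits = "".join(str(int(b)) for b in s.between.ravel())
                fh.write(f"{k}\t{wbits}\t{bbits}\n")
        meta = dict(self.meta)
        meta["n"] = n
        with open(meta_path or (str(path) + ".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path, meta_path=None) -> "DagSample":
        with open(meta_path or (str(path) + ".meta.json")) as fh:
            meta = json.load(fh)
        n = meta.pop("n")
        structures = []
        with open(path) as fh:
            for line in fh:
                _, wbits, bbits = line.split()
                W = np.fromiter(wbits, dtype=np.uint8).reshape(n, n).astype(bool)
                B = np.fromiter(bbits, dtype=np.uint8).reshape(n, n).astype(bool)
                structures.append(DbnStructure(W, B))
        return cls(structures=structures, meta=meta)


@dataclass
class EdgePosteriors:
    """Per-edge posterior frequencies (or exact probabilities)."""

    within: np.ndarray
    between: np.ndarray


def edge_posteriors(sample: DagSample) -> EdgePosteriors:
    """Frequency of each directed edge across the draws."""
    if len(sample) == 0:
        raise ValueError("empty sample")
    W = np.zeros((sample.n, sample.n))
    B = np.zeros((sample.n, sample.n))
    for s in sample:
        W += s.within
        B += s.between
    return EdgePosteriors(within=W / len(sample), between=B / len(sample))


# ---------------------------------------------------------------------------
# partition machinery
# ---------------------------------------------------------------------------

Layers = tuple[tuple[int, ...], ...]


def _canon(layers) -> Layers:
    return tuple(tuple(sorted(l)) for l in layers if l)


def canonical_partition(W: np.ndarray) -> Layers:
    """The unique ordered partition a within-slice DAG is consistent with:
    layer 1 holds the parentless nodes, and each later layer the nodes
    whose parents are all placed with at least one in the previous layer."""
    W = np.asarray(W, dtype=bool)
    n = W.shape[0]
    placed = np.zeros(n, dtype=bool)
    layers = []
    while not placed.all():
        if not layers:
            new = [v for v in range(n) if not W[:, v].any()]
        else:
            prev = np.zeros(n, dtype=bool)
            prev[list(layers[-1])] = True
            new = [
                v for v in range(n)
                if not placed[v]
                and not (W[:, v] & ~placed).any()
                and (W[:, v] & prev).any()
            ]
        if not new:  # pragma: no cover - impossible for a DAG
            raise RuntimeError("failed to layer a DAG")
        layers.append(tuple(sorted(new)))
        for v in new:
            placed[v] = True
    return tuple(layers)


class _PartitionScorer:
    """Vectorized layer-consistent score sums over the dense g-table."""

    def __init__(self, table: ScoreTable):
        self.table = table
        self.n = table.n
        self.M, self.G, self.V = table.dense_g()

    def masks(self, layers: Layers):
        """Per-node (allowed, required, first-layer) masks."""
        n = self.n
        A = np.zeros(n, dtype=np.int64)
        R = np.zeros(n, dtype=np.int64)
        first = np.zeros(n, dtype=bool)
        seen = 0
        prev = 0
        for li, layer in enumerate(layers):
            lm = 0
            for v in layer:
                lm |= 1 << v
            for v in layer:
                A[v] = seen
                R[v] = prev
                first[v] = li == 0
            seen |= lm
            prev = lm
        return A, R, first

    def node_scores(self, layers: Layers) -> np.ndarray:
        A, R, first = self.masks(layers)
        sel = (self.M & ~A[:, None]) == 0
        req = (self.M & R[:, None]) != 0
        ok = self.V & sel & np.where(first[:, None], self.M == 0, req)
        vals = np.where(ok, self.G, -np.inf)
        with np.errstate(invalid="ignore"):
            return logsumexp(vals, axis=1)

    def score(self, layers: Layers) -> float:
        return float(self.node_scores(layers).sum())

    def sample_structure(self, layers: Layers, rng: np.random.Generator) -> DbnStructure:
        """Draw (W, B) given the partition, in proportion to its score."""
        A, R, first = self.masks(layers)
        n = self.n
        W = np.zeros((n, n), dtype=bool)
        B = np.zeros((n, n), dtype=bool)
        for i in range(n):
            if first[i]:
                wm = 0
            else:
                sel = (self.M[i] & ~A[i]) == 0
                req = (self.M[i] & R[i]) != 0
                ok = self.V[i] & sel & req
                idx = np.flatnonzero(ok)
                gv = self.G[i, idx]
                p = np.exp(gv - logsumexp(gv))
                wm = int(self.M[i, idx[rng.choice(idx.size, p=p)]])
            bms, vals = self.table.s2_by_w[i][wm]
            p = np.exp(vals - logsumexp(vals))
            bm = int(bms[rng.choice(bms.size, p=p)])
            for v in range(n):
                if wm >> v & 1:
                    W[v, i] = True
                if bm >> v & 1:
                    B[v, i] = True
        return DbnStructure(W, B)


def _relocate_candidates(layers: Layers, v: int) -> list[Layers]:
    """All distinct states reachable by moving node ``v``, excluding the
    current state."""
    rem = [list(l) for l in layers]
    for l in rem:
        if v in l:
            l.remove(v)
    rem = [l for l in rem if l]
    out = []
    for j in range(len(rem)):
        cand = [list(l) for l in rem]
        cand[j].append(v)
        out.append(_canon(cand))
    for gap in range(len(rem) + 1):
        cand = [list(l) for l in rem]
        cand.insert(gap, [v])
        out.append(_canon(cand))
    cur = _canon(layers)
    uniq = []
    for c in out:
        if c != cur and c not in uniq:
            uniq.append(c)
    return uniq


def _propose(layers: Layers, rng: np.random.Generator):
    """One partition move; returns (new_layers, log proposal ratio
    log q(x|x') - log q(x'|x)) or None for a null proposal."""
    k = len(layers)
    n = sum(len(l) for l in layers)
    u = rng.random()
    if u < MOVE_PROBS["relocate"]:
        v = int(rng.integers(n))
        cands = _relocate_candidates(layers, v)
        if not cands:
            return None
        new = cands[int(rng.integers(len(cands)))]
        back = _relocate_candidates(new, v)
        return new, float(np.log(len(cands)) - np.log(len(back)))
    if u < MOVE_PROBS["relocate"] + MOVE_PROBS["split"]:
        j = int(rng.integers(k))
        s = len(layers[j])
        if s < 2:
            return None
        r = int(rng.integers(1, (1 << s) - 1))
        head = [layers[j][t] for t in range(s) if r >> t & 1]
        tail = [layers[j][t] for t in range(s) if not r >> t & 1]
        new = layers[:j] + (tuple(sorted(head)), tuple(sorted(tail))) + layers[j + 1:]
        return _canon(new), float(np.log((1 << s) - 2))
    if u < MOVE_PROBS["relocate"] + MOVE_PROBS["split"] + MOVE_PROBS["merge"]:
        if k < 2:
            return None
        j = int(rng.integers(k - 1))
        merged = tuple(sorted(layers[j] + layers[j + 1]))
        new = layers[:j] + (merged,) + layers[j + 2:]
        s = len(merged)
        return _canon(new), float(-np.log((1 << s) - 2))
    if k < 2:
        return None
    j = int(rng.integers(k - 1))
    a = layers[j][int(rng.integers(len(layers[j])))]
    b = layers[j + 1][int(rng.integers(len(layers[j + 1])))]
    la = tuple(sorted(set(layers[j]) - {a} | {b}))
    lb = tuple(sorted(set(layers[j + 1]) - {b} | {a}))
    new = layers[:j] + (la, lb) + layers[j + 2:]
    return _canon(new), 0.0


def _record_schedule(chain_length: int, burn_in: int, n_samples: int) -> np.ndarray:
    idxs = np.linspace(burn_in, chain_length - 1, n_samples).round().astype(int)
    rec = np.zeros(chain_length, dtype=int)
    np.add.at(rec, idxs, 1)
    return rec


def sample_dags(scores: ScoreTable, n_samples: int = 10_000,
                chain_length: int = 1_000_000, burn_in: int | None = None,
                seed: int | None = None, method: str = "partition",
                initial: Layers | DbnStructure | None = None) -> DagSample:
    """Draw structures approximately proportional to ``exp(score)``.

    ``burn_in`` defaults to 20% of ``chain_length``; the post-burn-in
    stretch is thinned evenly to exactly ``n_samples`` draws.  The seed is
    mandatory; identical inputs and seed give identical samples.
    """
    if seed is None:
        raise ConfigurationError("a seed is required for reproducible sampling")
    if burn_in is None:
        burn_in = chain_length // 5
    if not 0 <= burn_in < chain_length:
        raise ConfigurationError("burn_in must be smaller than chain_length")
    if n_samples < 1:
        raise ConfigurationError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    if method == "partition":
        return _sample_partition(scores, n_samples, chain_length, burn_in,
                                 rng, seed, initial)
    if method == "structure":
        return _sample_structure_mcmc(scores, n_samples, chain_length,
                                      burn_in, rng, seed, initial)
    raise ConfigurationError(f"unknown sampling method {method!r}")


def _sample_partition(scores, n_samples, chain_length, burn_in, rng, seed,
                      initial) -> DagSample:
    sc = _PartitionScorer(scores)
    n = scores.n
    if initial is None:
        layers: Layers = (tuple(range(n)),)
    elif isinstance(initial, DbnStructure):
        layers = canonical_partition(initial.within)
    else:
        layers = _canon(initial)
    cur = sc.score(layers)
    if not np.isfinite(cur):
        raise RuntimeError("initial partition has non-finite score")
    rec = _record_schedule(chain_length, burn_in, n_samples)
    draws: list[DbnStructure] = []
    accepted = 0
    proposed = 0
    trace = []
    trace_every = max(1, chain_length // 1000)
    for t in range(chain_length):
        move = _propose(layers, rng)
        if move is not None:
            proposed += 1
            new, logq = move
            new_score = sc.score(new)
            if np.isfinite(new_score) and (
                    np.log(rng.random()) < new_score - cur + logq):
                layers, cur = new, new_score
                accepted += 1
        if t % trace_every == 0:
            trace.append(cur)
        for _ in range(rec[t]):
            draws.append(sc.sample_structure(layers, rng))
    meta = {
        "method": "partition", "chain_length": chain_length,
        "burn_in": burn_in, "n_samples": n_samples, "seed": seed,
        "acceptance_rate": accepted / max(proposed, 1),
        "score_trace": trace,
    }
    return DagSample(structures=draws, meta=meta)


# ---------------------------------------------------------------------------
# structure MCMC baseline
# ---------------------------------------------------------------------------


def _sample_structure_mcmc(scores, n_samples, chain_length, burn_in, rng,
                           seed, initial) -> DagSample:
    n = scores.n
    cap = scores.max_parents
    if initial is None or not isinstance(initial, DbnStructure):
        W = np.zeros((n, n), dtype=bool)
        B = np.zeros((n, n), dtype=bool)
    else:
        W = initial.within.copy()
        B = initial.between.copy()

    def wmask(j):
        m = 0
        for v in np.flatnonzero(W[:, j]):
            m |= 1 << int(v)
        return m

    def bmask(j):
        m = 0
        for v in np.flatnonzero(B[:, j]):
            m |= 1 << int(v)
        return m

    local = [scores.local_total(j, wmask(j), bmask(j)) for j in range(n)]
    rec = _record_schedule(chain_length, burn_in, n_samples)
    draws = []
    accepted = 0
    proposed = 0
    for t in range(chain_length):
        u = rng.random()
        if u < 0.4:  # toggle a within-slice edge
            i, j = _random_pair(rng, n)
            proposed += 1
            W[i, j] = not W[i, j]
            ok = topological_order(W) is not None
            key = (wmask(j), bmask(j))
            ok = ok and key in scores.s2[j]
            if ok:
                new_j = scores.local_total(j, *key)
                if np.log(rng.random()) < new_j - local[j]:
                    local[j] = new_j
                    accepted += 1
                else:
                    ok = False
            if not ok:
                W[i, j] = not W[i, j]
        elif u < 0.6:  # reverse a within-slice edge
            i, j = _random_pair(rng, n)
            if W[i, j]:
                proposed += 1
                W[i, j] = False
                W[j, i] = True
                ok = topological_order(W) is not None
                ki = (wmask(i), bmask(i))
                kj = (wmask(j), bmask(j))
                ok = ok and ki in scores.s2[i] and kj in scores.s2[j]
                if ok:
                    new_i = scores.local_total(i, *ki)
                    new_j = scores.local_total(j, *kj)
                    if np.log(rng.random()) < (new_i + new_j
                                               - local[i] - local[j]):
                        local[i], local[j] = new_i, new_j
                        accepted += 1
                    else:
                        ok = False
                if not ok:
                    W[j, i] = False
                    W[i, j] = True
        else:  # toggle a between-slice edge
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            proposed += 1
            B[i, j] = not B[i, j]
            key = (wmask(j), bmask(j))
            ok = key in scores.s2[j]
            if ok:
                new_j = scores.local_total(j, *key)
                if np.log(rng.random()) < new_j - local[j]:
                    local[j] = new_j
                    accepted += 1
                else:
                    ok = False
            if not ok:
                B[i, j] = not B[i, j]
        for _ in range(rec[t]):
            draws.append(DbnStructure(W.copy(), B.copy()))
    meta = {
        "method": "structure", "chain_length": chain_length,
        "burn_in": burn_in, "n_samples": n_samples, "seed": seed,
        "acceptance_rate": accepted / max(proposed, 1),
    }
    return DagSample(structures=draws, meta=meta)


def _random_pair(rng, n):
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    return i, j


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------


@dataclass
class ExactPosterior:
    """Exact edge posteriors from full enumeration."""

    within: np.ndarray
    between: np.ndarray
    log_evidence: float
    n_structures: int


def exhaustive_posterior(scores: ScoreTable,
                         budget: int = 2_000_000) -> ExactPosterior:
    """Enumerate every admissible (W, B), exactly.

    Iterates all combinations of per-node within-parent sets, keeps the
    acyclic ones, and accumulates normalised posterior mass; between-slice
    parents are marginalised per node in closed form.  Refuses problems
    whose within-structure product exceeds ``budget``.
    """
    n = scores.n
    per_node_masks = [sorted(scores.g[i]) for i in range(n)]
    combos = prod(len(m) for m in per_node_masks)
    if combos > budget:
        raise BudgetError(
            f"{combos} within-structure combinations exceed budget {budget}")

    # per (node, within mask): P(between edge) vector and B-set count
    b_prob: list[dict[int, np.ndarray]] = [dict() for _ in range(n)]
    b_count: list[dict[int, int]] = [dict() for _ in range(n)]
    for i in range(n):
        for wm, (bms, vals) in scores.s2_by_w[i].items():
            w = np.exp(vals - logsumexp(vals))
            member = (bms[:, None] >> np.arange(n)) & 1
            b_prob[i][wm] = member.T @ w
            b_count[i][wm] = len(bms)

    logws = []
    states = []
    for masks in product(*per_node_masks):
        W = np.zeros((n, n), dtype=bool)
        for j, wm in enumerate(masks):
            for v in range(n):
                if wm >> v & 1:
                    W[v, j] = True
        if topological_order(W) is None:
            continue
        logws.append(sum(scores.g[j][wm] for j, wm in enumerate(masks)))
        states.append(masks)
    if not states:
        raise RuntimeError("no admissible structure")
    logws = np.asarray(logws)
    log_z = float(logsumexp(logws))
    w = np.exp(logws - log_z)

    within = np.zeros((n, n))
    between = np.zeros((n, n))
    n_structures = 0
    for weight, masks in zip(w, states):
        for j, wm in enumerate(masks):
            for v in range(n):
                if wm >> v & 1:
                    within[v, j] += weight
            between[:, j] += weight * b_prob[j][wm]
        n_structures += prod(b_count[j][wm] for j, wm in enumerate(masks))
    return ExactPosterior(within=within, between=between,
                          log_evidence=log_z, n_structures=n_structures)
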