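"""Bayesian-Dirichlet (BDe) marginal-likelihood scoring of two-slice DBNs.

Every node is binary, so each family score is a product of Beta functions:
for a node with parent set of size ``k`` (``q = 2**k`` configurations) and
per-cell prior weight ``alpha = ess / (2 q)`` (the BDeu choice, uniform
over the node's ``2 q`` cells), the log marginal likelihood is

    sum_j  log B(alpha + k_j, alpha + m_j) - log B(alpha, alpha)

with ``k_j`` ones and ``m_j`` zeros observed under configuration ``j``.
This score is decomposable over families and identical across
Markov-equivalent DAGs.

A two-slice structure ``(W, B)`` is scored as the sum of

* one slice-2 family per node: child = node's values at wave ``t + 1``,
  parents = its W-parents at ``t + 1`` plus its B-parents at ``t``;
* (by default) one slice-1 family per node: child = node's values at wave
  ``t``, parents = its W-parents at ``t`` — so the antecedent wave's data
  also inform the shared within-slice structure;
* the log structure prior (uniform by default, optionally a per-edge
  penalty ``gamma ** n_edges``).

:func:`build_score_table` precomputes all family scores up to a parent-set
cap, which is what the samplers consume.
"""

from __future__ import annotations

import hashlib
import json
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

from .panel_io import ConfigurationError, TransitionTable
from .structures import DbnStructure, StructureError


class BudgetError(RuntimeError):
    """Parent-set enumeration would exceed the configured budget."""


def _as_prior(prior) -> float:
    """Normalise a structure-prior spec to a per-edge log penalty."""
    if prior is None or prior == "uniform":
        return 0.0
    if isinstance(prior, dict) and "edge_penalty" in prior:
        gamma = float(prior["edge_penalty"])
        if gamma <= 0:
            raise ConfigurationError("edge_penalty must be positive")
        return float(np.log(gamma))
    raise ConfigurationError(f"unknown structure prior spec {prior!r}")


def local_bde_score(child_values, parent_values, ess: float) -> float:
    """Log BDe marginal likelihood of one binary family.

    ``parent_values`` is a (rows, k) 0/1 matrix (``None`` or zero columns
    for a parentless node).  Empty data scores 0 (log of 1).
    """
    if ess <= 0:
        raise ConfigurationError("equivalent sample size must be positive")
    child = np.asarray(child_values, dtype=np.int64).ravel()
    if parent_values is None:
        parents = np.zeros((child.size, 0), dtype=np.int64)
    else:
        parents = np.asarray(parent_values, dtype=np.int64)
        parents = parents.reshape(child.size, -1)
    if child.size == 0:
        return 0.0
    k = parents.shape[1]
    q = 1 << k
    alpha = ess / (2.0 * q)
    idx = parents @ (1 << np.arange(k, dtype=np.int64)) if k else np.zeros(child.size, dtype=np.int64)
    counts = np.bincount(2 * idx + child, minlength=2 * q)
    n0 = counts[0::2]
    n1 = counts[1::2]
    return float(np.sum(betaln(alpha + n1, alpha + n0) - betaln(alpha, alpha)))


def score_structure(structure: DbnStructure, table: TransitionTable,
                    ess: float = 1.0, prior=None,
                    score_first_slice: bool = True) -> float:
    """Log posterior score of a concrete structure, computed from the data.

    Decomposable: toggling one edge changes exactly one node's slice-2
    term (and, for a within-slice edge, the same node's slice-1 term).
    """
    if structure.n != table.n:
        raise StructureError("structure and table dimensions differ")
    log_pen = _as_prior(prior)
    X0, X1 = table.X0, table.X1
    total = 0.0
    for j in range(structure.n):
        wpa = structure.w_parents(j)
        bpa = structure.b_parents(j)
        par2 = np.hstack([X1[:, wpa], X0[:, bpa]])
        total += local_bde_score(X1[:, j], par2, ess)
        if score_first_slice:
            total += local_bde_score(X0[:, j], X0[:, wpa], ess)
    total += log_pen * structure.n_edges()
    return total


def _mask(subset: tuple[int, ...]) -> int:
    m = 0
    for v in subset:
        m |= 1 << v
    return m


class ScoreTable:
    """Precomputed family scores for every admissible parent set.

    Per node ``i`` the table stores

    * ``s1[i]``: within-parent-set mask -> slice-1 log likelihood,
    * ``s2[i]``: (within mask, between mask) -> slice-2 log likelihood,
      for all combined sets up to ``max_parents``,
    * ``g[i]``: within mask -> the node's full contribution with the
      between-slice parents marginalised out (log-sum-exp over all
      admissible between sets), including the structure prior — the
      quantity partition MCMC and exhaustive enumeration work with.
    """

    def __init__(self, n: int, var_names: list[str], ess: float,
                 max_parents: int, prior, score_first_slice: bool,
                 n_rows: int):
        self.n = n
        self.var_names = var_names
        self.ess = ess
        self.max_parents = max_parents
        self.prior = prior
        self.log_edge_penalty = _as_prior(prior)
        self.score_first_slice = score_first_slice
        self.n_rows = n_rows
        self.s1: list[dict[int, float]] = [dict() for _ in range(n)]
        self.s2: list[dict[tuple[int, int], float]] = [dict() for _ in range(n)]
        self.s2_by_w: list[dict[int, tuple[np.ndarray, np.ndarray]]] = [dict() for _ in range(n)]
        self.g: list[dict[int, float]] = [dict() for _ in range(n)]
        self._dense = None

    # -- lookups used by the structure sampler ---------------------------
    def local_total(self, i: int, wmask: int, bmask: int) -> float:
        """Full contribution of node ``i`` with concrete parent sets."""
        val = self.s2[i].get((wmask, bmask))
        if val is None:
            raise KeyError(f"parent sets exceed cap for node {i}")
        if self.score_first_slice:
            val = val + self.s1[i][wmask]
        nb = bin(wmask).count("1") + bin(bmask).count("1")
        return val + self.log_edge_penalty * nb

    def _finalize(self):
        """Build B-marginalised tables once all raw scores are stored."""
        for i in range(self.n):
            by_w: dict[int, tuple[list[int], list[float]]] = {}
            for (wm, bm), s in self.s2[i].items():
                pen = self.log_edge_penalty * bin(bm).count("1")
                by_w.setdefault(wm, ([], []))[0].append(bm)
                by_w[wm][1].append(s + pen)
            for wm, (bms, vals) in by_w.items():
                bms_arr = np.asarray(bms, dtype=np.int64)
                vals_arr = np.asarray(vals, dtype=float)
                self.s2_by_w[i][wm] = (bms_arr, vals_arr)
                g = logsumexp(vals_arr)
                if self.score_first_slice:
                    g += self.s1[i][wm]
                g += self.log_edge_penalty * bin(wm).count("1")
                self.g[i][wm] = float(g)

    def dense_g(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(masks, values, valid) padded to (n, max_sets) for vectorized
        partition scoring; entry 0 of each row is the empty set."""
        if self._dense is None:
            width = max(len(d) for d in self.g)
            M = np.zeros((self.n, width), dtype=np.int64)
            G = np.full((self.n, width), -np.inf)
            V = np.zeros((self.n, width), dtype=bool)
            for i in range(self.n):
                ms = sorted(self.g[i], key=lambda m: (bin(m).count("1"), m))
                assert ms[0] == 0
                for k, m in enumerate(ms):
                    M[i, k] = m
                    G[i, k] = self.g[i][m]
                    V[i, k] = True
            self._dense = (M, G, V)
        return self._dense

    # -- cache / serialisation -------------------------------------------
    def cache_key(self, table: TransitionTable) -> str:
        h = hashlib.sha256()
        h.update(table.X0.tobytes())
        h.update(table.X1.tobytes())
        h.update(json.dumps([self.ess, self.max_parents, str(self.prior),
                             self.score_first_slice]).encode())
        return h.hexdigest()

    def save(self, path) -> None:
        d = {
            "n": self.n, "var_names": self.var_names, "ess": self.ess,
            "max_parents": self.max_parents, "prior": self.prior,
            "score_first_slice": self.score_first_slice, "n_rows": self.n_rows,
            "s1": [{str(k): v for k, v in di.items()} for di in self.s1],
            "s2": [{f"{k[0]},{k[1]}": v for k, v in di.items()} for di in self.s2],
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def load(cls, path) -> "ScoreTable":
        with open(path) as fh:
            d = json.load(fh)
        t = cls(d["n"], d["var_names"], d["ess"], d["max_parents"],
                d["prior"], d["score_first_slice"], d["n_rows"])
        for i in range(t.n):
            t.s1[i] = {int(k): v for k, v in d["s1"][i].items()}
            t.s2[i] = {tuple(int(x) for x in k.split(",")): v
                       for k, v in d["s2"][i].items()}
        t._finalize()
        return t


def build_score_table(table: TransitionTable, ess: float = 1.0,
                      max_parents: int = 4, prior=None,
                      score_first_slice: bool = True,
                      budget: int = 2_000_000) -> ScoreTable:
    """Exhaustively score all admissible parent sets up to the cap.

    Slice-1 candidates for node ``i`` are the other ``n - 1`` variables;
    slice-2 candidates additionally include all ``n`` variables of the
    antecedent slice.  Raises :class:`BudgetError` when the total number
    of families would exceed ``budget``.
    """
    if max_parents < 0:
        raise ConfigurationError("max_parents must be non-negative")
    if ess <= 0:
        raise ConfigurationError("equivalent sample size must be positive")
    _as_prior(prior)  # validate early
    n = table.n
    rows = table.n_rows

    def n_subsets(m, cap):
        return sum(comb(m, k) for k in range(min(m, cap) + 1))

    per_node = sum(
        n_subsets(n - 1, max_parents - kb) * comb(n, kb)
        for kb in range(min(n, max_parents) + 1)
    ) + n_subsets(n - 1, max_parents)
    if per_node * n > budget:
        raise BudgetError(
            f"{per_node * n} parent sets exceed budget {budget}; "
            f"lower max_parents or raise the budget"
        )

    st = ScoreTable(n, list(table.var_names), ess, max_parents, prior,
                    score_first_slice, rows)
    X0 = table.X0.astype(np.int64)
    X1 = table.X1.astype(np.int64)

    # gammaln lookup tables per parent-set size, so each family score is a
    # pure table-lookup sum
    gl_a, gl_2a = {}, {}
    for k in range(max_parents + 1):
        alpha = ess / (2.0 * (1 << k))
        gl_a[k] = gammaln(alpha + np.arange(rows + 1))
        gl_2a[k] = gammaln(2 * alpha + np.arange(rows + 1))

    def family(child, idx, k):
        q = 1 << k
        counts = np.bincount(2 * idx + child, minlength=2 * q)
        n0 = counts[0::2]
        n1 = counts[1::2]
        return float(np.sum(gl_a[k][n1] + gl_a[k][n0] - gl_2a[k][n1 + n0])
                     - q * (2 * gl_a[k][0] - gl_2a[k][0]))

    zero_idx = np.zeros(rows, dtype=np.int64)
    for i in range(n):
        others = [v for v in range(n) if v != i]
        c0 = X0[:, i]
        c1 = X1[:, i]
        for kw in range(min(len(others), max_parents) + 1):
            for wsub in combinations(others, kw):
                wm = _mask(wsub)
                widx = (X1[:, list(wsub)] @ (1 << np.arange(kw, dtype=np.int64))
                        if kw else zero_idx)
                widx0 = (X0[:, list(wsub)] @ (1 << np.arange(kw, dtype=np.int64))
                         if kw else zero_idx)
                st.s1[i][wm] = family(c0, widx0, kw)
                for kb in range(max_parents - kw + 1):
                    for bsub in combinations(range(n), kb):
                        bidx = (X0[:, list(bsub)] @ (1 << np.arange(kb, dtype=np.int64))
                                if kb else zero_idx)
                        idx = widx + (bidx << kw)
                        st.s2[i][(wm, _mask(bsub))] = family(c1, idx, kw + kb)
    st._finalize()
    return st
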