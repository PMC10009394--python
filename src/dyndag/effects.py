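"""Posterior distributions of do-calculus intervention effects.

For each sampled structure the unrolled two-slice network is a ``2n``-node
DAG with conditional probability tables estimated from the transition
table.  The *total causal effect* of a slice-1 variable ``s`` on a slice-2
variable ``y`` is

    P(y = 1 | do(s = 1)) - P(y = 1 | do(s = 0)),

computed exactly on the mutilated graph (incoming edges of ``s`` deleted,
``s`` clamped) by summation over the ancestral set of ``y`` — no Monte
Carlo inference anywhere.  Effects flow through all causal paths,
including mediation through within-slice edges of the later slice.

Parameter uncertainty is propagated by conjugacy: each CPT cell has a
Beta posterior with prior weight ``ess / (2 q)`` per cell plus the
observed counts, and one parameter draw is taken per structure draw.
Collating one effect per (structure draw, source, target) yields the
posterior effect distribution, summarised by its mean and an equal-tailed
credible interval; a pair is flagged significant when the interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import ConfigurationError, TransitionTable
from .sampler import DagSample
from .structures import DbnStructure, topological_order


@dataclass
class ParameterDraw:
    """One draw of all CPTs for a structure.

    ``theta_first[j]``: P(node j = 1 | within-parent config) on slice 1;
    ``theta_trans[j]``: P(node j = 1 | within-parents (low bits) then
    between-parents (high bits)) on slice 2.  Configuration indexing uses
    sorted parent order, first parent = least significant bit.
    """

    structure: DbnStructure
    theta_first: list[np.ndarray]
    theta_trans: list[np.ndarray]


def _family_counts(child: np.ndarray, parents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = parents.shape[1]
    q = 1 << k
    idx = parents @ (1 << np.arange(k, dtype=np.int64)) if k else np.zeros(len(child), dtype=np.int64)
    counts = np.bincount(2 * idx + child, minlength=2 * q)
    return counts[1::2], counts[0::2]


class _CountCache:
    """Memoises per-family counts across structure draws."""

    def __init__(self, table: TransitionTable):
        self.X0 = table.X0.astype(np.int64)
        self.X1 = table.X1.astype(np.int64)
        self._cache: dict = {}

    def first(self, j: int, wpa: tuple[int, ...]):
        key = ("first", j, wpa)
        if key not in self._cache:
            self._cache[key] = _family_counts(self.X0[:, j], self.X0[:, list(wpa)])
        return self._cache[key]

    def trans(self, j: int, wpa: tuple[int, ...], bpa: tuple[int, ...]):
        key = ("trans", j, wpa, bpa)
        if key not in self._cache:
            parents = np.hstack([self.X1[:, list(wpa)], self.X0[:, list(bpa)]])
            self._cache[key] = _family_counts(self.X1[:, j], parents)
        return self._cache[key]


def draw_parameters(structure: DbnStructure, table: TransitionTable,
                    ess: float = 1.0, seed=None,
                    _cache: _CountCache | None = None) -> ParameterDraw:
    """One independent Beta draw per (node, parent configuration).

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if ess <= 0:
        raise ConfigurationError("equivalent sample size must be positive")
    if structure.n != table.n:
        raise ConfigurationError("structure and table dimensions differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cache = _cache or _CountCache(table)
    theta_first, theta_trans = [], []
    for j in range(structure.n):
        wpa = tuple(int(v) for v in structure.w_parents(j))
        bpa = tuple(int(v) for v in structure.b_parents(j))
        eps = 1e-12  # Beta draws with tiny shape can underflow to exactly 0/1
        n1, n0 = cache.first(j, wpa)
        alpha = ess / (2.0 * (1 << len(wpa)))
        theta_first.append(np.clip(rng.beta(alpha + n1, alpha + n0), eps, 1 - eps))
        n1, n0 = cache.trans(j, wpa, bpa)
        alpha = ess / (2.0 * (1 << (len(wpa) + len(bpa))))
        theta_trans.append(np.clip(rng.beta(alpha + n1, alpha + n0), eps, 1 - eps))
    return ParameterDraw(structure=structure, theta_first=theta_first,
                         theta_trans=theta_trans)


# ---------------------------------------------------------------------------
# exact inference on the unrolled network
# ---------------------------------------------------------------------------


def _unrolled_cpts(params: ParameterDraw):
    """Node -> (parents tuple, P(node=1 | config) table) over 2n nodes."""
    st = params.structure
    n = st.n
    out = {}
    for j in range(n):
        wpa = tuple(int(v) for v in st.w_parents(j))
        out[j] = (wpa, np.asarray(params.theta_first[j]))
        bpa = tuple(int(v) for v in st.b_parents(j))
        par2 = tuple(v + n for v in wpa) + bpa
        out[j + n] = (par2, np.asarray(params.theta_trans[j]))
    return out


def _slice2_descendants(structure: DbnStructure) -> np.ndarray:
    """Boolean (source, target) matrix: is slice-2 ``target`` a descendant
    of slice-1 ``source`` in the unrolled (mutilated-or-not) graph?"""
    n = structure.n
    W = structure.within
    B = structure.between
    # reflexive-transitive closure of W by repeated squaring
    reach = np.eye(n, dtype=bool) | W
    for _ in range(int(np.ceil(np.log2(max(n, 2))))):
        reach = reach | (reach @ reach)
    # source -> (W paths at t) -> B -> (W paths at t+1) -> target
    return (reach @ B @ reach).astype(bool)


def _ancestors(cpts: dict, target: int) -> set[int]:
    anc = set()
    stack = [target]
    while stack:
        v = stack.pop()
        for p in cpts[v][0]:
            if p not in anc:
                anc.add(p)
                stack.append(p)
    return anc


def _enum_prob(cpts: dict, target: int, source: int, x: int,
               variables: list[int]) -> float:
    """P(target = 1 | do(source = x)) by joint enumeration over
    ``variables`` (which contains target; source is clamped)."""
    free = [v for v in variables if v != source]
    m = len(free)
    pos = {v: t for t, v in enumerate(free)}
    bits = (np.arange(1 << m)[:, None] >> np.arange(m)) & 1

    def col(v):
        return np.full(1 << m, x) if v == source else bits[:, pos[v]]

    joint = np.ones(1 << m)
    for v in variables:
        if v == source:
            continue
        pa, tab = cpts[v]
        idx = np.zeros(1 << m, dtype=np.int64)
        for t, p in enumerate(pa):
            idx += col(p) << t
        p1 = tab[idx]
        joint *= np.where(col(v) == 1, p1, 1.0 - p1)
    return float(joint[col(target) == 1].sum())


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars_, table):
        self.vars = tuple(vars_)
        self.table = np.asarray(table, dtype=float)

    def multiply(self, other: "_Factor") -> "_Factor":
        vs = list(self.vars) + [v for v in other.vars if v not in self.vars]
        a = self._expand(vs)
        b = other._expand(vs)
        return _Factor(vs, a * b)

    def _expand(self, vs):
        shape = [2 if v in self.vars else 1 for v in vs]
        order = [self.vars.index(v) for v in vs if v in self.vars]
        return np.transpose(self.table, order).reshape(shape)

    def sum_out(self, v) -> "_Factor":
        ax = self.vars.index(v)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:],
                       self.table.sum(axis=ax))


def _ve_prob(cpts: dict, target: int, source: int, x: int,
             variables: list[int]) -> float:
    """P(target = 1 | do(source = x)) by variable elimination."""
    factors = []
    for v in variables:
        if v == source:
            continue
        pa, tab = cpts[v]
        k = len(pa)
        configs = (np.arange(1 << k)[:, None] >> np.arange(k)) & 1
        p1 = tab[np.arange(1 << k)]
        full = np.empty((2,) * (k + 1))
        # axis order: (v, pa[0], pa[1], ...)
        full[1] = p1.reshape((2,) * k, order="F") if k else p1[0]
        full[0] = 1.0 - full[1]
        fvars = [v] + [p for p in pa]
        f = _Factor(fvars, full)
        if source in f.vars:
            ax = f.vars.index(source)
            f = _Factor(f.vars[:ax] + f.vars[ax + 1:],
                        np.take(f.table, x, axis=ax))
        factors.append(f)
    elim = [v for v in variables if v not in (source, target)]
    while elim:
        # greedy: eliminate the variable whose combined factor is smallest
        def cost(v):
            vs = set()
            for f in factors:
                if v in f.vars:
                    vs |= set(f.vars)
            return len(vs)
        v = min(elim, key=cost)
        elim.remove(v)
        group = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = group[0]
        for f in group[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.sum_out(v)]
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    table = result.table
    if result.vars != (target,):
        table = table.reshape(2)
    return float(table[1])


def do_effect(structure: DbnStructure, params: ParameterDraw, source: int,
              target: int, enum_limit: int = 20) -> float:
    """Exact total effect of slice-1 ``source`` on slice-2 ``target``.

    Deletes the source's incoming edges, clamps it to 1 then 0, and
    marginalises the remaining variables restricted to the ancestral set
    of the target; joint enumeration is used up to ``enum_limit``
    ancestral variables and variable elimination beyond.  Returns exactly
    0 whenever the target is not a descendant of the clamped source.
    """
    n = structure.n
    cpts = _unrolled_cpts(params)
    tgt = target + n
    if not _slice2_descendants(structure)[source, target]:
        return 0.0
    anc = _ancestors(cpts, tgt)
    variables = sorted(anc | {tgt})
    fn = _enum_prob if len(variables) <= enum_limit else _ve_prob
    return fn(cpts, tgt, source, 1, variables) - fn(cpts, tgt, source, 0, variables)


def all_effects(structure: DbnStructure, params: ParameterDraw,
                max_enum_vars: int = 14) -> np.ndarray:
    """Effect matrix (source at t, target at t + 1) for all pairs.

    Vectorized exact computation: the slice-1 joint under ``do(s = x)``
    is enumerated once per (source, value) over the ``2**n`` slice-1
    configurations, and each target's conditional success probability
    given slice 1 is tabulated by summing over its within-slice ancestor
    set.  Falls back to pairwise :func:`do_effect` for large ``n``.
    """
    n = structure.n
    if n > max_enum_vars:
        return np.array([[do_effect(structure, params, s, y)
                          for y in range(n)] for s in range(n)])

    bits = ((np.arange(1 << n)[:, None] >> np.arange(n)) & 1).astype(np.int64)
    # per-node conditionals on slice 1
    pnode = np.empty((1 << n, n))
    for j in range(n):
        wpa = structure.w_parents(j)
        idx = bits[:, wpa] @ (1 << np.arange(len(wpa), dtype=np.int64))
        p1 = params.theta_first[j][idx]
        pnode[:, j] = np.where(bits[:, j] == 1, p1, 1.0 - p1)
    joint_all = pnode.prod(axis=1)

    # f[y][z] = P(y at t+1 = 1 | slice-1 config z), marginalising y's
    # within-slice ancestors at t+1
    W = structure.within
    f = np.empty((n, 1 << n))
    anc_sets = {}
    for y in range(n):
        anc = set()
        stack = [int(v) for v in np.flatnonzero(W[:, y])]
        while stack:
            v = stack.pop()
            if v not in anc:
                anc.add(v)
                stack.extend(int(u) for u in np.flatnonzero(W[:, v]))
        anc_sets[y] = sorted(anc)
    for y in range(n):
        L = anc_sets[y]
        m = len(L)
        pos = {v: t for t, v in enumerate(L)}
        abits = ((np.arange(1 << m)[:, None] >> np.arange(m)) & 1).astype(np.int64)
        acc = np.ones((1 << n, 1 << m))
        for j in L + [y]:
            wpa = [int(v) for v in structure.w_parents(j)]
            bpa = [int(v) for v in structure.b_parents(j)]
            idx_w = np.zeros(1 << m, dtype=np.int64)
            for t, p in enumerate(wpa):
                idx_w += abits[:, pos[p]] << t
            idx_b = bits[:, bpa] @ (1 << np.arange(len(bpa), dtype=np.int64))
            idx = idx_w[None, :] + (idx_b[:, None] << len(wpa))
            p1 = params.theta_trans[j][idx]
            if j == y:
                acc *= p1
            else:
                val = abits[:, pos[j]][None, :]
                acc *= np.where(val == 1, p1, 1.0 - p1)
        f[y] = acc.sum(axis=1)

    eff = np.empty((n, n))
    for s in range(n):
        w_do = joint_all / pnode[:, s]
        sel1 = bits[:, s] == 1
        sel0 = ~sel1
        p1 = f[:, sel1] @ w_do[sel1]
        p0 = f[:, sel0] @ w_do[sel0]
        eff[s] = p1 - p0
    eff[~_slice2_descendants(structure)] = 0.0
    return eff


# ---------------------------------------------------------------------------
# posterior effect distributions
# ---------------------------------------------------------------------------


@dataclass
class EffectDistribution:
    """Per (source at t, target at t + 1) posterior effect draws and their
    summaries.  ``draws`` has shape (n_draws, n_sources, n_targets)."""

    sources: list[str]
    targets: list[str]
    draws: np.ndarray
    level: float = 0.95
    mean: np.ndarray = field(init=False)
    lower: np.ndarray = field(init=False)
    upper: np.ndarray = field(init=False)
    significant: np.ndarray = field(init=False)

    def __post_init__(self):
        lo = (1.0 - self.level) / 2.0
        self.mean = self.draws.mean(axis=0)
        self.lower = np.quantile(self.draws, lo, axis=0)
        self.upper = np.quantile(self.draws, 1.0 - lo, axis=0)
        self.significant = (self.lower > 0) | (self.upper < 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, s in enumerate(self.sources):
            for b, t in enumerate(self.targets):
                rows.append({
                    "source": s, "target": t,
                    "mean": self.mean[a, b],
                    "lower": self.lower[a, b], "upper": self.upper[a, b],
                    "significant": bool(self.significant[a, b]),
                    "n_draws": self.draws.shape[0],
                })
        return pd.DataFrame(rows)

    def save(self, summary_path, draws_path=None) -> None:
        self.to_frame().to_csv(summary_path, index=False)
        if draws_path is not None:
            np.save(draws_path, self.draws)


def effect_distribution(sample: DagSample, table: TransitionTable,
                        ess: float = 1.0, seed: int | None = None,
                        level: float = 0.95) -> EffectDistribution:
    """Posterior effect distribution over a structure sample.

    One parameter draw per structure draw; each contributes one exact
    effect value per (source, target) pair, including the diagonal (a
    variable's effect on itself at the next slice — its momentum).
    """
    if len(sample) == 0:
        raise ValueError("empty structure sample")
    if not 0 < level < 1:
        raise ConfigurationError("credibility level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cache = _CountCache(table)
    n = table.n
    draws = np.empty((len(sample), n, n))
    for k, structure in enumerate(sample):
        params = draw_parameters(structure, table, ess=ess, seed=rng,
                                 _cache=cache)
        draws[k] = all_effects(structure, params)
    return EffectDistribution(sources=list(table.var_names),
                              targets=list(table.var_names),
                              draws=draws, level=level)
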